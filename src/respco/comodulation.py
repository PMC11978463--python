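"""Circular-predictor model comparison: does respiratory phase predict behaviour?

For each lag on a 0.3 s grid the trial-wise phase enters a mixed model as a
sine/cosine pair (sqrt(RT): Gaussian; accuracy: logistic), alongside the
stimulus level and per-participant random intercepts and trial-number
slopes.  Evidence for a phase effect is the AIC difference between the full
model and a reduced model without the pair (positive = respiration model
favoured; an AIC difference of 9.2 corresponds to an Akaike weight above
0.99).  The rotation-invariant effect size is the vector strength
V = sqrt(beta_sin^2 + beta_cos^2), tested by shuffling the trial-phase
pairing within participant; p-values from several datasets combine via
Fisher's method.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import PhaseSampleMatrix, apply_trial_exclusions
from .mixedlm import MixedFit, fit_gaussian_lmm, fit_binomial_glmm
from .synth import trial_centred

__all__ = ["ModelSpec", "fit_model", "fit_full_reduced", "delta_aic",
           "akaike_weight", "LagScanResult", "lag_scan", "sum_lag_scans",
           "compare_lags", "vector_strength", "shuffle_test", "fisher_combine",
           "EVIDENCE_DAIC"]

#: AIC difference treated as evidence for a phase effect (Akaike weight > 0.99)
EVIDENCE_DAIC = 9.2


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, whether the sine/cosine pair is included, and
    the random-effects structure (the pair is always included or excluded
    together)."""

    outcome: str = "sqrt_rt"            # "sqrt_rt" | "correct"
    include_phase: bool = True
    re_structure: str = "intercept_slope"   # "intercept_slope" | "intercept"

    def __post_init__(self):
        if self.outcome not in ("sqrt_rt", "correct"):
            raise ValueError("outcome must be 'sqrt_rt' or 'correct'")
        if self.re_structure not in ("intercept_slope", "intercept"):
            raise ValueError("unknown random-effects structure")


def _design(trials: pd.DataFrame, phase: np.ndarray, spec: ModelSpec):
    lvl = trials["stim_level"].to_numpy(dtype=float)
    lvl_c = lvl - lvl.mean()
    n_max = int(trials["trial_nr"].max())
    tc = trial_centred(trials["trial_nr"].to_numpy(), n_max)
    cols = [np.ones(len(trials)), lvl_c]
    names = ["intercept", "stim_level"]
    if spec.include_phase:
        cols += [np.sin(phase), np.cos(phase)]
        names += ["resp_sin", "resp_cos"]
    X = np.column_stack(cols)
    if spec.re_structure == "intercept_slope":
        Z = np.column_stack([np.ones(len(trials)), tc])
    else:
        Z = np.ones((len(trials), 1))
    if spec.outcome == "sqrt_rt":
        y = np.sqrt(trials["rt_s"].to_numpy(dtype=float))
    else:
        y = trials["correct"].to_numpy(dtype=float)
    return y, X, Z, names


def fit_model(trials: pd.DataFrame, phase: np.ndarray | None,
              spec: ModelSpec, theta0: np.ndarray | None = None) -> MixedFit:
    """Fit one mixed model on retained trials.

    ``phase`` must be aligned with ``trials`` rows (ignored when the spec
    excludes the phase pair).  Degenerate outcomes (all identical) raise.
    """
    if spec.include_phase:
        if phase is None:
            raise ValueError("phase values required for the full model")
        phase = np.asarray(phase, dtype=float)
        if not np.all(np.isfinite(phase)):
            raise ValueError("undefined phases in the model data; exclude first")
    y, X, Z, names = _design(trials, phase, spec)
    if np.ptp(y) == 0:
        raise ValueError("degenerate outcome: all values identical")
    if trials["participant_id"].nunique() < 1:
        raise ValueError("no participants")
    groups = trials["participant_id"].to_numpy()
    if spec.outcome == "sqrt_rt":
        fit = fit_gaussian_lmm(y, X, groups, Z, names=names,
                               re_structure=spec.re_structure, theta0=theta0)
    else:
        fit = fit_binomial_glmm(y, X, groups, Z, names=names,
                                re_structure=spec.re_structure)
    fit.outcome = spec.outcome
    return fit


def fit_full_reduced(trials: pd.DataFrame, phase: np.ndarray,
                     outcome: str = "sqrt_rt") -> tuple[MixedFit, MixedFit]:
    """Fit the phase and no-phase models with a matched random-effects
    structure: if either fit fails to converge with the random trial-number
    slope, both are refitted with the random intercept only so the AIC
    difference stays comparable."""
    full = fit_model(trials, phase, ModelSpec(outcome, True))
    reduced = fit_model(trials, None, ModelSpec(outcome, False))
    if not (full.converged and reduced.converged):
        full = fit_model(trials, phase, ModelSpec(outcome, True, "intercept"))
        reduced = fit_model(trials, None, ModelSpec(outcome, False, "intercept"))
    return full, reduced


def delta_aic(full: MixedFit, reduced: MixedFit) -> tuple[float, float]:
    """AIC(reduced) - AIC(full) and the Akaike weight of the full model.

    Positive values favour the model with the respiratory predictors.  The
    two fits must be on identical data (same n_obs).
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits use different numbers of observations; "
                         "apply the same exclusions to both")
    d = reduced.aic - full.aic
    return float(d), akaike_weight(d)


def akaike_weight(d_aic: float) -> float:
    """Conditional probability of the full model given an AIC difference."""
    with np.errstate(over="ignore"):
        return float(1.0 / (1.0 + np.exp(-0.5 * d_aic)))


@dataclass
class LagScanResult:
    """Delta-AIC as a function of lag (positive favours the phase model)."""

    alignment: str
    outcome: str
    lags: np.ndarray
    delta_aic: np.ndarray
    akaike_weights: np.ndarray
    n_obs: np.ndarray
    beta_sin: np.ndarray
    beta_cos: np.ndarray
    skipped: list = field(default_factory=list)

    @property
    def peak_lag(self) -> float:
        ok = np.isfinite(self.delta_aic)
        if not ok.any():
            return float("nan")
        return float(self.lags[ok][np.argmax(self.delta_aic[ok])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alignment": self.alignment, "outcome": self.outcome,
            "lag_s": self.lags, "delta_aic": self.delta_aic,
            "akaike_weight": self.akaike_weights, "n_obs": self.n_obs,
            "beta_sin": self.beta_sin, "beta_cos": self.beta_cos,
        })


def lag_scan(trials: pd.DataFrame, phases: PhaseSampleMatrix,
             outcome: str = "sqrt_rt",
             lags: np.ndarray | None = None,
             common_trials: bool = True) -> LagScanResult:
    """Refit the full/reduced pair at every lag of the sampled grid.

    With ``common_trials`` (default) the scan keeps only trials whose
    phase is defined at every scanned lag (plus the usual RT/button
    rules), so the delta-AIC values are computed on identical data and are
    comparable across lags — the peak of the curve is then a valid
    cross-lag model comparison.  With ``common_trials=False`` exclusions
    are re-applied per lag (each lag keeps every trial usable at that
    lag); full and reduced models still always share the same trials.
    Lags where more than half the phases are undefined are skipped with a
    warning.
    """
    if lags is None:
        lags = phases.lags
    lags = np.asarray(lags, dtype=float)
    daic = np.full(lags.size, np.nan)
    wts = np.full(lags.size, np.nan)
    nobs = np.zeros(lags.size, dtype=int)
    bs = np.full(lags.size, np.nan)
    bc = np.full(lags.size, np.nan)
    skipped = [float(l) for l in lags if phases.defined_fraction(l) < 0.5]
    use = np.array([l not in skipped for l in lags])
    common_keep = None
    if common_trials:
        cols = [phases.lag_column(l) for l, u in zip(lags, use) if u]
        defined_all = np.all(np.isfinite(np.column_stack(cols)), axis=1)
        flagged = apply_trial_exclusions(trials, phases, lags[use][0])
        rt_ok = ~flagged["excluded"].to_numpy() | \
            (flagged["exclusion_reason"] == "PHASE_UNDEFINED").to_numpy()
        common_keep = defined_all & rt_ok
    for j, lag in enumerate(lags):
        if not use[j]:
            continue
        if common_trials:
            keep = common_keep
            sub = trials[keep]
        else:
            flagged = apply_trial_exclusions(trials, phases, lag)
            keep = ~flagged["excluded"].to_numpy()
            sub = flagged[keep]
        phi = phases.lag_column(lag)[keep]
        full, reduced = fit_full_reduced(sub, phi, outcome)
        daic[j], wts[j] = delta_aic(full, reduced)
        nobs[j] = full.n_obs
        bs[j] = full.coef("resp_sin")
        bc[j] = full.coef("resp_cos")
    if skipped:
        warnings.warn(f"lags skipped (>50% undefined phase): {skipped}",
                      RuntimeWarning)
    return LagScanResult(alignment=phases.alignment, outcome=outcome,
                         lags=lags, delta_aic=daic, akaike_weights=wts,
                         n_obs=nobs, beta_sin=bs, beta_cos=bc, skipped=skipped)


def sum_lag_scans(scans: list[LagScanResult]) -> LagScanResult:
    """Summed-across-datasets evidence curve (delta-AICs add)."""
    if not scans:
        raise ValueError("no scans to sum")
    lags = scans[0].lags
    for s in scans[1:]:
        if not np.allclose(s.lags, lags):
            raise ValueError("scans use different lag grids")
    total = np.nansum(np.vstack([s.delta_aic for s in scans]), axis=0)
    all_nan = np.all(np.vstack([~np.isfinite(s.delta_aic) for s in scans]), axis=0)
    total[all_nan] = np.nan
    return LagScanResult(alignment=scans[0].alignment, outcome=scans[0].outcome,
                         lags=lags, delta_aic=total,
                         akaike_weights=np.array([akaike_weight(d) for d in total]),
                         n_obs=np.sum([s.n_obs for s in scans], axis=0),
                         beta_sin=np.full(lags.size, np.nan),
                         beta_cos=np.full(lags.size, np.nan))


def compare_lags(trials: pd.DataFrame, phases: PhaseSampleMatrix,
                 lag_a: float, lag_b: float,
                 outcome: str = "sqrt_rt") -> tuple[float, float]:
    """AIC difference between the full models of two lags, on the common
    retained trial set (positive favours ``lag_a``)."""
    fa = apply_trial_exclusions(trials, phases, lag_a)
    fb = apply_trial_exclusions(trials, phases, lag_b)
    keep = ~(fa["excluded"].to_numpy() | fb["excluded"].to_numpy())
    sub = trials[keep]
    fit_a = fit_model(sub, phases.lag_column(lag_a)[keep], ModelSpec(outcome, True))
    fit_b = fit_model(sub, phases.lag_column(lag_b)[keep], ModelSpec(outcome, True))
    d = fit_b.aic - fit_a.aic
    return float(d), akaike_weight(d)


def vector_strength(fit: MixedFit) -> float:
    """Resultant amplitude of the sine/cosine coefficient pair.

    V = sqrt(beta_sin^2 + beta_cos^2) is invariant under rotation of the
    phase origin, making it a scale-free circular-linear effect size.
    """
    return float(np.hypot(fit.coef("resp_sin"), fit.coef("resp_cos")))


def shuffle_test(trials: pd.DataFrame, phase: np.ndarray,
                 outcome: str = "sqrt_rt", n_shuffles: int = 4000,
                 seed: int | None = 0) -> dict:
    """Permutation test of the vector strength.

    The trial-wise pairing of phase and behaviour is destroyed by permuting
    the phase values within each participant (preserving both marginals);
    the full model is refitted per shuffle and the add-one p-value is the
    rank of the observed V in the surrogate distribution.  Non-convergent
    surrogate fits are dropped and counted (warning above 10%).
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a p-value")
    phase = np.asarray(phase, dtype=float)
    rng = np.random.default_rng(seed)
    spec = ModelSpec(outcome, True)
    obs_fit = fit_model(trials, phase, spec)
    v_obs = vector_strength(obs_fit)

    pid = trials["participant_id"].to_numpy()
    blocks = [np.nonzero(pid == g)[0] for g in np.unique(pid)]
    v_surr = np.full(n_shuffles, np.nan)
    n_failed = 0
    for s in range(n_shuffles):
        perm = phase.copy()
        for m in blocks:
            perm[m] = phase[m[rng.permutation(m.size)]]
        try:
            # warm-started from the observed fit: the permuted design differs
            # only in the phase columns, so the covariance optimum is close
            fit = fit_model(trials, perm, spec, theta0=obs_fit.theta)
        except FloatingPointError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        v_surr[s] = vector_strength(fit)
    if n_failed > 0.1 * n_shuffles:
        warnings.warn(f"{n_failed}/{n_shuffles} surrogate fits failed",
                      RuntimeWarning)
    ok = np.isfinite(v_surr)
    p = (1 + np.sum(v_surr[ok] >= v_obs)) / (1 + int(ok.sum()))
    return {"p": float(p), "v_observed": v_obs, "v_surrogate": v_surr[ok],
            "n_failed": n_failed, "fit": obs_fit}


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: X = -2 sum(log p) ~ chi-square with 2k df.

    Returns (X, combined p).  Requires every p in (0, 1]; a permutation p
    of exactly zero indicates the add-one estimator was not used upstream.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]; use add-one "
                         "permutation p-values")
    x = -2.0 * np.sum(np.log(p))
    combined = float(stats.chi2.sf(x, df=2 * p.size))
    return float(x), combined
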
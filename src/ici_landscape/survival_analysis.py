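"""Kaplan-Meier/log-rank machinery, cutpoint dichotomization, Cox models,
nomogram and calibration.

lifelines provides the estimators (product-limit curve, log-rank test, Cox
partial likelihood with Efron ties); this module wraps them behind the
pipeline's contracts and adds the maximally-selected-cutpoint surrogate for
X-tile style dichotomization, backward-AIC stepwise selection, the nomogram
point mapping and calibration tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger("ici_landscape")


@dataclass
class SurvivalCurve:
    """Product-limit estimate: event times, at-risk counts, S(t)."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function; S(t)=1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxModel:
    coefficients: pd.Series
    standard_errors: pd.Series
    log_likelihood: float
    aic: float
    covariates: list
    baseline_survival: pd.Series  # S0(t) at the covariate means
    covariate_means: pd.Series


@dataclass
class NomogramSpec:
    """Value -> points mapping per covariate plus total-points -> S(t)."""

    coefficients: pd.Series
    reference: pd.Series  # covariate value worth 0 points
    ranges: pd.DataFrame  # min/max per covariate
    scale: float  # linear-predictor units per 100 points
    horizons_months: list
    baseline_at_horizons: dict  # horizon -> S0 at the reference covariates
    points: dict = field(default_factory=dict)

    def points_for(self, covariate: str, value: float) -> float:
        beta = self.coefficients[covariate]
        ref = self.reference[covariate]
        return 100.0 * abs(beta) * abs(value - ref) / self.scale if self.scale > 0 else 0.0

    def survival_for(self, total_points: float, horizon: float) -> float:
        s0 = self.baseline_at_horizons.get(horizon)
        if s0 is None or np.isnan(s0):
            return np.nan
        lp = self.scale * total_points / 100.0
        return float(s0 ** np.exp(lp))


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator (events precede censorings at tied times)."""
    times, events = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    ev = ev[ev.index > 0]
    surv = kmf.survival_function_["KM_estimate"]
    s_at = np.array([surv.loc[:t].iloc[-1] for t in ev.index])
    return SurvivalCurve(
        times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        survival=s_at,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Log-rank chi-square across >=2 non-empty groups; returns (chi2, df, p)."""
    times, events = _validate(times, events)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def optimal_cutpoint(
    score, times, events, bounds: tuple[float, float] = (0.1, 0.9)
) -> tuple[float, float]:
    """Maximally selected log-rank cut within the bounds-quantile window.

    Scans candidate cuts (midpoints of consecutive sorted unique scores
    between the quantile bounds) and returns the cut maximizing the log-rank
    chi-square (ties -> lower cut). The implied p-value is an uncorrected,
    maximally selected statistic and is flagged as such downstream.
    """
    score = np.asarray(score, dtype=float)
    times, events = _validate(times, events)
    if score.size < 10:
        raise ValueError("need at least 10 subjects for cutpoint selection")
    if np.unique(score).size == 1:
        raise ValueError("score is constant; no cutpoint exists")
    lo, hi = np.quantile(score, bounds)
    uniq = np.unique(score)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = mids[(mids >= lo) & (mids <= hi)]
    if cands.size == 0:
        cands = np.array([np.median(score)])
    best_cut, best_chi2 = None, -np.inf
    for cut in cands:
        grp = score > cut
        if grp.all() or (~grp).all():
            continue
        chi2, _, _ = logrank_test(times, events, grp.astype(int))
        if chi2 > best_chi2 + 1e-12:
            best_chi2, best_cut = chi2, float(cut)
    if best_cut is None:
        raise ValueError("no admissible cutpoint in the window")
    return best_cut, float(best_chi2)


def cox_fit(
    covariates: pd.DataFrame, times, events, stepwise: bool = False
) -> CoxModel:
    """Cox proportional hazards by partial likelihood (Efron ties).

    ``stepwise`` performs backward elimination by AIC, stopping when no
    single-covariate removal lowers the AIC.
    """
    times, events = _validate(times, events)
    if events.sum() == 0:
        raise ValueError("no events; the partial likelihood is undefined")
    if len(covariates) <= covariates.shape[1]:
        raise ValueError("need more subjects than covariates")

    def _fit(cols: list) -> tuple[CoxPHFitter, float]:
        df = covariates[cols].copy()
        df["T"], df["E"] = times, events
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        aic = -2.0 * cph.log_likelihood_ + 2.0 * len(cols)
        return cph, aic

    cols = list(covariates.columns)
    cph, aic = _fit(cols)
    if stepwise:
        improved = True
        while improved and len(cols) > 1:
            improved = False
            trials = []
            for drop in cols:
                reduced = [c for c in cols if c != drop]
                _, a = _fit(reduced)
                trials.append((a, reduced))
            best_a, best_cols = min(trials, key=lambda t: t[0])
            if best_a < aic:
                cols, aic = best_cols, best_a
                cph, _ = _fit(cols)
                improved = True

    base = cph.baseline_survival_["baseline survival"]
    return CoxModel(
        coefficients=cph.params_.copy(),
        standard_errors=cph.standard_errors_.copy(),
        log_likelihood=float(cph.log_likelihood_),
        aic=float(aic),
        covariates=cols,
        baseline_survival=base,
        covariate_means=covariates[cols].mean(),
    )


def _baseline_at(model: CoxModel, t: float) -> float:
    base = model.baseline_survival
    if t > base.index.max():
        return np.nan
    prior = base.loc[:t]
    return float(prior.iloc[-1]) if len(prior) else 1.0


def predict_survival(model: CoxModel, covariates: pd.DataFrame, horizon: float) -> pd.Series:
    """S(horizon | x) = S0(horizon)^exp(lp) with lp centered at the fit means."""
    s0 = _baseline_at(model, horizon)
    lp = (covariates[model.covariates] - model.covariate_means) @ model.coefficients
    if np.isnan(s0):
        return pd.Series(np.nan, index=covariates.index)
    return pd.Series(s0 ** np.exp(lp), index=covariates.index)


def build_nomogram(
    model: CoxModel,
    data: pd.DataFrame,
    horizons_years: tuple[float, ...] = (3.0, 5.0, 10.0),
) -> NomogramSpec:
    """Map covariate values to 0-100 points and total points to S(t).

    points_j(x) = 100*|beta_j|*(x - ref_j)/max_k(|beta_k|*range_k) with the
    reference chosen at the low-risk end, so the covariate with the largest
    |beta|*range spans exactly 0-100 points. Horizons beyond the observed
    follow-up yield NA survival.
    """
    if not model.covariates:
        raise ValueError("model has no covariates")
    ranges = data[model.covariates].agg(["min", "max"]).T
    spans = (ranges["max"] - ranges["min"]).abs()
    contrib = model.coefficients.abs() * spans
    scale = float(contrib.max())
    reference = pd.Series(
        {
            c: (ranges.loc[c, "min"] if model.coefficients[c] > 0 else ranges.loc[c, "max"])
            for c in model.covariates
        }
    )
    horizons_months = [h * 12.0 for h in horizons_years]
    lp_ref = float((reference - model.covariate_means) @ model.coefficients)
    baseline = {}
    for h in horizons_months:
        s0 = _baseline_at(model, h)
        baseline[h] = np.nan if np.isnan(s0) else float(s0 ** np.exp(lp_ref))
        if np.isnan(s0):
            logger.warning("horizon %.0f months beyond follow-up; survival is NA", h)
    return NomogramSpec(
        coefficients=model.coefficients.copy(),
        reference=reference,
        ranges=ranges,
        scale=scale,
        horizons_months=horizons_months,
        baseline_at_horizons=baseline,
    )


def calibration_curve(
    model: CoxModel,
    covariates: pd.DataFrame,
    times,
    events,
    horizon: float,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Predicted vs observed survival at ``horizon`` in predicted-risk bins.

    Samples are binned by predicted S(horizon) (quantile bins); observed is
    the KM estimate at the horizon within each bin (NA if the bin's
    follow-up cannot reach the horizon).
    """
    times, events = _validate(times, events)
    pred = predict_survival(model, covariates, horizon)
    if pred.isna().all():
        raise ValueError("horizon beyond observed follow-up")
    if n_bins == 1:
        bins = pd.Series(0, index=pred.index)
    else:
        bins = pd.Series(
            pd.qcut(pred.rank(method="first"), n_bins, labels=False), index=pred.index
        )
    rows = []
    for b in sorted(bins.unique()):
        mask = (bins == b).to_numpy()
        t_b, e_b = times[mask], events[mask]
        curve = km_estimate(t_b, e_b) if len(t_b) else None
        if curve is None or (t_b.max() < horizon and e_b.sum() == 0):
            obs = np.nan
        elif t_b.max() < horizon:
            obs = np.nan
        else:
            obs = curve.survival_at(horizon)
        rows.append(
            {
                "bin": int(b),
                "n": int(mask.sum()),
                "predicted_mean": float(pred[mask].mean()),
                "observed_km": obs,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(values, groups) -> tuple[float, float, str]:
    """Rank-sum comparison: Wilcoxon for 2 groups, Kruskal-Wallis for more."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(labels) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return float(stat), float(p), "wilcoxon"
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p), "kruskal-wallis"
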
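"""Survival analysis: KM, log-rank, Cox PH with DESNT as a continuous covariate,
bootstrap validation, calibration and nomogram construction.

The clinical endpoint is biochemical recurrence (PSA failure) after
prostatectomy, in months. The headline analysis shape is a Cox proportional
hazards model with the DESNT signature proportion entered as a continuous
covariate alongside Gleason category (<7 reference, 3+4, 4+3, >7),
log-scale PSA, pathological stage (T1-T2 vs T3-T4) and surgical margin
status. Partial likelihood uses Breslow tie handling; the baseline
cumulative hazard is the Breslow estimator centred at the covariate means,
so nomogram predictions are a pure re-parameterisation of the fitted model.

Kaplan-Meier, log-rank and Harrell's C are delegated to lifelines; the Cox
fit to statsmodels PHReg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

__all__ = [
    "kaplan_meier", "logrank_test", "build_design", "fit_cox", "CoxModel",
    "concordance_index", "bootstrap_validate", "calibration_at_horizon",
    "NomogramSpec", "build_nomogram",
]

GLEASON_LEVELS = ["lt7", "3+4", "4+3", "gt7"]
STAGE_LEVELS = ["T1-T2", "T3-T4"]
DEFAULT_HORIZONS = (12, 36, 60, 84)   # months: 1, 3, 5, 7 years


# ---------------------------------------------------------------------------
# non-parametric estimators
# ---------------------------------------------------------------------------

def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with right censoring.

    Returns a step-function table (time, survival, at_risk); S(0) = 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({"time": surv.index.to_numpy(),
                         "survival": surv.to_numpy(),
                         "at_risk": at_risk.to_numpy()})


def km_survival_at(times, events, horizon: float) -> float:
    """KM survival probability at a fixed horizon."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    return float(kmf.predict(horizon))


def logrank_test(times, events, groups):
    """Log-rank test across >= 2 groups: (chi2, df, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix with fixed reference levels.

    Categorical covariates are dummy-encoded against their first category
    (gleason: lt7; stage: T1-T2); numeric covariates pass through unchanged.
    """
    cols = {}
    for cov in covariates:
        s = df[cov]
        if cov == "gleason":
            s = pd.Categorical(s, categories=GLEASON_LEVELS)
        elif cov == "stage":
            s = pd.Categorical(s, categories=STAGE_LEVELS)
        if isinstance(s, pd.Categorical) or s.dtype == object \
                or isinstance(s.dtype, pd.CategoricalDtype):
            cat = s if isinstance(s, pd.Categorical) else pd.Categorical(s)
            for level in cat.categories[1:]:
                cols[f"{cov}[{level}]"] = (cat == level).astype(float)
        else:
            cols[cov] = pd.to_numeric(s).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    return X


@dataclass
class CoxModel:
    """Fitted Cox PH model (Breslow ties) with its Breslow baseline hazard."""

    covariate_names: list[str]
    coef: pd.Series                    # log hazard ratios
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    x_mean: pd.Series                  # centering point of the linear predictor
    baseline_times: np.ndarray         # event times (ascending)
    baseline_cumhaz: np.ndarray        # H0 at x_mean, non-decreasing
    training_c_index: float
    n: int
    n_events: int

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Centred linear predictor (x - x_mean) @ beta."""
        Xc = X[self.covariate_names].to_numpy(float) - self.x_mean.to_numpy()
        return Xc @ self.coef.to_numpy()

    def cumhaz_at(self, t: float) -> float:
        if t > self.baseline_times.max():
            raise ValueError(f"horizon {t} beyond last event time "
                             f"{self.baseline_times.max():.1f}")
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return float(self.baseline_cumhaz[idx]) if idx >= 0 else 0.0

    def predict_survival(self, X: pd.DataFrame, t: float) -> np.ndarray:
        """S(t | x) = exp(-H0(t) * exp(lp(x))) with lp centred at x_mean."""
        return np.exp(-self.cumhaz_at(t) * np.exp(self.linear_predictor(X)))

    def summary(self) -> str:
        lines = ["Cox proportional hazards (Breslow ties)",
                 "=" * 64,
                 f"n = {self.n}, events = {self.n_events}, "
                 f"training C-index = {self.training_c_index:.3f}",
                 "",
                 f"{'covariate':<18}{'coef':>9}{'HR':>8}{'95% CI':>18}{'p':>12}"]
        for name in self.covariate_names:
            lines.append(
                f"{name:<18}{self.coef[name]:>9.3f}{self.hr[name]:>8.3f}"
                f"  [{self.ci_lower[name]:.2f}, {self.ci_upper[name]:.2f}]"
                f"{self.p_values[name]:>12.2e}")
        return "\n".join(lines)


def _breslow_baseline(times, events, lp):
    """Breslow cumulative hazard at the centering point of ``lp``."""
    order = np.argsort(times, kind="stable")
    t, d, r = times[order], events[order], np.exp(lp[order])
    # risk-set denominators: cumulative sum of exp(lp) from the end
    denom = np.cumsum(r[::-1])[::-1]
    event_times = np.unique(t[d == 1])
    cumhaz = np.empty(event_times.size)
    h = 0.0
    for i, et in enumerate(event_times):
        at = t == et
        d_i = int(d[at].sum())
        first = np.searchsorted(t, et, side="left")
        h += d_i / denom[first]
        cumhaz[i] = h
    return event_times, cumhaz


def fit_cox(df: pd.DataFrame, covariates, duration_col: str = "time",
            event_col: str = "event", impute: bool = False) -> CoxModel:
    """Fit a Cox PH model by Newton-Raphson on the Breslow partial likelihood.

    ``covariates`` may mix continuous columns (e.g. desnt proportion, PSA)
    and categoricals (gleason, stage); encodings are fixed by
    :func:`build_design`. Missing covariate rows are dropped (complete-case)
    unless ``impute`` is set, which fills numeric medians / categorical modes
    (warned).
    """
    import statsmodels.duration.hazard_regression as hzr
    work = df[[duration_col, event_col, *covariates]].copy()
    if work.isna().to_numpy().any():
        if impute:
            for c in covariates:
                if work[c].dtype.kind in "fiu":
                    fill = work[c].median()
                else:
                    fill = work[c].mode().iloc[0]
                n_filled = int(work[c].isna().sum())
                if n_filled:
                    warnings.warn(f"imputed {n_filled} missing '{c}' values with {fill!r}")
                work[c] = work[c].fillna(fill)
        else:
            n_drop = int(work.isna().any(axis=1).sum())
            warnings.warn(f"dropped {n_drop} incomplete case(s)")
            work = work.dropna()
    X = build_design(work, covariates)
    if (X.nunique() <= 1).any():
        bad = X.columns[(X.nunique() <= 1)].tolist()
        raise ValueError(f"constant covariate column(s): {bad}")
    times = work[duration_col].to_numpy(float)
    events = work[event_col].to_numpy(int)
    if events.sum() < X.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    model = hzr.PHReg(times, X.to_numpy(float), status=events, ties="breslow")
    try:
        res = model.fit(disp=False)
    except Exception as exc:
        raise RuntimeError(f"Cox fit failed (separation or non-convergence): {exc}")
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 50):
        raise RuntimeError("Cox fit diverged (monotone likelihood / separation)")
    names = list(X.columns)
    coef = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    ci_l = coef - 1.959963984540054 * se
    ci_u = coef + 1.959963984540054 * se
    x_mean = X.mean()
    lp = (X.to_numpy(float) - x_mean.to_numpy()) @ coef.to_numpy()
    bt, bh = _breslow_baseline(times, events, lp)
    cindex = concordance_index(lp, times, events)
    return CoxModel(
        covariate_names=names, coef=coef, se=se,
        hr=np.exp(coef), ci_lower=np.exp(ci_l), ci_upper=np.exp(ci_u),
        p_values=pd.Series(res.pvalues, index=names),
        x_mean=x_mean, baseline_times=bt, baseline_cumhaz=bh,
        training_c_index=cindex, n=len(work), n_events=int(events.sum()),
    )


def concordance_index(risk_scores, times, events) -> float:
    """Harrell's C over comparable pairs; predictor ties count 0.5."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk_scores, float)
    if events.sum() == 0:
        raise ValueError("no events: no comparable pairs")
    # lifelines scores 'predicted survival time': higher = longer survival
    return float(_lifelines_cindex(times, -risk, events))


def bootstrap_validate(df: pd.DataFrame, covariates, B: int = 1000,
                       duration_col: str = "time", event_col: str = "event",
                       seed: int = 0) -> dict:
    """Harrell optimism-corrected C-index by bootstrap.

    For each resample: refit, score C on the resample (apparent) and on the
    original data; optimism = mean difference; corrected C = apparent C on
    the full data minus mean optimism. Resamples without events (or failing
    to fit) are skipped and logged.
    """
    rng = np.random.default_rng(seed)
    full = fit_cox(df, covariates, duration_col, event_col)
    X_full = build_design(df, covariates)
    t_full = df[duration_col].to_numpy(float)
    e_full = df[event_col].to_numpy(int)
    apparent = full.training_c_index
    optimisms = []
    skipped = 0
    n = len(df)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        if boot[event_col].sum() == 0:
            skipped += 1
            continue
        try:
            m = fit_cox(boot, covariates, duration_col, event_col)
        except (RuntimeError, ValueError):
            skipped += 1
            continue
        c_boot = m.training_c_index
        lp_orig = (X_full[m.covariate_names].to_numpy(float)
                   - m.x_mean.to_numpy()) @ m.coef.to_numpy()
        c_orig = concordance_index(lp_orig, t_full, e_full)
        optimisms.append(c_boot - c_orig)
    if skipped:
        warnings.warn(f"skipped {skipped}/{B} bootstrap resample(s)")
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return {"apparent_c": apparent, "optimism": optimism,
            "corrected_c": apparent - optimism,
            "n_resamples_used": len(optimisms)}


def calibration_at_horizon(model: CoxModel, df: pd.DataFrame, covariates,
                           horizon: float = 60.0, n_bins: int = 10,
                           duration_col: str = "time",
                           event_col: str = "event") -> pd.DataFrame:
    """Predicted vs KM-observed survival at a horizon, by deciles of prediction.

    Mirrors 5-year (60-month) calibration of the recurrence model: samples
    are binned by predicted S(horizon); each bin reports the mean prediction
    and the bin's KM estimate at the horizon. Bins with nobody at risk at the
    horizon are flagged with NaN observation.
    """
    times = df[duration_col].to_numpy(float)
    if horizon > times.max():
        raise ValueError(f"horizon {horizon} beyond observed time range")
    X = build_design(df, covariates)
    pred = model.predict_survival(X, horizon)
    events = df[event_col].to_numpy(int)
    # quantile bins; duplicate edges collapse when predictions tie
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_bins + 1)))
    bin_of = np.clip(np.searchsorted(edges, pred, side="right") - 1,
                     0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        inb = bin_of == b
        if not inb.any():
            continue
        at_risk_at_t = ((times[inb] >= horizon) | (events[inb] == 1)).sum()
        obs = km_survival_at(times[inb], events[inb], horizon) \
            if at_risk_at_t > 0 else np.nan
        rows.append({"bin": b + 1, "n": int(inb.sum()),
                     "mean_predicted": float(pred[inb].mean()),
                     "km_observed": obs})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramSpec:
    """Point-scale re-parameterisation of a Cox model.

    Each covariate value maps to 0-100 points relative to its least-risk
    reference value; the covariate with the largest |beta x range| spans
    exactly 0-100. Total points map back to the linear predictor and then to
    survival probabilities at the requested horizons.
    """

    covariate_points: dict            # name -> (values, points) arrays
    reference_values: dict            # name -> least-risk value
    scale: float                      # lp units per 100 points
    lp_at_reference: float            # centred lp of the all-reference profile
    horizons: tuple
    survival_tables: dict = field(default_factory=dict)  # horizon -> DataFrame
    _model: CoxModel | None = None

    def points_for(self, name: str, value: float) -> float:
        vals, pts = self.covariate_points[name]
        return float(np.interp(value, vals, pts))

    def total_points(self, profile: dict) -> float:
        return float(sum(self.points_for(name, v) for name, v in profile.items()))

    def lp_from_points(self, total_points: float) -> float:
        return self.lp_at_reference + total_points * self.scale / 100.0

    def survival_from_points(self, total_points: float, horizon: float) -> float:
        if self._model is None:
            raise ValueError("nomogram is detached from its Cox model")
        h0 = self._model.cumhaz_at(horizon)
        return float(np.exp(-h0 * np.exp(self.lp_from_points(total_points))))

    def to_text(self) -> str:
        lines = ["Nomogram point scales", "=" * 48]
        for name, (vals, pts) in self.covariate_points.items():
            entries = ", ".join(f"{v:g} -> {p:.1f}" for v, p in zip(vals, pts))
            lines.append(f"{name}: {entries}")
        lines.append("")
        for h, table in self.survival_tables.items():
            lines.append(f"Survival at {h} months (total points -> S):")
            for _, row in table.iterrows():
                lines.append(f"  {row['total_points']:7.1f} -> {row['survival']:.3f}")
        return "\n".join(lines)


def build_nomogram(model: CoxModel, covariate_ranges: dict,
                   horizons=DEFAULT_HORIZONS, n_grid: int = 9) -> NomogramSpec:
    """Construct a nomogram from a fitted Cox model.

    ``covariate_ranges``: design-column name -> (min, max) observed value
    range (binary dummies: (0, 1)). Points for covariate j at value x are
    ``100 * beta_j (x - x_ref_j) / max_j' |beta_j' range_j'|`` with x_ref the
    least-risk end of the range, so all points are non-negative and the
    largest-effect covariate spans exactly 0-100.
    """
    missing = [c for c in model.covariate_names if c not in covariate_ranges]
    if missing:
        raise ValueError(f"no range supplied for covariate(s) {missing}")
    for h in horizons:
        model.cumhaz_at(h)   # raises if beyond baseline support
    spans = {c: abs(model.coef[c]) * (covariate_ranges[c][1] - covariate_ranges[c][0])
             for c in model.covariate_names}
    max_span = max(spans.values())
    if max_span <= 0:
        raise ValueError("all covariates have zero effect range")
    cov_points, refs = {}, {}
    for c in model.covariate_names:
        lo, hi = covariate_ranges[c]
        beta = model.coef[c]
        ref = lo if beta >= 0 else hi   # least-risk end
        vals = np.linspace(lo, hi, n_grid)
        pts = 100.0 * beta * (vals - ref) / max_span
        order = np.argsort(vals)
        cov_points[c] = (vals[order], pts[order])
        refs[c] = float(ref)
    # centred lp of the all-reference profile
    lp_ref = float(sum(model.coef[c] * (refs[c] - model.x_mean[c])
                       for c in model.covariate_names))
    spec = NomogramSpec(covariate_points=cov_points, reference_values=refs,
                        scale=max_span, lp_at_reference=lp_ref,
                        horizons=tuple(horizons), _model=model)
    total_max = sum(max(p.max(), 0.0) for _, p in cov_points.values())
    grid = np.linspace(0, total_max, 25)
    for h in horizons:
        spec.survival_tables[h] = pd.DataFrame({
            "total_points": grid,
            "survival": [spec.survival_from_points(tp, h) for tp in grid],
        })
    return spec
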
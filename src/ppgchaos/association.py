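"""Association between complexity features and hemodynamics.

Intrasubject Pearson correlations across analysis windows, empirical
sensitivity slopes (the regression counterpart of dFeature/dSBP evaluated
per subject and conditioned on the hemodynamic fluctuation sigma), median
splits with Wilcoxon rank-sum comparison, bidirectional Granger-causality
classification (unidirectional either way / bidirectional feedback / none),
and cohort-level median +/- STD summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr, ranksums

__all__ = [
    "CorrResult",
    "SensitivityResult",
    "GrangerVerdict",
    "GRANGER_CATEGORIES",
    "intrasubject_corr",
    "sensitivity_slope",
    "fluctuation_split",
    "granger_classify",
    "cohort_summary",
]

GRANGER_CATEGORIES = (
    "UNI_HEMO_TO_FEATURE",
    "UNI_FEATURE_TO_HEMO",
    "BIDIRECTIONAL",
    "NONE",
)

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_LAG_S = 50.0


@dataclass
class CorrResult:
    subject_id: str
    feature: str
    hemo: str
    r: float
    p: float
    n_windows: int


@dataclass
class SensitivityResult:
    subject_id: str
    feature: str
    target: str
    slope: float
    stderr: float
    n_windows: int
    sigma: dict = field(default_factory=dict)


@dataclass
class GrangerVerdict:
    subject_id: str
    hemo: str
    feature: str
    p_hemo_to_feature: float
    p_feature_to_hemo: float
    lags: int
    category: str
    degenerate: bool = False


def _paired(a, b, min_n):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must be paired (equal length)")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} paired windows, got {len(a)}")
    return a, b


def intrasubject_corr(
    feature: np.ndarray,
    hemo: np.ndarray,
    subject_id: str = "",
    feature_name: str = "feature",
    hemo_name: str = "hemo",
    min_windows: int = 10,
) -> CorrResult:
    """Pearson r between per-window feature and hemodynamic series, with the
    two-sided t-distribution p-value; missing pairs dropped pairwise."""
    f, h = _paired(feature, hemo, min_windows)
    if f.std() == 0 or h.std() == 0:
        return CorrResult(subject_id, feature_name, hemo_name, np.nan, np.nan, len(f))
    r, p = pearsonr(f, h)
    return CorrResult(subject_id, feature_name, hemo_name, float(r), float(p), len(f))


def sensitivity_slope(
    feature: np.ndarray,
    target: np.ndarray,
    subject_id: str = "",
    feature_name: str = "feature",
    target_name: str = "target",
    sigma: dict | None = None,
    min_windows: int = 20,
) -> SensitivityResult:
    """Within-subject OLS slope of feature on a hemodynamic target across
    windows — the empirical sensitivity dFeature/dTarget — annotated with
    the subject's fluctuation sigmas."""
    f, t = _paired(feature, target, min_windows)
    if t.std() == 0:
        return SensitivityResult(subject_id, feature_name, target_name,
                                 np.nan, np.nan, len(f), sigma or {})
    res = linregress(t, f)
    return SensitivityResult(
        subject_id, feature_name, target_name,
        float(res.slope), float(res.stderr), len(f), sigma or {},
    )


def fluctuation_split(
    values: np.ndarray,
    sigma_co: np.ndarray,
    alternative: str = "two-sided",
) -> dict:
    """Median split of subjects by sigma_CO into low/high fluctuation groups
    (ties to the low group) with a Wilcoxon rank-sum comparison of ``values``.

    Returns group medians, group sizes and the rank-sum p-value.
    """
    values = np.asarray(values, dtype=float)
    sigma_co = np.asarray(sigma_co, dtype=float)
    if len(values) != len(sigma_co):
        raise ValueError("values and sigma_co must be paired")
    ok = np.isfinite(values) & np.isfinite(sigma_co)
    values, sigma_co = values[ok], sigma_co[ok]
    if len(values) < 6:
        raise ValueError("need at least 6 subjects")
    med = np.median(sigma_co)
    if np.all(sigma_co == sigma_co[0]):
        raise ValueError("all sigma values identical; cannot split")
    low = sigma_co <= med
    high = ~low
    if high.sum() == 0:  # heavy ties at the median
        raise ValueError("median split degenerate (all subjects tied low)")
    stat, p = ranksums(values[low], values[high], alternative=alternative)
    return {
        "sigma_median": float(med),
        "median_low": float(np.median(values[low])),
        "median_high": float(np.median(values[high])),
        "n_low": int(low.sum()),
        "n_high": int(high.sum()),
        "statistic": float(stat),
        "p": float(p),
    }


def _adf_p(x: np.ndarray) -> float:
    from statsmodels.tsa.stattools import adfuller

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(adfuller(x, autolag="AIC")[1])


def _granger_p(caused: np.ndarray, causing: np.ndarray, lag: int) -> float:
    from statsmodels.tsa.stattools import grangercausalitytests

    import contextlib
    import io

    data = np.column_stack([caused, causing])
    with warnings.catch_warnings(), contextlib.redirect_stdout(io.StringIO()):
        warnings.simplefilter("ignore")
        res = grangercausalitytests(data, maxlag=[lag])
    return float(res[lag][0]["ssr_ftest"][1])


def granger_classify(
    hemo: np.ndarray,
    feature: np.ndarray,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    hop_s: float = 5.0,
    alpha: float = DEFAULT_ALPHA,
    subject_id: str = "",
    hemo_name: str = "hemo",
    feature_name: str = "feature",
    min_windows: int = 100,
    lag_select: str = "fixed",
) -> GrangerVerdict:
    """Bidirectional Granger F-tests on per-window series and the four-way
    causal category.

    Lag cap = max_lag_s / hop_s (10 at the 5 s hop).  By default both F-tests
    use the full cap (``lag_select="fixed"``), which avoids post-selection
    bias; ``lag_select`` may instead name a VAR information criterion
    ("aic", "bic", "hqic") to reduce the order.  Both series are
    first-differenced when an augmented Dickey-Fuller check fails to reject
    a unit root in either.  Category: both p < alpha -> BIDIRECTIONAL;
    exactly one -> the corresponding unidirectional label; neither -> NONE.
    """
    x, y = _paired(hemo, feature, min_windows)
    if x.std() == 0 or y.std() == 0:
        return GrangerVerdict(subject_id, hemo_name, feature_name,
                              np.nan, np.nan, 0, "NONE", degenerate=True)
    if max(_adf_p(x), _adf_p(y)) > 0.05:
        x, y = np.diff(x), np.diff(y)
        if x.std() == 0 or y.std() == 0:
            return GrangerVerdict(subject_id, hemo_name, feature_name,
                                  np.nan, np.nan, 0, "NONE", degenerate=True)
    cap = max(int(round(max_lag_s / hop_s)), 1)
    cap = min(cap, (len(x) - 10) // 3)
    if lag_select == "fixed":
        lag = cap
    else:
        from statsmodels.tsa.api import VAR

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                order = getattr(
                    VAR(np.column_stack([x, y])).select_order(cap), lag_select)
            except Exception:
                order = 1
        lag = int(np.clip(order, 1, cap))
    try:
        p_xy = _granger_p(y, x, lag)  # hemo -> feature
        p_yx = _granger_p(x, y, lag)  # feature -> hemo
    except Exception:
        return GrangerVerdict(subject_id, hemo_name, feature_name,
                              np.nan, np.nan, lag, "NONE", degenerate=True)
    sig_xy, sig_yx = p_xy < alpha, p_yx < alpha
    if sig_xy and sig_yx:
        cat = "BIDIRECTIONAL"
    elif sig_xy:
        cat = "UNI_HEMO_TO_FEATURE"
    elif sig_yx:
        cat = "UNI_FEATURE_TO_HEMO"
    else:
        cat = "NONE"
    return GrangerVerdict(subject_id, hemo_name, feature_name,
                          p_xy, p_yx, lag, cat)


def cohort_summary(
    results: pd.DataFrame,
    value_col: str = "r",
    group_col: str | None = None,
    category_col: str | None = None,
) -> dict:
    """Cohort summaries: median +/- STD of a per-subject statistic, optional
    two-group Wilcoxon rank-sum comparison, and causal-category counts."""
    if len(results) < 3:
        raise ValueError("need at least 3 subjects")
    out: dict = {}
    vals = results[value_col].astype(float)
    out["median"] = float(np.nanmedian(vals))
    out["std"] = float(np.nanstd(vals, ddof=1))
    out["n"] = int(vals.notna().sum())
    if group_col is not None:
        groups = results[group_col].dropna().unique()
        if len(groups) == 2:
            a = vals[results[group_col] == groups[0]].dropna()
            b = vals[results[group_col] == groups[1]].dropna()
            stat, p = ranksums(a, b)
            out["groups"] = {
                str(groups[0]): {"median": float(a.median()), "n": len(a)},
                str(groups[1]): {"median": float(b.median()), "n": len(b)},
                "p": float(p),
            }
    if category_col is not None:
        counts = results[category_col].value_counts()
        out["category_counts"] = {c: int(counts.get(c, 0)) for c in GRANGER_CATEGORIES}
    return out
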
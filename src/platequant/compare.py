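"""Statistical comparison of a candidate method against a reference method.

Given paired results (one mean ± SD per sample and method), four standard
method-validation analyses are provided:

* OLS regression of the reference results on the candidate results, with
  marginal 95 % confidence intervals for slope and intercept and the joint
  confidence ellipse

      (beta - b)' X'X (beta - b) <= 2 s² F(alpha; 2, n-2),

  whose membership test for the ideal point (intercept 0, slope 1) asks
  whether the two methods are statistically interchangeable;
* a paired Student t test on the per-sample differences (accuracy);
* an F test on the pooled replicate variances (precision), with pooled
  variance per method the mean of the per-sample squared SDs and degrees
  of freedom (n_samples − 1, n_samples − 1) by default;
* relative-error summaries against the reference and against declared
  label values, with inclusive band membership.

All critical values are computed from scipy.stats quantiles at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAIRS_COLUMNS",
    "MethodComparisonResult",
    "PairedTResult",
    "VarianceFResult",
    "fit_comparison",
    "paired_t",
    "variance_f",
    "error_summary",
    "compare_methods",
    "plot_joint_ellipse",
]

PAIRS_COLUMNS = [
    "sample_id",
    "candidate_mean",
    "candidate_sd",
    "reference_mean",
    "reference_sd",
    "label",
]


def _validate_pairs(pairs: pd.DataFrame, need_sd: bool = False) -> pd.DataFrame:
    required = ["sample_id", "candidate_mean", "reference_mean"]
    if need_sd:
        required += ["candidate_sd", "reference_sd"]
    missing = [c for c in required if c not in pairs.columns]
    if missing:
        raise ValueError(f"paired table missing columns: {missing}")
    return pairs


@dataclass(frozen=True)
class MethodComparisonResult:
    slope: float
    intercept: float
    ci_slope_halfwidth: float  # marginal 95 % half-widths
    ci_intercept_halfwidth: float
    xtx: np.ndarray  # 2x2 normal-equation matrix of [1, candidate]
    s2: float  # residual mean square, df n-2
    ellipse_bound: float  # 2 s² F(alpha; 2, n-2)
    ideal_point_inside: bool
    n: int
    alpha: float

    def ellipse_quadform(self, intercept: float, slope: float) -> float:
        """(beta − b)' X'X (beta − b) for a candidate (intercept, slope)."""
        d = np.array([intercept - self.intercept, slope - self.slope])
        return float(d @ self.xtx @ d)

    def contains(self, intercept: float, slope: float) -> bool:
        return bool(self.ellipse_quadform(intercept, slope) <= self.ellipse_bound)


@dataclass(frozen=True)
class PairedTResult:
    t_calc: float
    t_crit: float
    df: int
    significant: bool
    mean_difference: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class VarianceFResult:
    f_calc: float
    f_crit: float
    df: tuple[int, int]
    significant: bool
    pooled_var_candidate: float
    pooled_var_reference: float


def fit_comparison(pairs: pd.DataFrame, alpha: float = 0.05) -> MethodComparisonResult:
    """OLS of reference on candidate with marginal CIs and joint ellipse.

    The candidate method sits on the abscissa, the reference on the
    ordinate.  Requires >= 3 pairs and non-degenerate candidate variance.
    """
    pairs = _validate_pairs(pairs)
    x = pairs["candidate_mean"].to_numpy(dtype=float)
    y = pairs["reference_mean"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"regression comparison needs >= 3 pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("candidate results have zero variance")
    res = stats.linregress(x, y)
    b = np.array([res.intercept, res.slope])
    X = np.column_stack([np.ones(n), x])
    resid = y - X @ b
    s2 = float(resid @ resid) / (n - 2)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    fcrit = stats.f.ppf(1 - alpha, 2, n - 2)
    bound = float(2.0 * s2 * fcrit)
    result = MethodComparisonResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_slope_halfwidth=float(tcrit * res.stderr),
        ci_intercept_halfwidth=float(tcrit * res.intercept_stderr),
        xtx=X.T @ X,
        s2=s2,
        ellipse_bound=bound,
        ideal_point_inside=False,  # placeholder, replaced below
        n=n,
        alpha=alpha,
    )
    object.__setattr__(result, "ideal_point_inside", bool(result.contains(0.0, 1.0)))
    return result


def paired_t(pairs: pd.DataFrame, alpha: float = 0.05) -> PairedTResult:
    """Paired Student t test of candidate vs reference means.

    t_calc = |mean d| / (SD(d)/sqrt(n)) on the per-sample differences
    d = candidate − reference, df = n − 1, two-sided critical value.
    """
    pairs = _validate_pairs(pairs)
    d = (
        pairs["candidate_mean"].to_numpy(dtype=float)
        - pairs["reference_mean"].to_numpy(dtype=float)
    )
    n = len(d)
    if n < 2:
        raise ValueError(f"paired t test needs >= 2 pairs, got {n}")
    sd = d.std(ddof=1)
    flags: tuple[str, ...] = ()
    if sd == 0:
        if d.mean() == 0:
            t_calc = 0.0
        else:
            t_calc = float("inf")
            flags = ("zero_variance_nonzero_mean",)
    else:
        t_calc = abs(d.mean()) / (sd / np.sqrt(n))
    t_crit = float(stats.t.ppf(1 - alpha / 2, n - 1))
    return PairedTResult(
        t_calc=float(t_calc),
        t_crit=t_crit,
        df=n - 1,
        significant=bool(t_calc > t_crit),
        mean_difference=float(d.mean()),
        flags=flags,
    )


def variance_f(
    pairs: pd.DataFrame, alpha: float = 0.05, df_mode: str = "samples"
) -> VarianceFResult:
    """F test on pooled replicate variances of the two methods.

    The pooled variance per method is the mean of the per-sample squared
    SDs; F_calc is larger/smaller.  ``df_mode="samples"`` (default) uses
    (n_samples − 1, n_samples − 1); ``"replicates"`` uses n_samples·(r − 1)
    per method for r replicates per sample (pass r via a ``replicates``
    column, default 3).  The critical value is the one-tailed upper-alpha
    F quantile.
    """
    pairs = _validate_pairs(pairs, need_sd=True)
    sd_c = pairs["candidate_sd"].to_numpy(dtype=float)
    sd_r = pairs["reference_sd"].to_numpy(dtype=float)
    n = len(sd_c)
    if n < 2:
        raise ValueError(f"variance comparison needs >= 2 samples, got {n}")
    var_c = float(np.mean(sd_c**2))
    var_r = float(np.mean(sd_r**2))
    if min(var_c, var_r) == 0:
        raise ZeroDivisionError("zero pooled variance in the denominator")
    if df_mode == "samples":
        df = (n - 1, n - 1)
    elif df_mode == "replicates":
        r = (
            pairs["replicates"].to_numpy(dtype=int)
            if "replicates" in pairs.columns
            else np.full(n, 3)
        )
        df_each = int(np.sum(r - 1))
        df = (df_each, df_each)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    f_calc = max(var_c, var_r) / min(var_c, var_r)
    f_crit = float(stats.f.ppf(1 - alpha, *df))
    return VarianceFResult(
        f_calc=float(f_calc),
        f_crit=f_crit,
        df=df,
        significant=f_calc > f_crit,
        pooled_var_candidate=var_c,
        pooled_var_reference=var_r,
    )


def error_summary(
    pairs: pd.DataFrame, band: tuple[float, float] = (0.0, 6.0)
) -> tuple[pd.DataFrame, dict]:
    """Per-sample relative errors vs reference and label, with aggregates.

    Returns a per-sample table with ``rel_err_vs_reference_pct`` and, where
    a label exists, ``rel_err_vs_label_pct``, plus an aggregate dict with
    mean/min/max of each error and the share of labelled samples whose
    label error falls inside ``band`` (inclusive bounds).  Samples with a
    zero reference are skipped from the reference errors and flagged.
    """
    pairs = _validate_pairs(pairs)
    rows = []
    for _, rec in pairs.iterrows():
        cand, ref = float(rec["candidate_mean"]), float(rec["reference_mean"])
        label = rec.get("label")
        label = None if label is None or pd.isna(label) else float(label)
        flags = []
        if ref == 0:
            err_ref = np.nan
            flags.append("zero_reference")
        else:
            err_ref = 100.0 * abs(cand - ref) / ref
        err_label = (
            100.0 * abs(cand - label) / label if label not in (None, 0) else np.nan
        )
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "rel_err_vs_reference_pct": err_ref,
                "rel_err_vs_label_pct": err_label,
                "flags": ";".join(flags),
            }
        )
    table = pd.DataFrame(rows)
    ref_errs = table["rel_err_vs_reference_pct"].dropna()
    lab_errs = table["rel_err_vs_label_pct"].dropna()
    lo, hi = band
    summary = {
        "n_samples": len(table),
        "mean_rel_err_vs_reference_pct": float(ref_errs.mean()) if len(ref_errs) else None,
        "min_rel_err_vs_reference_pct": float(ref_errs.min()) if len(ref_errs) else None,
        "max_rel_err_vs_reference_pct": float(ref_errs.max()) if len(ref_errs) else None,
        "n_labelled": int(len(lab_errs)),
        "mean_rel_err_vs_label_pct": float(lab_errs.mean()) if len(lab_errs) else None,
        "max_rel_err_vs_label_pct": float(lab_errs.max()) if len(lab_errs) else None,
        "share_label_err_in_band_pct": (
            100.0 * float(((lab_errs >= lo) & (lab_errs <= hi)).mean())
            if len(lab_errs)
            else None
        ),
        "band_pct": [lo, hi],
    }
    return table, summary


def compare_methods(pairs: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full comparison battery and return a JSON-serializable report.

    Rows are sorted by sample id first so the report is invariant to the
    input row order (floating-point sums are order-sensitive).
    """
    pairs = pairs.sort_values("sample_id", kind="stable").reset_index(drop=True)
    reg = fit_comparison(pairs, alpha=alpha)
    t_res = paired_t(pairs, alpha=alpha)
    f_res = variance_f(pairs, alpha=alpha)
    _, errs = error_summary(pairs)
    return {
        "n_pairs": reg.n,
        "alpha": alpha,
        "regression": {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "ci_slope_halfwidth": reg.ci_slope_halfwidth,
            "ci_intercept_halfwidth": reg.ci_intercept_halfwidth,
            "ellipse_bound": reg.ellipse_bound,
            "ideal_point_quadform": reg.ellipse_quadform(0.0, 1.0),
            "ideal_point_inside": reg.ideal_point_inside,
        },
        "paired_t": {
            "t_calc": t_res.t_calc,
            "t_crit": t_res.t_crit,
            "df": t_res.df,
            "significant_difference": t_res.significant,
        },
        "variance_f": {
            "f_calc": f_res.f_calc,
            "f_crit": f_res.f_crit,
            "df": list(f_res.df),
            "significant_difference": f_res.significant,
        },
        "errors": errs,
    }


def plot_joint_ellipse(result: MethodComparisonResult, path) -> None:
    """Plot the joint confidence ellipse with the ideal point marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # eigen-decomposition of the quadratic form gives the ellipse axes
    evals, evecs = np.linalg.eigh(result.xtx / result.ellipse_bound)
    theta = np.linspace(0, 2 * np.pi, 400)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    pts = evecs @ (circle / np.sqrt(evals)[:, None])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.intercept + pts[0], result.slope + pts[1], label="joint 95% region")
    ax.plot([result.intercept], [result.slope], "o", label="fit")
    ax.plot([0], [1], "r*", markersize=12, label="ideal (0, 1)")
    ax.set_xlabel("intercept")
    ax.set_ylabel("slope")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
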
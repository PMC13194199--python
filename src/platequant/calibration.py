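"""Calibration, figures of merit, time selection and inverse prediction.

The calibration is an ordinary least-squares line of the analytical signal
S on concentration (% w/v), with the blank excluded by default: the blank
is chromatically different from the analyte complex (yellow vs orange), so
its blue-channel signal is not an additive zero point and including it
degrades linearity.  Figures of merit follow the standard regression-based
definitions::

    S_r = sqrt(SSE / (n - 2))        standard error of the regression
    LOD = 3.3 S_r / m                limit of detection, % w/v
    LOQ = 10  S_r / m                limit of quantification, % w/v

so LOQ/LOD is exactly 10/3.3 by construction.

Reaction-time selection: calibrations are refit at each acquisition time;
slopes rise and saturate as colour develops.  The chosen time is the
earliest at which the *remaining* slope gain is below one third of the
total gain (strict inequality), which under first-order kinetics with
k = ln(3)/90 per minute and 15-minute sampling selects 90 minutes.
A per-interval increment variant is available via ``mode="interval"``.

Inverse prediction maps a sample signal back through the line to a well
concentration, then through the declared preparation chain to product
content in % w/w; results outside the calibrated span or below the LOQ are
flagged, never censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plate import PrepChain

__all__ = [
    "CalibrationModel",
    "TimeCourse",
    "PrecisionReport",
    "RecoveryReport",
    "PredictionResult",
    "fit_calibration",
    "select_stabilization_time",
    "predict_product_concentration",
    "precision_accuracy",
    "recovery",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationModel:
    slope: float  # signal units per % w/v
    intercept: float  # signal units
    s_r: float  # standard error of the regression
    r_squared: float
    n_points: int
    conc_range: tuple[float, float]  # calibrated span, % w/v
    lod: float  # % w/v
    loq: float  # % w/v
    signal_span: tuple[float, float] = (0.0, 255.0)  # observed S range
    flags: tuple[str, ...] = ()

    def predict_signal(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def invert(self, s: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope calibration")
        return (s - self.intercept) / self.slope


@dataclass(frozen=True)
class TimeCourse:
    """Fitted calibration slope (and R²) at each acquisition time."""

    times_min: np.ndarray
    slopes: np.ndarray
    r_squareds: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        m = np.asarray(self.slopes, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "slopes", m)
        if self.r_squareds is not None:
            r2 = np.asarray(self.r_squareds, dtype=float)
            object.__setattr__(self, "r_squareds", r2)
            if r2.shape != t.shape:
                raise ValueError("r_squareds length mismatch")
        if t.ndim != 1 or t.shape != m.shape:
            raise ValueError("times and slopes must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class PrecisionReport:
    level: float  # nominal, % w/v (or % w/w for product-level checks)
    accuracy_pct: float  # 100·|mean − nominal|/nominal
    rsd_pct: float  # 100·SD/mean
    scope: str  # "intra_image" or "inter_image"
    n: int


@dataclass(frozen=True)
class RecoveryReport:
    base_level: float
    spike_added: float
    found_increment: float
    recovery_pct: float


@dataclass(frozen=True)
class PredictionResult:
    conc_well: float  # % w/v in the well
    conc_product: float | None  # % w/w in the product (None without prep)
    sd_well: float | None
    sd_product: float | None
    n_replicates: int
    flags: tuple[str, ...] = ()


def fit_calibration(
    standards: pd.DataFrame,
    exclude_blank: bool = True,
    conc_col: str = "conc_pct_wv",
    signal_col: str = "signal",
) -> CalibrationModel:
    """OLS fit of signal on concentration over the standard wells.

    ``standards`` needs the concentration and signal columns; if a ``role``
    column is present only rows with role ``standard`` (plus ``blank`` when
    not excluded) are used, otherwise blanks are identified by zero
    concentration.  Requires >= 3 distinct concentrations after exclusion.
    A non-positive slope is not an error but flags the model
    ``nonincreasing_signal``.
    """
    df = standards
    if "role" in df.columns:
        keep = df["role"] == "standard"
        if not exclude_blank:
            keep |= df["role"] == "blank"
        df = df[keep]
    elif exclude_blank:
        df = df[df[conc_col] > 0]
    df = df.dropna(subset=[conc_col, signal_col])
    conc = df[conc_col].to_numpy(dtype=float)
    sig = df[signal_col].to_numpy(dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError(
            f"calibration needs >= 3 distinct concentrations, got "
            f"{len(np.unique(conc))}"
        )
    if np.ptp(conc) == 0:
        raise ValueError("zero concentration variance")
    res = stats.linregress(conc, sig)
    n = len(conc)
    resid = sig - (res.slope * conc + res.intercept)
    sse = float(np.sum(resid**2))
    s_r = math.sqrt(sse / (n - 2))
    flags: tuple[str, ...] = ()
    if res.slope <= 0:
        flags = ("nonincreasing_signal",)
        lod = loq = math.inf
    else:
        lod = LOD_FACTOR * s_r / res.slope
        loq = LOQ_FACTOR * s_r / res.slope
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        s_r=s_r,
        r_squared=float(res.rvalue**2),
        n_points=n,
        conc_range=(float(conc.min()), float(conc.max())),
        lod=lod,
        loq=loq,
        signal_span=(float(sig.min()), float(sig.max())),
        flags=flags,
    )


def select_stabilization_time(
    course: TimeCourse,
    threshold: float = 1.0 / 3.0,
    mode: str = "remaining",
) -> tuple[float, tuple[str, ...]]:
    """Earliest time at which colour development has effectively stabilized.

    ``remaining`` (default): first t_k with
    (m(t_N) − m(t_k)) / (m(t_N) − m(t_0)) < threshold — the slope gain still
    to come is below the threshold fraction of the total gain (strict).
    ``interval``: first t_k whose per-step increment m(t_k) − m(t_{k-1})
    falls below threshold × total gain.

    A flat course (zero total gain) returns the first time flagged
    ``flat_course``; a non-monotone course is flagged ``nonmonotone_slopes``
    but still evaluated.
    """
    t, m = course.times_min, course.slopes
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    flags: list[str] = []
    if np.any(np.diff(m) < 0):
        flags.append("nonmonotone_slopes")
    total = m[-1] - m[0]
    if total == 0:
        flags.append("flat_course")
        return float(t[0]), tuple(flags)
    if mode == "remaining":
        remaining = (m[-1] - m) / total
        idx = np.flatnonzero(remaining < threshold)
    elif mode == "interval":
        increments = np.diff(m) / total
        idx = np.flatnonzero(increments < threshold) + 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(idx) == 0:  # only possible for the interval variant
        flags.append("never_stabilized")
        return float(t[-1]), tuple(flags)
    return float(t[idx[0]]), tuple(flags)


def predict_product_concentration(
    model: CalibrationModel,
    sample_signal,
    prep: PrepChain | None = None,
) -> PredictionResult:
    """Invert sample signal(s) through the calibration and prep chain.

    ``sample_signal`` may be a scalar or a sequence of replicate signals;
    replicate spread propagates as the SD of per-replicate predictions.
    Signals outside the calibrated span are flagged ``extrapolation``; well
    concentrations below the LOQ are flagged ``below_loq`` but reported.
    """
    if model.slope == 0:
        raise ZeroDivisionError("zero-slope calibration cannot be inverted")
    s = np.atleast_1d(np.asarray(sample_signal, dtype=float))
    flags: list[str] = []
    lo, hi = model.signal_span
    if np.any((s < lo) | (s > hi)):
        flags.append("extrapolation")
    conc_well_reps = (s - model.intercept) / model.slope
    conc_well = float(conc_well_reps.mean())
    sd_well = float(conc_well_reps.std(ddof=1)) if len(s) > 1 else None
    if conc_well < model.loq:
        flags.append("below_loq")
    conc_product = sd_product = None
    if prep is not None:
        conc_product = prep.well_to_product(conc_well)
        if sd_well is not None:
            sd_product = prep.well_to_product(sd_well)
    return PredictionResult(
        conc_well=conc_well,
        conc_product=conc_product,
        sd_well=sd_well,
        sd_product=sd_product,
        n_replicates=len(s),
        flags=tuple(flags),
    )


def precision_accuracy(
    measurements: pd.DataFrame,
    nominal_col: str = "nominal",
    value_col: str = "value",
    image_col: str = "image_id",
) -> list[PrecisionReport]:
    """Intra- and inter-image accuracy and precision per nominal level.

    Accuracy is the relative error of the replicate mean against nominal;
    precision is the RSD.  Intra-image groups replicates within one image
    (reported per level as the mean across images of per-image values);
    inter-image pools all replicates of a level across images.  Every scope
    needs >= 2 replicates, else a ValueError names the offending group.
    """
    reports: list[PrecisionReport] = []
    for level, grp in measurements.groupby(nominal_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"level {level}: need >= 2 replicates for RSD")
        intra_acc, intra_rsd, n_intra = [], [], 0
        for img, sub in grp.groupby(image_col, sort=True):
            v = sub[value_col].to_numpy(dtype=float)
            if len(v) < 2:
                raise ValueError(
                    f"level {level}, image {img}: single replicate, RSD undefined"
                )
            intra_acc.append(100.0 * abs(v.mean() - level) / level)
            intra_rsd.append(100.0 * v.std(ddof=1) / v.mean())
            n_intra += len(v)
        reports.append(
            PrecisionReport(
                level=float(level),
                accuracy_pct=float(np.mean(intra_acc)),
                rsd_pct=float(np.mean(intra_rsd)),
                scope="intra_image",
                n=n_intra,
            )
        )
        reports.append(
            PrecisionReport(
                level=float(level),
                accuracy_pct=100.0 * abs(vals.mean() - level) / level,
                rsd_pct=100.0 * vals.std(ddof=1) / vals.mean(),
                scope="inter_image",
                n=len(vals),
            )
        )
    return reports


def recovery(base_found: float, spiked_found: float, added: float) -> RecoveryReport:
    """Standard-addition recovery: 100·(spiked − base)/added."""
    if added <= 0:
        raise ValueError(f"spike amount must be positive, got {added}")
    increment = spiked_found - base_found
    return RecoveryReport(
        base_level=base_found,
        spike_added=added,
        found_increment=increment,
        recovery_pct=100.0 * increment / added,
    )
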
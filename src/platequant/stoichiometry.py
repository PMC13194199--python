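"""Continuous-variation (Job's plot) analysis of complex stoichiometry.

In the method of continuous variation, mixtures of ligand and metal are
prepared at constant total concentration C_T while the ligand mole fraction
x = [L]/([L]+[M]) sweeps (0, 1).  The response (absorbance of the complex,
or an image-derived signal) peaks at the mole fraction matching the complex
composition: an MLn species peaks at x = n/(n+1), so the ligand:metal ratio
is recovered as x_max / (1 − x_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JobPlotSeries",
    "MaximumLocation",
    "StoichiometryResult",
    "locate_maximum",
    "ratio_from_xmax",
    "job_mixture_fractions",
]


@dataclass(frozen=True)
class JobPlotSeries:
    """Mole fractions and responses of one continuous-variation experiment."""

    x: np.ndarray  # ligand mole fractions, strictly increasing, in (0,1)
    response: np.ndarray  # nonnegative responses, same length
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "response", r)
        if x.shape != r.shape or x.ndim != 1:
            raise ValueError("x and response must be 1-D and the same length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("mole fractions must be strictly increasing")
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError("mole fractions must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class MaximumLocation:
    x_max: float
    method: str  # "quadratic_vertex" or "argmax"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class StoichiometryResult:
    x_max: float
    continuous_ratio: float
    integer_ratio: int
    flags: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return f"{self.integer_ratio}:1"


def locate_maximum(series: JobPlotSeries, method: str = "quadratic_vertex") -> MaximumLocation:
    """Locate the response maximum over mole fraction.

    ``quadratic_vertex`` (default) fits a parabola through the top point and
    its two neighbours and returns the vertex, beating the grid resolution;
    it needs >= 5 points and falls back to ``argmax`` (with a flag) when the
    vertex escapes the bracketing interval or the peak sits on an endpoint.
    Ties in ``argmax`` resolve to the smallest x, flagged.
    """
    x, r = series.x, series.response
    flags: list[str] = []
    i = int(np.argmax(r))
    if np.sum(r == r[i]) > 1:
        flags.append("tie_smallest_x")
    if method == "argmax":
        return MaximumLocation(float(x[i]), "argmax", tuple(flags))
    if method != "quadratic_vertex":
        raise ValueError(f"unknown method {method!r}")
    if len(x) < 5:
        raise ValueError("quadratic_vertex needs at least 5 points")
    if i == 0 or i == len(x) - 1:
        flags.append("peak_at_endpoint")
        return MaximumLocation(float(x[i]), "argmax", tuple(flags))
    xs, rs = x[i - 1 : i + 2], r[i - 1 : i + 2]
    a, b, _c = np.polyfit(xs, rs, 2)
    if a >= 0:  # degenerate: not concave at the top
        flags.append("vertex_not_concave")
        return MaximumLocation(float(x[i]), "argmax", tuple(flags))
    vertex = -b / (2.0 * a)
    if not (xs[0] <= vertex <= xs[2]):
        flags.append("vertex_outside_bracket")
        return MaximumLocation(float(x[i]), "argmax", tuple(flags))
    return MaximumLocation(float(vertex), "quadratic_vertex", tuple(flags))


def ratio_from_xmax(x_max: float) -> StoichiometryResult:
    """Convert a peak mole fraction to ligand:metal ratios.

    The continuous ratio is x_max/(1 − x_max); the integer ratio rounds it
    to the nearest positive integer.  Ratios within 0.1 of a half-integer
    are flagged ambiguous (the grid rarely resolves them).
    """
    if not 0.0 < x_max < 1.0:
        raise ValueError(f"x_max must be strictly inside (0, 1), got {x_max}")
    ratio = x_max / (1.0 - x_max)
    integer = max(1, int(round(ratio)))
    flags: list[str] = []
    frac_part = abs(ratio - np.floor(ratio) - 0.5)
    if frac_part <= 0.1:
        flags.append("ambiguous_rounding")
    return StoichiometryResult(x_max, ratio, integer, tuple(flags))


def job_mixture_fractions(ligand_volumes, metal_volumes) -> np.ndarray:
    """Mole fractions from equal-molarity stock volumes (e.g. 1:9 ... 9:1)."""
    vl = np.asarray(ligand_volumes, dtype=float)
    vm = np.asarray(metal_volumes, dtype=float)
    if np.any(vl < 0) or np.any(vm < 0) or np.any(vl + vm <= 0):
        raise ValueError("volumes must be non-negative with positive totals")
    return vl / (vl + vm)
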
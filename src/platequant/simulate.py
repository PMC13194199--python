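"""Synthetic microplate images for an FeCl3-type colorimetric assay.

The assay being emulated: an analyte (niacinamide) forms an orange complex
with Fe(III) whose blue-channel attenuation grows linearly with analyte
concentration, while the reagent blank stays yellow — a chromatically
different species, which is why blanks are excluded from calibration
downstream.  The simulator produces 8-bit RGB plate photographs with:

* a linear (default) or Beer–Lambert colour response per well,
* first-order colour development ``1 - exp(-k t)`` toward equilibrium,
* a multiplicative illumination plane (uneven lighting across the plate),
* a per-image exposure gain and per-well concentration jitter (the two
  between-replicate variance components a camera-plus-pipette workflow has),
* additive per-pixel Gaussian sensor noise, clipped and quantized to uint8.

Defaults realize a calibration with slope 1865 signal units per % w/v and
intercept −19 on the S = 255 − B scale over 0.040–0.125 % w/v, and kinetics
k = ln(3)/90 per minute so two thirds of the final colour has developed at
90 minutes.

The module also hosts the mass-action equilibrium generator behind
continuous-variation (Job's plot) series for an M + nL <=> MLn complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.optimize import brentq

from .plate import PlateLayout, PrepChain, Role, WellSpec
from .stoichiometry import JobPlotSeries

__all__ = [
    "ColourModel",
    "NoiseModel",
    "KineticModel",
    "EquilibriumSpec",
    "render_plate",
    "write_png",
    "truth_table",
    "complex_fraction",
    "equilibrium_complex_concentration",
    "job_series",
    "calibration_design_layout",
    "demo_plate_layout",
    "STANDARD_CONCS",
]

# eight calibration standards spanning the assay's linear range, % w/v
STANDARD_CONCS = tuple(float(c) for c in np.round(np.linspace(0.04, 0.125, 8), 6))

BACKGROUND_RGB = (245, 245, 245)  # white LED light panel seen through the plate


@dataclass(frozen=True)
class ColourModel:
    """Maps analyte concentration in a well to its noiseless RGB colour.

    ``linear`` mode realizes an empirically linear S = 255 − B response with
    the configured slope/intercept; ``beer_lambert`` maps each channel
    through a transmittance 10^(−eps_c · c · l), which is mildly nonlinear
    on the 255 − B scale and serves as a robustness regime.
    """

    mode: str = "linear"
    true_slope: float = 1865.0  # signal units per % w/v
    true_intercept: float = -19.0  # signal units
    blank_rgb: tuple[int, int, int] = (230, 200, 90)  # yellow reagent blank
    conc_range: tuple[float, float] = (0.04, 0.125)  # valid % w/v span
    # orange complex chromaticity in linear mode: R stays high, G sinks
    red_base: float = 250.0
    red_slope: float = 80.0
    green_base: float = 190.0
    green_slope: float = 600.0
    # beer_lambert mode only
    channel_absorptivities: tuple[float, float, float] = (0.3, 1.5, 6.0)
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "beer_lambert"):
            raise ValueError(f"unknown colour mode {self.mode!r}")
        if any(not 0 <= v <= 255 for v in self.blank_rgb):
            raise ValueError(f"blank_rgb outside [0,255]: {self.blank_rgb}")
        if self.mode == "linear":
            for c in self.conc_range:
                b = 255.0 - (self.true_slope * c + self.true_intercept)
                if not 0.0 <= b <= 255.0:
                    raise ValueError(
                        f"linear model leaves the blue channel out of range "
                        f"at c={c} % w/v (B={b:.1f})"
                    )

    def rgb_at(self, conc: float) -> tuple[float, float, float]:
        """Noiseless well colour at effective concentration ``conc`` % w/v."""
        if conc < 0 or conc > self.conc_range[1] + 1e-12:
            raise ValueError(
                f"concentration {conc} % w/v outside the model's valid range "
                f"[0, {self.conc_range[1]}]"
            )
        if self.mode == "linear":
            r = self.red_base - self.red_slope * conc
            g = self.green_base - self.green_slope * conc
            b = 255.0 - (self.true_slope * conc + self.true_intercept)
        else:
            er, eg, eb = self.channel_absorptivities
            l = self.path_length
            r = 255.0 * 10.0 ** (-er * conc * l)
            g = 255.0 * 10.0 ** (-eg * conc * l)
            b = 255.0 * 10.0 ** (-eb * conc * l)
        clip = lambda v: min(255.0, max(0.0, v))
        return (clip(r), clip(g), clip(b))


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic degradations applied at render time.

    pixel_sigma          additive Gaussian sensor noise per channel (counts)
    illumination_gradient  (gx, gy): relative change of the multiplicative
                         illumination plane per pixel, 1 + gx*x + gy*y
    gain_sigma           relative SD of a per-image exposure gain (auto-ISO
                         shot-to-shot variation); drives inter-image spread
    well_sigma           relative SD of each well's effective concentration
                         (pipetting error); drives intra-image spread
    seed                 RNG seed; equal seeds give byte-identical renders
    """

    pixel_sigma: float = 3.0
    illumination_gradient: tuple[float, float] = (5e-5, 3e-5)
    gain_sigma: float = 0.015
    well_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sigma < 0 or self.gain_sigma < 0 or self.well_sigma < 0:
            raise ValueError("noise magnitudes must be non-negative")


NOISELESS = NoiseModel(
    pixel_sigma=0.0, illumination_gradient=(0.0, 0.0), gain_sigma=0.0, well_sigma=0.0
)


@dataclass(frozen=True)
class KineticModel:
    """First-order approach of the complex toward its equilibrium colour."""

    rate_k: float = math.log(3.0) / 90.0  # per minute; 2/3 developed at 90 min

    def __post_init__(self) -> None:
        if self.rate_k <= 0:
            raise ValueError(f"rate_k must be positive, got {self.rate_k}")


def complex_fraction(kinetics: KineticModel, t_min: float) -> float:
    """Fraction of the equilibrium complex formed after ``t_min`` minutes.

    Returns 1 − exp(−k t); monotone nondecreasing, 0 at t=0, → 1 as t → ∞.
    """
    if t_min < 0:
        raise ValueError(f"time must be non-negative, got {t_min}")
    return 1.0 - math.exp(-kinetics.rate_k * t_min)


def _image_shape_for(layout: PlateLayout, margin: float = 15.0) -> tuple[int, int]:
    xs, ys = zip(*(layout.center_of(w.row, w.col) for w in layout.active_wells()))
    r = layout.roi_radius
    width = int(math.ceil(max(xs) + r + margin))
    height = int(math.ceil(max(ys) + r + margin))
    return (height, width)


def render_plate(
    layout: PlateLayout,
    colour: ColourModel,
    noise: NoiseModel = NoiseModel(),
    time_min: float = float("inf"),
    kinetics: KineticModel = KineticModel(),
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one plate photograph as an (H, W, 3) uint8 array.

    Each non-empty well is a filled disc of radius ``layout.roi_radius + 2``
    (slightly larger than the analysis ROI so edge pixels are in-well) whose
    interior colour is the colour model applied to the well concentration
    scaled by the kinetic fraction at ``time_min``.  Blanks keep their fixed
    blank colour at all times.  Illumination plane, exposure gain and pixel
    noise are then applied, and the result clipped to [0, 255] and quantized.
    """
    rng = np.random.default_rng(noise.seed)
    shape = image_shape or _image_shape_for(layout)
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB

    frac = complex_fraction(kinetics, time_min) if math.isfinite(time_min) else 1.0
    yy, xx = np.mgrid[0:h, 0:w]
    paint_r = layout.roi_radius + 2.0

    for well in layout.active_wells():
        cx, cy = layout.center_of(well.row, well.col)
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(
                f"well ({well.row},{well.col}) center ({cx},{cy}) outside the "
                f"{h}x{w} image"
            )
        if well.role is Role.BLANK:
            rgb = tuple(float(v) for v in colour.blank_rgb)
        else:
            conc = 0.0 if well.conc is None else well.conc
            jitter = 1.0 + noise.well_sigma * rng.standard_normal()
            conc_eff = max(0.0, conc * frac * jitter)
            rgb = colour.rgb_at(min(conc_eff, colour.conc_range[1]))
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= paint_r**2
        img[disc] = rgb

    gx, gy = noise.illumination_gradient
    if gx != 0.0 or gy != 0.0:
        plane = 1.0 + gx * xx + gy * yy
        img *= plane[..., None]
    if noise.gain_sigma > 0:
        img *= 1.0 + noise.gain_sigma * rng.standard_normal()
    if noise.pixel_sigma > 0:
        img += rng.normal(0.0, noise.pixel_sigma, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def write_png(image: np.ndarray, path) -> None:
    """Write an (H, W, 3) uint8 array as an 8-bit RGB PNG."""
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def truth_table(
    layout: PlateLayout,
    colour: ColourModel,
    time_min: float = float("inf"),
    kinetics: KineticModel = KineticModel(),
    seed: int | None = None,
):
    """Per-well noiseless ground truth as a DataFrame (sidecar for a render)."""
    import pandas as pd

    frac = complex_fraction(kinetics, time_min) if math.isfinite(time_min) else 1.0
    rows = []
    for well in layout.active_wells():
        if well.role is Role.BLANK:
            rgb = tuple(float(v) for v in colour.blank_rgb)
        else:
            conc = 0.0 if well.conc is None else well.conc
            rgb = colour.rgb_at(min(conc * frac, colour.conc_range[1]))
        rows.append(
            {
                "row": well.row,
                "col": well.col,
                "role": well.role.value,
                "conc_pct_wv": well.conc,
                "true_R": rgb[0],
                "true_G": rgb[1],
                "true_B": rgb[2],
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def calibration_design_layout(
    n_replicates: int = 3,
    roi_radius: float = 10.0,
    pitch: float = 40.0,
    origin: float = 30.0,
) -> PlateLayout:
    """Blank + eight standards (0.040–0.125 % w/v), replicated row-wise.

    Column 0 holds the blank, columns 1–8 the ascending standards; each of
    the ``n_replicates`` rows repeats the series.
    """
    wells = []
    for r in range(n_replicates):
        wells.append(WellSpec(r, 0, Role.BLANK, 0.0, replicate_group="blank"))
        for j, c in enumerate(STANDARD_CONCS, start=1):
            wells.append(WellSpec(r, j, Role.STANDARD, c, replicate_group=f"std{j}"))
    return PlateLayout(
        n_rows=n_replicates,
        n_cols=9,
        roi_radius=roi_radius,
        wells=wells,
        grid={"origin_x": origin, "origin_y": origin, "pitch_x": pitch, "pitch_y": pitch},
    )


def demo_plate_layout(
    sample_conc_well: float = 0.08,
    prep: PrepChain | None = None,
    n_replicates: int = 3,
) -> PlateLayout:
    """Calibration design plus one triplicate sample group.

    The sample well concentration defaults to 0.08 % w/v with a
    320 µL / 400 µL aliquot of a 1:100 (w/v) dissolution — a product
    holding 10 % w/w of analyte.
    """
    base = calibration_design_layout(n_replicates=n_replicates)
    prep = prep or PrepChain(dilution=100.0, aliquot_ul=320.0, total_ul=400.0)
    wells = list(base.wells)
    for r in range(n_replicates):
        wells.append(
            WellSpec(
                n_replicates,
                r,
                Role.SAMPLE,
                sample_conc_well,
                replicate_group="sample_A",
                prep=prep,
            )
        )
    return PlateLayout(
        n_rows=n_replicates + 1,
        n_cols=9,
        roi_radius=base.roi_radius,
        wells=wells,
        grid=dict(base.grid),
    )


# --- continuous-variation (Job's plot) equilibrium generator ----------------


@dataclass(frozen=True)
class EquilibriumSpec:
    """Single M + nL <=> MLn equilibrium at constant total concentration."""

    n: int = 2  # ligands per metal
    log_K: float = 8.0  # magnitude of the overall formation constant
    total_conc: float = 0.1  # mol/L, [L]0 + [M]0 at every mixture

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"stoichiometry n must be >= 1, got {self.n}")
        if self.total_conc <= 0:
            raise ValueError(f"total_conc must be positive, got {self.total_conc}")


def equilibrium_complex_concentration(
    metal_total: float, ligand_total: float, n: int, K: float
) -> float:
    """Solve M + nL <=> MLn mass action for the complex concentration.

    Root of  z = K (M0 − z)(L0 − n z)^n  on [0, min(M0, L0/n)], found by
    bracketed root finding.  Free species follow by difference, so mass is
    conserved by construction.
    """
    z_max = min(metal_total, ligand_total / n)
    if z_max <= 0:
        return 0.0

    def f(z: float) -> float:
        return z - K * (metal_total - z) * (ligand_total - n * z) ** n

    try:
        return brentq(f, 0.0, z_max, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise ArithmeticError(
            f"equilibrium solver failed at M0={metal_total}, L0={ligand_total}: {exc}"
        ) from exc


def job_series(spec: EquilibriumSpec, fractions) -> JobPlotSeries:
    """Continuous-variation series: response vs ligand mole fraction.

    For each mole fraction x in (0,1) the mixture holds [L]0 = x C_T and
    [M]0 = (1−x) C_T; the response is proportional to the complex
    concentration at equilibrium (unit molar response assumed).
    """
    x = np.asarray(list(fractions), dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("mole fractions must lie strictly inside (0, 1)")
    K = 10.0**spec.log_K
    response = np.array(
        [
            equilibrium_complex_concentration(
                (1.0 - xi) * spec.total_conc, xi * spec.total_conc, spec.n, K
            )
            for xi in x
        ]
    )
    order = np.argsort(x)
    return JobPlotSeries(x=x[order], response=response[order])
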
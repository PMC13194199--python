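"""Plate layouts: wells, roles, preparation chains and their YAML serialization.

A :class:`PlateLayout` declares where each well sits in a photographed image
(real-valued pixel centers, origin top-left, y down), what the well contains
(blank / calibration standard / sample / empty) and, for samples, how the
product was diluted into the well.  All downstream stages — the simulator,
the ROI extractor, the calibration inverse prediction — share this one
geometry and unit convention.

Units: concentrations inside a well are % w/v (grams analyte per 100 mL of
well solution); product-level results are % w/w.  The only place the two
are converted is :meth:`PrepChain.well_to_product`.

Layout files are YAML with top-level keys ``plate``, ``wells`` and either a
``grid`` spec or explicit ``centers``::

    plate: {n_rows: 3, n_cols: 9, roi_radius: 10}
    grid: {origin_x: 30.0, origin_y: 30.0, pitch_x: 40.0, pitch_y: 40.0}
    wells:
      - {row: 0, col: 0, role: blank, conc: 0.0, replicate_group: blk}
      - {row: 0, col: 1, role: standard, conc: 0.04, replicate_group: s1}
      - {row: 0, col: 2, role: sample, replicate_group: serum_A,
         prep: {dilution: 100, aliquot_ul: 320, total_ul: 400}}
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml

__all__ = [
    "Role",
    "PrepChain",
    "WellSpec",
    "PlateLayout",
    "LayoutParseError",
    "LayoutValidationError",
    "read_layout",
    "write_layout",
]


class LayoutParseError(ValueError):
    """Raised when a layout file is structurally malformed (names the key)."""


class LayoutValidationError(ValueError):
    """Raised when a parsed layout violates an invariant (names the well)."""


class Role(str, enum.Enum):
    BLANK = "blank"
    STANDARD = "standard"
    SAMPLE = "sample"
    EMPTY = "empty"


@dataclass(frozen=True)
class PrepChain:
    """Dilution arithmetic from product to well.

    ``dilution`` is the mass-per-volume factor of the primary dissolution
    (100 for a "1:100 (w/v)" solution, i.e. 250 mg in 25.00 mL),
    ``aliquot_ul`` the volume of that solution pipetted into the well and
    ``total_ul`` the final well volume after reagent and solvent addition.
    """

    dilution: float
    aliquot_ul: float
    total_ul: float

    def __post_init__(self) -> None:
        if self.dilution <= 0 or self.aliquot_ul <= 0 or self.total_ul <= 0:
            raise LayoutValidationError(
                f"prep chain factors must be positive, got {self}"
            )
        if self.aliquot_ul > self.total_ul:
            raise LayoutValidationError(
                f"aliquot ({self.aliquot_ul} uL) exceeds final well volume "
                f"({self.total_ul} uL)"
            )

    def well_to_product(self, conc_well_pct_wv: float) -> float:
        """Convert a well concentration (% w/v) to product content (% w/w)."""
        conc_solution = conc_well_pct_wv * self.total_ul / self.aliquot_ul
        return conc_solution * self.dilution

    def product_to_well(self, conc_product_pct_ww: float) -> float:
        """Inverse of :meth:`well_to_product` (used by the simulator)."""
        return conc_product_pct_ww / self.dilution * self.aliquot_ul / self.total_ul


@dataclass
class WellSpec:
    row: int
    col: int
    role: Role
    conc: float | None = None  # % w/v in the well; None allowed for samples
    replicate_group: str = ""
    prep: PrepChain | None = None

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        if self.role is Role.STANDARD:
            if self.conc is None or self.conc < 0:
                raise LayoutValidationError(
                    f"well ({self.row},{self.col}): standard requires a "
                    f"non-negative concentration, got {self.conc}"
                )
        if self.role is Role.BLANK:
            if self.conc is None:
                self.conc = 0.0
            if self.conc != 0.0:
                raise LayoutValidationError(
                    f"well ({self.row},{self.col}): blank must have zero "
                    f"concentration, got {self.conc}"
                )


@dataclass
class PlateLayout:
    """Geometry plus contents of one photographed plate."""

    n_rows: int
    n_cols: int
    roi_radius: float
    wells: list[WellSpec]
    centers: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    grid: dict[str, float] | None = None  # origin_x, origin_y, pitch_x, pitch_y

    def __post_init__(self) -> None:
        if self.roi_radius < 1:
            raise LayoutValidationError(
                f"roi_radius must be >= 1 pixel, got {self.roi_radius}"
            )
        if not self.wells:
            raise LayoutValidationError("layout has no wells")
        seen: set[tuple[int, int]] = set()
        for w in self.wells:
            key = (w.row, w.col)
            if key in seen:
                raise LayoutValidationError(f"duplicate well position {key}")
            seen.add(key)
            if not (0 <= w.row < self.n_rows and 0 <= w.col < self.n_cols):
                raise LayoutValidationError(
                    f"well {key} outside the {self.n_rows}x{self.n_cols} plate"
                )
        if self.grid is None and not self.centers:
            raise LayoutValidationError(
                "layout needs either a grid spec or explicit centers"
            )

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """Pixel center (x, y) of a well; grid-derived unless explicit."""
        if (row, col) in self.centers:
            return self.centers[(row, col)]
        g = self.grid
        if g is None:
            raise LayoutValidationError(f"no center known for well ({row},{col})")
        return (g["origin_x"] + col * g["pitch_x"], g["origin_y"] + row * g["pitch_y"])

    def active_wells(self) -> list[WellSpec]:
        """Non-empty wells in row-major order."""
        return sorted(
            (w for w in self.wells if w.role is not Role.EMPTY),
            key=lambda w: (w.row, w.col),
        )


def _well_to_dict(w: WellSpec) -> dict:
    d: dict = {"row": int(w.row), "col": int(w.col), "role": w.role.value}
    if w.conc is not None:
        d["conc"] = float(w.conc)
    if w.replicate_group:
        d["replicate_group"] = w.replicate_group
    if w.prep is not None:
        d["prep"] = {
            "dilution": w.prep.dilution,
            "aliquot_ul": w.prep.aliquot_ul,
            "total_ul": w.prep.total_ul,
        }
    return d


def _well_from_dict(d: dict) -> WellSpec:
    try:
        prep = None
        if "prep" in d and d["prep"] is not None:
            p = d["prep"]
            prep = PrepChain(
                dilution=float(p["dilution"]),
                aliquot_ul=float(p["aliquot_ul"]),
                total_ul=float(p["total_ul"]),
            )
        conc = d.get("conc")
        return WellSpec(
            row=int(d["row"]),
            col=int(d["col"]),
            role=Role(d["role"]),
            conc=None if conc is None else float(conc),
            replicate_group=str(d.get("replicate_group", "")),
            prep=prep,
        )
    except KeyError as exc:
        raise LayoutParseError(f"well entry missing key {exc}") from exc


def read_layout(path) -> PlateLayout:
    """Read and validate a YAML plate layout."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LayoutParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise LayoutParseError("layout file must be a YAML mapping")
    for key in ("plate", "wells"):
        if key not in doc:
            raise LayoutParseError(f"missing top-level key '{key}'")
    plate = doc["plate"]
    for key in ("n_rows", "n_cols", "roi_radius"):
        if key not in plate:
            raise LayoutParseError(f"missing key 'plate.{key}'")
    centers: dict[tuple[int, int], tuple[float, float]] = {}
    for c in doc.get("centers") or []:
        try:
            centers[(int(c["row"]), int(c["col"]))] = (float(c["x"]), float(c["y"]))
        except KeyError as exc:
            raise LayoutParseError(f"centers entry missing key {exc}") from exc
    grid = doc.get("grid")
    if grid is not None:
        for key in ("origin_x", "origin_y", "pitch_x", "pitch_y"):
            if key not in grid:
                raise LayoutParseError(f"missing key 'grid.{key}'")
        grid = {k: float(grid[k]) for k in ("origin_x", "origin_y", "pitch_x", "pitch_y")}
    wells = [_well_from_dict(d) for d in doc["wells"]]
    return PlateLayout(
        n_rows=int(plate["n_rows"]),
        n_cols=int(plate["n_cols"]),
        roi_radius=float(plate["roi_radius"]),
        wells=wells,
        centers=centers,
        grid=grid,
    )


def write_layout(layout: PlateLayout, path) -> None:
    """Serialize a layout to YAML, losslessly round-trippable by read_layout."""
    doc: dict = {
        "plate": {
            "n_rows": layout.n_rows,
            "n_cols": layout.n_cols,
            "roi_radius": layout.roi_radius,
        },
        "wells": [_well_to_dict(w) for w in layout.wells],
    }
    if layout.grid is not None:
        doc["grid"] = dict(layout.grid)
    if layout.centers:
        doc["centers"] = [
            {"row": r, "col": c, "x": x, "y": y}
            for (r, c), (x, y) in sorted(layout.centers.items())
        ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
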
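"""Anatomy-derived hydraulic trait computations.

Light-microscopy traits (hydraulically weighted vessel diameter ``D_h``,
vessel frequency ``VF``, theoretical Hagen-Poiseuille conductivity ``K_th``,
stomatal density/size under the top-left border inclusion rule) and
SEM-derived intervessel pit traits (membrane/aperture diameters and areas,
shape ratios ``R_pit``/``R_pa``, pit density ``D_p``, and the pit-wall
coverage fraction used to gauge distance from the geometric packing limit).

All raw measurements (vessel outlines, pit dimensions, stomatal centroids)
are assumed to come from upstream image analysis; this module only derives
traits from them.

Units follow the conventions of wood-anatomy practice: lengths in µm,
areas in µm² (pits, stomata) or mm² (fields of view), densities in
no. mm⁻² (vessels, stomata) or no. µm⁻² (pits), and ``K_th`` in
kg m⁻¹ MPa⁻¹ s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import InputError

__all__ = [
    "PhysicalConstants",
    "VesselSection",
    "PitMorphology",
    "StomatalField",
    "PitSummary",
    "StomatalTraits",
    "equivalent_circular_diameter",
    "hydraulic_diameter",
    "vessel_frequency",
    "theoretical_conductivity",
    "pit_summary",
    "stomatal_traits",
    "packing_position",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fluid properties used in the Hagen-Poiseuille conductivity.

    Parameters
    ----------
    rho : float
        Fluid density, kg m⁻³. Default 998.2 (water at 20 °C).
    eta : float
        Dynamic viscosity, MPa·s. Default 1.002e-9 (water at 20 °C;
        equal to 1.002e-3 Pa·s expressed in MPa·s).
    """

    rho: float = 998.2
    eta: float = 1.002e-9

    def __post_init__(self):
        if self.rho <= 0 or self.eta <= 0:
            raise InputError("density and viscosity must be positive")

    @property
    def poiseuille_prefactor(self) -> float:
        """π·ρ/(128·η) in kg m⁻³ MPa⁻¹ s⁻¹ (≈2.445e10 for defaults)."""
        return math.pi * self.rho / (128.0 * self.eta)


def _as_positive_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InputError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise InputError(f"{name} must be finite and positive")
    return arr


@dataclass
class VesselSection:
    """Vessel lumen measurements from one cross-section image.

    ``vessel_diameters`` are equivalent circular lumen diameters (µm), each
    computed upstream from the long and short axis of the (elliptical)
    lumen — see :func:`equivalent_circular_diameter`.
    ``wall_thickness_pairs`` holds double-wall thickness measurements
    ``T_w`` (µm) between connected vessel pairs.  ``image_area`` is the
    cross-section field of view in mm².
    """

    vessel_diameters: Sequence[float]
    image_area: float
    wall_thickness_pairs: Sequence[float] = field(default_factory=list)

    def __post_init__(self):
        self.vessel_diameters = np.asarray(self.vessel_diameters, dtype=float)
        if self.vessel_diameters.size == 0:
            raise InputError("vessel section needs at least one vessel diameter")
        if np.any(~np.isfinite(self.vessel_diameters)) or np.any(self.vessel_diameters <= 0):
            raise InputError("vessel diameters must be finite and positive")
        if not (np.isfinite(self.image_area) and self.image_area > 0):
            raise InputError("image_area must be positive")
        self.wall_thickness_pairs = np.asarray(self.wall_thickness_pairs, dtype=float)
        if self.wall_thickness_pairs.size and np.any(self.wall_thickness_pairs <= 0):
            raise InputError("wall thicknesses must be positive")

    @property
    def n_vessels(self) -> int:
        return int(self.vessel_diameters.size)

    @property
    def mean_wall_thickness(self) -> float:
        """Mean double vessel wall thickness T_w (µm); NaN if unmeasured."""
        if self.wall_thickness_pairs.size == 0:
            return float("nan")
        return float(np.mean(self.wall_thickness_pairs))


def equivalent_circular_diameter(d_long, d_short):
    """Area-preserving circular diameter of an elliptical lumen, √(a·b).

    An ellipse with axes ``d_long`` × ``d_short`` has the same area as a
    circle of diameter √(d_long·d_short).
    """
    a = np.asarray(d_long, dtype=float)
    b = np.asarray(d_short, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InputError("axis lengths must be positive")
    return np.sqrt(a * b)


def hydraulic_diameter(section) -> float:
    """Hydraulically weighted vessel diameter D_h = (ΣD⁴/N)^0.25, µm.

    The fourth-power mean weights each vessel by its Hagen-Poiseuille
    conductance contribution, so D_h is biased toward the wide vessels
    that carry most of the flow, and always ≥ the arithmetic mean.

    ``section`` may be a :class:`VesselSection` or a plain sequence of
    diameters.
    """
    d = section.vessel_diameters if isinstance(section, VesselSection) else None
    if d is None:
        d = _as_positive_array(section, "vessel diameters")
    return float(np.mean(d**4) ** 0.25)


def vessel_frequency(section: VesselSection) -> float:
    """Vessel frequency VF = N / image area, vessels mm⁻²."""
    if isinstance(section, VesselSection):
        return section.n_vessels / section.image_area
    raise InputError("vessel_frequency expects a VesselSection")


def theoretical_conductivity(
    vf: float, d_h: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Theoretical xylem conductivity K_th = (πρ/128η)·VF·D_h⁴.

    Parameters
    ----------
    vf : float
        Vessel frequency in mm⁻² (converted to m⁻² internally).
    d_h : float
        Hydraulically weighted diameter in µm (converted to m internally).

    Returns
    -------
    float
        K_th in kg m⁻¹ MPa⁻¹ s⁻¹.  Scales linearly with VF and with the
        fourth power of D_h; end walls and pit resistance are ignored.
    """
    if not (np.isfinite(d_h) and d_h > 0):
        raise InputError("D_h must be positive")
    if not (np.isfinite(vf) and vf >= 0):
        raise InputError("VF must be nonnegative")
    vf_si = vf * 1e6  # mm^-2 -> m^-2
    dh_si = d_h * 1e-6  # um -> m
    return constants.poiseuille_prefactor * vf_si * dh_si**4


@dataclass
class PitMorphology:
    """Per-pit SEM measurements from intervessel walls.

    Diameters (µm): pit membrane long/short axes ``d_pml``/``d_pms`` and
    pit aperture long/short axes ``d_pal``/``d_pas``.  Areas (µm²):
    membrane ``a_pit`` and aperture ``a_pa``.  ``pit_counts`` is a list of
    ``(n_pits, wall_area_um2)`` observations used for pit density.
    """

    d_pml: Sequence[float]
    d_pms: Sequence[float]
    d_pal: Sequence[float]
    d_pas: Sequence[float]
    a_pit: Sequence[float]
    a_pa: Sequence[float]
    pit_counts: Sequence[tuple] = field(default_factory=list)

    def __post_init__(self):
        for name in ("d_pml", "d_pms", "d_pal", "d_pas", "a_pit", "a_pa"):
            setattr(self, name, _as_positive_array(getattr(self, name), name))
        lengths = {
            len(self.d_pml), len(self.d_pms), len(self.d_pal),
            len(self.d_pas), len(self.a_pit), len(self.a_pa),
        }
        if len(lengths) != 1:
            raise InputError("per-pit measurement arrays must have equal length")
        if np.any(self.d_pml < self.d_pms) or np.any(self.d_pal < self.d_pas):
            raise InputError("long axes must be >= short axes for every pit")
        if np.any(self.a_pa > self.a_pit):
            raise InputError("aperture area cannot exceed pit membrane area")
        counts = [(int(n), float(a)) for n, a in self.pit_counts]
        for n, a in counts:
            if n < 0 or a <= 0:
                raise InputError("pit_counts entries need n >= 0 and wall area > 0")
        self.pit_counts = counts

    @property
    def n_pits(self) -> int:
        return int(len(self.d_pml))


@dataclass(frozen=True)
class PitSummary:
    """Mean pit traits for one sample (units as in the field: µm, µm²)."""

    d_pml: float
    d_pms: float
    d_pal: float
    d_pas: float
    a_pit: float
    a_pa: float
    r_pa: float
    r_pit: float
    d_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def pit_summary(
    pits: PitMorphology,
    ratio_mode: Literal["per_pit", "mean_diameter"] = "per_pit",
) -> PitSummary:
    """Summarize pit morphology: mean diameters/areas, shape ratios, density.

    Shape ratios R_pa = D_pal/D_pas and R_pit = D_pml/D_pms are ≥ 1 by
    construction (circular pits give exactly 1).  With the default
    ``ratio_mode='per_pit'`` the ratio is computed pit by pit and then
    averaged; ``'mean_diameter'`` takes the ratio of mean diameters
    instead.  Pit density D_p pools counts over walls, Σn / Σarea
    (no. µm⁻²), weighting by observed wall area.
    """
    if pits.n_pits < 1:
        raise InputError("need at least one pit")
    if ratio_mode == "per_pit":
        r_pa = float(np.mean(pits.d_pal / pits.d_pas))
        r_pit = float(np.mean(pits.d_pml / pits.d_pms))
    elif ratio_mode == "mean_diameter":
        r_pa = float(np.mean(pits.d_pal) / np.mean(pits.d_pas))
        r_pit = float(np.mean(pits.d_pml) / np.mean(pits.d_pms))
    else:
        raise InputError(f"unknown ratio_mode {ratio_mode!r}")
    if pits.pit_counts:
        total_n = sum(n for n, _ in pits.pit_counts)
        total_area = sum(a for _, a in pits.pit_counts)
        d_p = total_n / total_area
    else:
        d_p = float("nan")
    return PitSummary(
        d_pml=float(np.mean(pits.d_pml)),
        d_pms=float(np.mean(pits.d_pms)),
        d_pal=float(np.mean(pits.d_pal)),
        d_pas=float(np.mean(pits.d_pas)),
        a_pit=float(np.mean(pits.a_pit)),
        a_pa=float(np.mean(pits.a_pa)),
        r_pa=r_pa,
        r_pit=r_pit,
        d_p=d_p,
    )


@dataclass
class StomatalField:
    """Stomatal annotations within one rectangular field of view.

    Coordinates are in µm with the origin at the top-left corner of the
    image, x increasing rightward and y increasing downward (image
    convention).  ``stomatal_areas`` are guard-cell-pair outline areas in
    µm².
    """

    centroids: Sequence[tuple]
    field_width: float
    field_height: float
    stomatal_areas: Sequence[float] = field(default_factory=list)

    def __post_init__(self):
        if self.field_width <= 0 or self.field_height <= 0:
            raise InputError("field dimensions must be positive")
        pts = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if pts.size and (
            np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > self.field_width)
            or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > self.field_height)
        ):
            raise InputError("centroids must lie within the field of view")
        self.centroids = pts
        self.stomatal_areas = np.asarray(self.stomatal_areas, dtype=float)

    @property
    def area_mm2(self) -> float:
        return self.field_width * self.field_height / 1e6


@dataclass(frozen=True)
class StomatalTraits:
    d_s: float            # stomatal density, no. mm^-2
    s_s: float            # stomatal size, um^2 (NaN when no outlines)
    n_counted: int
    s_s_defined: bool


def stomatal_traits(field_: StomatalField, border_tol: float = 1.0) -> StomatalTraits:
    """Stomatal density and size with the unbiased border-counting rule.

    Objects within ``border_tol`` (µm) of the bottom or right edge are
    discarded; objects within tolerance of the top or left edge are kept;
    everything else is interior and kept.  This is the standard top/left
    inclusion rule that makes density estimates unbiased for objects
    straddling frame edges.  An empty field yields D_s = 0 and an
    undefined (NaN, flagged) stomatal size.
    """
    pts = field_.centroids
    if pts.size == 0:
        return StomatalTraits(d_s=0.0, s_s=float("nan"), n_counted=0, s_s_defined=False)
    x, y = pts[:, 0], pts[:, 1]
    on_bottom_right = (x >= field_.field_width - border_tol) | (y >= field_.field_height - border_tol)
    on_top_left = (x <= border_tol) | (y <= border_tol)
    keep = ~on_bottom_right | on_top_left  # top/left inclusion wins over bottom/right
    # a stoma in a corner touching both an include- and a discard-edge is kept
    n = int(np.count_nonzero(keep))
    d_s = n / field_.area_mm2
    areas = field_.stomatal_areas
    if areas.size:
        return StomatalTraits(d_s=d_s, s_s=float(np.mean(areas)), n_counted=n, s_s_defined=True)
    return StomatalTraits(d_s=d_s, s_s=float("nan"), n_counted=n, s_s_defined=False)


def packing_position(a_pit: float, d_p: float) -> float:
    """Fraction of intervessel wall covered by pit membranes, D_p·A_pit.

    The geometric packing limit is defined as full coverage,
    D_p·A_pit = 1; values ≤ 1 are geometrically feasible and values near
    1 indicate pits packed close to the limit.  Dimensionless (µm² × µm⁻²).
    """
    if not (np.isfinite(a_pit) and a_pit > 0 and np.isfinite(d_p) and d_p > 0):
        raise InputError("A_pit and D_p must be positive")
    return float(a_pit * d_p)
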
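"""Minimum diffusive conductance (g_min) from bench drying curves.

An excised organ with its cut end sealed loses water only by diffusion
across its surface (cuticle plus any leaky stomata).  Weighing it
repeatedly while recording air temperature and relative humidity gives a
mass-vs-time series whose slope, normalized and scaled by the ratio of
atmospheric pressure to vapor pressure deficit, is the minimum diffusive
conductance:

    g_min = WL · P_atm / VPD

where WL is the water-loss rate in mmol s⁻¹ per unit projected area
(m²) or dry mass (g), P_atm is atmospheric pressure (kPa) and VPD is
the vapor pressure deficit (kPa) from the Buck saturation-vapor-pressure
formula.  Both the area-normalized (mmol m⁻² s⁻¹) and mass-normalized
(mmol g⁻¹ s⁻¹) conductances are reported; the two are linked exactly by
g_min_area · area = g_min_mass · dry_mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import ComputationError, InputError

__all__ = [
    "MOLAR_MASS_WATER",
    "DryingCurve",
    "WaterLossFit",
    "GminResult",
    "vpd",
    "saturation_vapor_pressure",
    "water_loss_rate",
    "gmin",
]

MOLAR_MASS_WATER = 18.015  # g mol^-1


def saturation_vapor_pressure(temp_c):
    """Buck saturation vapor pressure over water, kPa.

    e_s(T) = 0.61121 · exp(17.502·T / (240.97 + T)) with T in °C.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -40) or np.any(t >= 60):
        raise InputError("temperature outside the validity range (-40, 60) degC")
    return 0.61121 * np.exp(17.502 * t / (240.97 + t))


def vpd(temp_c, rh_pct):
    """Vapor pressure deficit (kPa) from air temperature (°C) and RH (%).

    VPD = (1 − RH/100) · e_s(T); zero at saturation, increasing with
    temperature at any RH < 100.
    """
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise InputError("relative humidity must be within [0, 100] %")
    out = (1.0 - rh / 100.0) * saturation_vapor_pressure(temp_c)
    return float(out) if np.ndim(out) == 0 else out


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares line fit returning (slope, intercept, r2).

    r² is defined as 1 − SSE/SST, with a perfect fit (SSE ≈ 0, e.g. a
    constant series) reported as r² = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise InputError("zero variance in x; cannot fit a slope")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    scale = max(sst, float(np.sum(y**2)), 1.0)
    if sse <= 1e-14 * scale:
        r2 = 1.0
    elif sst == 0:
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    return float(slope), float(intercept), float(r2)


@dataclass
class DryingCurve:
    """A timed weighing series for one drying organ (the model object).

    Fields: ``times`` (s, strictly increasing), ``masses`` (g), per-weighing
    air ``temps`` (°C) and ``rhs`` (RH, %), single-sided ``projected_area``
    (m²), ``dry_mass`` (g) and atmospheric pressure ``p_atm`` (kPa).
    ``fit()`` estimates g_min.
    """

    times: Sequence[float]
    masses: Sequence[float]
    temps: Sequence[float]
    rhs: Sequence[float]
    projected_area: float
    dry_mass: float
    p_atm: float = 101.3

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.masses = np.asarray(self.masses, float)
        self.temps = np.asarray(self.temps, float)
        self.rhs = np.asarray(self.rhs, float)
        n = self.times.size
        if n < 3:
            raise InputError("drying curve needs at least 3 weighings")
        if not (self.masses.size == self.temps.size == self.rhs.size == n):
            raise InputError("times, masses, temps, rhs must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(self.rhs <= 0) or np.any(self.rhs >= 100):
            raise InputError("RH must lie strictly within (0, 100) %")
        if self.projected_area <= 0 or self.dry_mass <= 0 or self.p_atm <= 0:
            raise InputError("projected_area, dry_mass and p_atm must be positive")
        if np.any(self.masses < self.dry_mass - 1e-12):
            raise InputError("masses cannot fall below dry mass")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    def vpds(self) -> np.ndarray:
        """Per-weighing VPD (kPa)."""
        return np.asarray(vpd(self.temps, self.rhs), float)

    def water_loss_rate(
        self, window: Literal["full", "auto"] = "full", min_window: int = 5
    ) -> "WaterLossFit":
        """OLS slope of mass over time, reported as a positive loss rate.

        ``window='full'`` uses every weighing.  ``window='auto'`` scans all
        contiguous windows of at least ``min_window`` points and keeps the
        one maximizing r² (ties broken toward longer, then later windows),
        which isolates the linear tail when an initial fast phase (e.g.
        incomplete stomatal closure) is present.
        """
        n = self.n_obs
        if window == "full":
            lo, hi = 0, n
        elif window == "auto":
            m = min(max(min_window, 3), n)
            best = None
            for i0 in range(0, n - m + 1):
                for i1 in range(i0 + m, n + 1):
                    s, _, r2 = _ols_line(self.times[i0:i1], self.masses[i0:i1])
                    key = (round(r2, 12), i1 - i0, i0)
                    if best is None or key > best[0]:
                        best = (key, (i0, i1))
            lo, hi = best[1]
        else:
            raise InputError(f"unknown window mode {window!r}")
        slope, _, r2 = _ols_line(self.times[lo:hi], self.masses[lo:hi])
        mass_gain = slope > 0
        if mass_gain:
            warnings.warn(
                "mass increases over the fit window; water-loss rate is negative",
                stacklevel=2,
            )
        return WaterLossFit(slope_g_s=-slope, window=(lo, hi), r2=r2, mass_gain=mass_gain)

    def fit(self, window: Literal["full", "auto"] = "full", min_window: int = 5) -> "GminResult":
        """Estimate g_min (area- and mass-normalized) for this curve.

        The water-loss slope (g s⁻¹) is converted to mmol s⁻¹ (÷ molar
        mass of water, × 1000), normalized by projected area or dry mass,
        and multiplied by P_atm / mean VPD, where the VPD is averaged over
        the weighings inside the fit window.
        """
        wl = self.water_loss_rate(window=window, min_window=min_window)
        lo, hi = wl.window
        mean_vpd = float(np.mean(self.vpds()[lo:hi]))
        if mean_vpd < 1e-9:
            raise ComputationError("mean VPD ~ 0 (saturated air): g_min undefined")
        wl_mmol = wl.slope_g_s / MOLAR_MASS_WATER * 1000.0
        factor = self.p_atm / mean_vpd
        return GminResult(
            g_min_area=wl_mmol / self.projected_area * factor,
            g_min_mass=wl_mmol / self.dry_mass * factor,
            wl_slope=wl.slope_g_s,
            fit_window=wl.window,
            r2=wl.r2,
            mean_vpd=mean_vpd,
            mass_gain=wl.mass_gain,
        )

    def plot(self, ax=None, result: "GminResult | None" = None):
        """Mass-vs-time diagnostic plot with the fitted window highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times / 60.0, self.masses, "o", color="0.4")
        if result is not None:
            lo, hi = result.fit_window
            t = self.times[lo:hi]
            ax.plot(t / 60.0, self.masses[lo:hi].mean() - result.wl_slope * (t - t.mean()), "-")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("mass (g)")
        return ax


@dataclass(frozen=True)
class WaterLossFit:
    slope_g_s: float          # positive when mass declines
    window: tuple
    r2: float
    mass_gain: bool


@dataclass(frozen=True)
class GminResult:
    """Minimum diffusive conductance estimates for one drying curve."""

    g_min_area: float   # mmol m^-2 s^-1
    g_min_mass: float   # mmol g^-1 s^-1
    wl_slope: float     # g s^-1, positive loss
    fit_window: tuple
    r2: float
    mean_vpd: float     # kPa
    mass_gain: bool

    def summary(self) -> str:
        lo, hi = self.fit_window
        lines = [
            "Minimum diffusive conductance fit",
            "---------------------------------",
            f"g_min (area basis) : {self.g_min_area:10.4f} mmol m^-2 s^-1",
            f"g_min (mass basis) : {self.g_min_mass:10.6f} mmol g^-1 s^-1",
            f"water-loss slope   : {self.wl_slope:10.3e} g s^-1",
            f"fit window         : points {lo}..{hi - 1} (r2 = {self.r2:.4f})",
            f"mean VPD           : {self.mean_vpd:10.4f} kPa",
        ]
        if self.mass_gain:
            lines.append("WARNING: mass increased over the fit window")
        return "\n".join(lines)


def water_loss_rate(curve: DryingCurve, window: str = "full", min_window: int = 5) -> WaterLossFit:
    """Functional wrapper around :meth:`DryingCurve.water_loss_rate`."""
    return curve.water_loss_rate(window=window, min_window=min_window)


def gmin(curve: DryingCurve, window: str = "full", min_window: int = 5) -> GminResult:
    """Functional wrapper around :meth:`DryingCurve.fit`."""
    return curve.fit(window=window, min_window=min_window)
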
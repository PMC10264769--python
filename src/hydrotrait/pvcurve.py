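"""Pressure-volume curve analysis on a dry-mass basis.

A pressure-volume (PV) curve records bulk water potential Ψ (MPa,
negative) against sample mass as an organ dehydrates.  Above the turgor
loss point (TLP) the measured Ψ is the sum of an osmotic component and a
positive turgor component; below the TLP turgor is zero and Ψ is purely
osmotic, so the transformed variable −1/Ψ becomes linear in the
cumulative water deficit (Tyree-Hammel analysis).  The fit locates the
TLP as the breakpoint that maximizes linearity of the post-TLP segment
and extracts:

* ``swc``      saturated water content, (sat_mass − dry_mass)/dry_mass, g g⁻¹
* ``psi_sft``  osmotic potential at full turgor, −1/(intercept of the
  post-TLP line at zero deficit), MPa
* ``psi_tlp``  water potential at the turgor loss point, from the fitted
  line evaluated at the breakpoint deficit, MPa
* ``c_t``      absolute capacitance at full turgor: slope of water
  content (mol per kg dry mass) against Ψ over the pre-TLP segment,
  mol kg⁻¹ MPa⁻¹ (a post-TLP capacitance is reported as a diagnostic)

All quantities are expressed per unit dry mass because the surface area
of a wilted flower cannot be measured reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .drying import MOLAR_MASS_WATER, _ols_line
from .exceptions import FitError, InputError

__all__ = ["PVCurve", "PVParameters", "SaturatedMass", "swc", "fit_pv", "saturated_mass"]


@dataclass
class PVCurve:
    """Ordered (mass, water potential) observations for one sample.

    ``masses`` (g) and ``psis`` (MPa, all negative) are stored in drying
    order (first point most hydrated).  Mild non-monotonicity from
    measurement noise is tolerated with a warning; hard validation covers
    point count (≥6), sign of Ψ, and masses exceeding ``dry_mass``.
    """

    masses: Sequence[float]
    psis: Sequence[float]
    dry_mass: float

    def __post_init__(self):
        self.masses = np.asarray(self.masses, float)
        self.psis = np.asarray(self.psis, float)
        if self.masses.size != self.psis.size:
            raise InputError("masses and psis must have equal length")
        if self.masses.size < 6:
            raise InputError("PV curve needs at least 6 points")
        if not np.all(np.isfinite(self.masses)) or not np.all(np.isfinite(self.psis)):
            raise InputError("masses and psis must be finite")
        if np.any(self.psis >= 0):
            raise InputError("water potentials must be negative (MPa)")
        if self.dry_mass <= 0:
            raise InputError("dry mass must be positive")
        if np.any(self.masses <= self.dry_mass):
            raise InputError("all masses must exceed dry mass")
        if np.any(np.diff(self.masses) > 1e-9) or np.any(np.diff(self.psis) > 0.2):
            warnings.warn("PV curve is not monotone in drying order", stacklevel=2)

    @property
    def n_obs(self) -> int:
        return int(self.masses.size)

    # -- saturated mass ------------------------------------------------
    def saturated_mass(self, correct: bool = False, max_head: int = 3) -> "SaturatedMass":
        """Saturated (fully hydrated) mass, optionally plateau-corrected.

        Default: the maximum observed mass.  With ``correct=True`` the
        initial linear region of mass vs Ψ is extrapolated to Ψ = 0 and
        the intercept used instead; leading points are dropped (up to
        ``max_head``) when doing so improves linearity, which corrects
        the oversaturation plateau seen in samples rehydrated past
        saturation.
        """
        m_max = float(np.max(self.masses))
        if not correct:
            return SaturatedMass(value=m_max, corrected=False, fallback=False, head_dropped=0)
        n = self.n_obs
        win = max(3, min(5, n - 2))
        if n - 0 < 3:  # unreachable with n >= 6; kept for safety
            return SaturatedMass(value=m_max, corrected=False, fallback=True, head_dropped=0)
        best = None
        for j in range(0, min(max_head, n - win) + 1):
            seg = slice(j, j + win)
            try:
                slope, intercept, r2 = _ols_line(self.psis[seg], self.masses[seg])
            except InputError:
                continue
            if best is None or r2 > best[0] + 1e-12:
                best = (r2, j, slope, intercept)
        if best is None:
            return SaturatedMass(value=m_max, corrected=False, fallback=True, head_dropped=0)
        r2, j, slope, intercept = best
        sat = float(intercept)  # mass at psi = 0
        if sat <= self.dry_mass:
            return SaturatedMass(value=m_max, corrected=False, fallback=True, head_dropped=0)
        plateau = j > 0 or sat < m_max * (1 - 1e-9)
        return SaturatedMass(value=sat, corrected=plateau, fallback=False, head_dropped=j, r2=r2)

    # -- full fit ------------------------------------------------------
    def fit(
        self,
        plateau_correct: bool = False,
        min_segment: int = 3,
        degenerate_r2: float = 0.9995,
    ) -> "PVParameters":
        """Extract PV parameters (see module docstring for the model).

        The breakpoint is found by exhaustive search over all admissible
        splits with at least ``min_segment`` points on each side,
        maximizing r² of the post-TLP line (−1/Ψ vs deficit); ties break
        toward the more hydrated split.  If the whole curve is already
        linear to ``degenerate_r2`` the sample is treated as purely
        osmotic (no turgor phase): the breakpoint is flagged at the first
        point and Ψ_sft comes from the whole-curve line.
        """
        n = self.n_obs
        sat = self.saturated_mass(correct=plateau_correct)
        deficit = sat.value - self.masses  # g water lost since saturation
        y = -1.0 / self.psis              # positive, MPa^-1

        # post-TLP, -1/psi declines linearly with deficit: negative slope,
        # intercept 1/|psi_sft| at zero deficit
        slope_all, int_all, r2_all = _ols_line(deficit, y)
        if r2_all >= degenerate_r2 and int_all > 0 and slope_all <= 0:
            return self._assemble(
                sat, deficit, b=0, slope=slope_all, intercept=int_all,
                r2_post=r2_all, no_turgor=True,
            )

        candidates = []
        for b in range(min_segment, n - min_segment + 1):
            s, c, r2 = _ols_line(deficit[b:], y[b:])
            candidates.append((b, s, c, r2))
        if not candidates:
            raise FitError("curve too short for a breakpoint search")
        best = None
        for b, s, c, r2 in candidates:
            if best is None or r2 > best[3] + 1e-12:
                best = (b, s, c, r2)
        b, slope, intercept, r2_post = best
        if intercept <= 0 or slope > 0 or intercept + slope * deficit[b] <= 0:
            raise FitError(
                "no admissible turgor-loss breakpoint: post-segment line has "
                f"intercept {intercept:.4g} and slope {slope:.4g}",
                diagnostics={"candidates": candidates},
            )
        return self._assemble(sat, deficit, b, slope, intercept, r2_post, no_turgor=False)

    def _assemble(self, sat, deficit, b, slope, intercept, r2_post, no_turgor):
        psi_sft = -1.0 / intercept
        psi_tlp = -1.0 / (intercept + slope * deficit[b])
        # water content in mol per kg dry mass
        content = (self.masses - self.dry_mass) / MOLAR_MASS_WATER / (self.dry_mass / 1000.0)
        pre = slice(0, b) if not no_turgor else slice(0, self.n_obs)
        post = slice(b, self.n_obs)
        if (pre.stop - pre.start) >= 3:
            c_t, _, r2_pre = _ols_line(self.psis[pre], content[pre])
        else:
            c_t, r2_pre = float("nan"), float("nan")
        if (post.stop - post.start) >= 3:
            c_t_post, _, _ = _ols_line(self.psis[post], content[post])
        else:
            c_t_post = float("nan")
        diagnostics = self._diagnostics(deficit, slope, intercept, b, sat, no_turgor)
        return PVParameters(
            swc=(sat.value - self.dry_mass) / self.dry_mass,
            psi_sft=float(psi_sft),
            psi_tlp=float(psi_tlp),
            c_t=float(abs(c_t)),
            c_t_post=float(abs(c_t_post)),
            tlp_index=int(b),
            sat_mass=float(sat.value),
            sat_corrected=bool(sat.corrected),
            r2_post=float(r2_post),
            r2_pre=float(r2_pre),
            no_turgor=bool(no_turgor),
            diagnostics=diagnostics,
        )

    def _diagnostics(self, deficit, slope, intercept, b, sat, no_turgor) -> dict:
        """Internal elastic/apoplastic diagnostics (not headline outputs)."""
        out = {}
        if slope < 0:
            w_sym = -intercept / slope  # deficit at which -1/psi extrapolates to 0
            total_water = sat.value - self.dry_mass
            out["symplastic_water_g"] = float(w_sym)
            out["apoplastic_fraction"] = float(max(0.0, 1.0 - w_sym / total_water))
            if not no_turgor and b >= 3:
                # turgor = measured psi minus osmotic component from the fitted line
                psi_s = -1.0 / (intercept + slope * deficit[:b])
                psi_p = self.psis[:b] - psi_s
                r_sym = 1.0 - deficit[:b] / w_sym
                try:
                    eps, _, _ = _ols_line(r_sym, psi_p)
                    out["elastic_modulus"] = float(eps)
                except InputError:
                    pass
        return out

    def plot(self, ax=None, result: "PVParameters | None" = None):
        """−1/Ψ vs cumulative deficit with the fitted post-TLP line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sat = result.sat_mass if result is not None else float(np.max(self.masses))
        deficit = sat - self.masses
        ax.plot(deficit, -1.0 / self.psis, "o", color="0.4")
        if result is not None:
            b = result.tlp_index
            c = -1.0 / result.psi_sft
            s, _, _ = _ols_line(deficit[b:], (-1.0 / self.psis)[b:]) if self.n_obs - b >= 3 else (0, 0, 0)
            ax.plot(deficit, c + s * deficit, "-")
            ax.axvline(deficit[b], ls=":", color="0.6")
        ax.set_xlabel("cumulative water deficit (g)")
        ax.set_ylabel(r"$-1/\Psi$ (MPa$^{-1}$)")
        return ax


@dataclass(frozen=True)
class SaturatedMass:
    value: float
    corrected: bool
    fallback: bool
    head_dropped: int
    r2: float = float("nan")


@dataclass(frozen=True)
class PVParameters:
    """Pressure-volume parameters extracted from one curve."""

    swc: float          # g g^-1
    psi_sft: float      # MPa
    psi_tlp: float      # MPa
    c_t: float          # mol kg^-1 MPa^-1, pre-TLP
    c_t_post: float     # mol kg^-1 MPa^-1, post-TLP (diagnostic)
    tlp_index: int
    sat_mass: float     # g
    sat_corrected: bool
    r2_post: float
    r2_pre: float
    no_turgor: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.no_turgor and self.psi_tlp > self.psi_sft + 1e-9:
            warnings.warn("fitted psi_tlp is less negative than psi_sft", stacklevel=2)

    def summary(self) -> str:
        lines = [
            "Pressure-volume fit",
            "-------------------",
            f"SWC                : {self.swc:8.3f} g g^-1",
            f"psi_sft            : {self.psi_sft:8.3f} MPa",
            f"psi_tlp            : {self.psi_tlp:8.3f} MPa",
            f"C_T (pre-TLP)      : {self.c_t:8.3f} mol kg^-1 MPa^-1",
            f"C_T (post-TLP)     : {self.c_t_post:8.3f} mol kg^-1 MPa^-1",
            f"saturated mass     : {self.sat_mass:8.4f} g"
            + ("  (plateau-corrected)" if self.sat_corrected else ""),
            f"TLP breakpoint     : point {self.tlp_index} (post r2 = {self.r2_post:.4f})",
        ]
        if self.no_turgor:
            lines.append("NOTE: curve linear throughout; treated as purely osmotic")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# functional wrappers


def saturated_mass(curve: PVCurve, correct: bool = False) -> SaturatedMass:
    """Saturated mass of a PV curve; see :meth:`PVCurve.saturated_mass`."""
    return curve.saturated_mass(correct=correct)


def swc(curve: PVCurve, sat_mass: float) -> float:
    """Saturated water content (sat_mass − dry_mass)/dry_mass, g g⁻¹."""
    if sat_mass <= curve.dry_mass:
        raise InputError("saturated mass must exceed dry mass")
    return (sat_mass - curve.dry_mass) / curve.dry_mass


def fit_pv(curve: PVCurve, plateau_correct: bool = False) -> PVParameters:
    """Extract PV parameters; see :meth:`PVCurve.fit`."""
    return curve.fit(plateau_correct=plateau_correct)
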
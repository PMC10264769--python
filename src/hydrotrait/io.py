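"""CSV readers for the long-format measurement files.

Schemas (all plain CSV, strict unit suffixes in column names):

* drying curves: ``sample_id, time_s, mass_g, temp_c, rh_pct`` with a
  companion metadata file ``sample_id, species, organ, area_m2,
  dry_mass_g[, p_atm_kpa]``
* PV curves: ``sample_id, step, mass_g, psi_mpa`` with metadata
  ``sample_id, species, organ, dry_mass_g``
* vessels: one row per vessel: ``sample_id, d_long_um, d_short_um`` (or a
  precomputed ``diameter_um``), plus per-sample ``image_area_mm2`` and
  optional ``t_w_um`` wall-thickness rows
* pits: one row per pit: ``sample_id, d_pml_um, d_pms_um, d_pal_um,
  d_pas_um, a_pit_um2, a_pa_um2``; counts: ``sample_id, n_pits,
  wall_area_um2``
* stomata: one row per stoma: ``sample_id, x_um, y_um[, area_um2]`` plus
  per-sample ``field_width_um, field_height_um``
* trait tables: long format ``species, organ, trait, mean[, se, n]``
"""

from __future__ import annotations

import pandas as pd

from .anatomy import PitMorphology, StomatalField, VesselSection, equivalent_circular_diameter
from .drying import DryingCurve
from .exceptions import InputError
from .pvcurve import PVCurve

__all__ = [
    "read_drying_curves",
    "read_pv_curves",
    "read_vessel_sections",
    "read_pits",
    "read_stomatal_fields",
]


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{what} is missing columns {missing}")


def read_drying_curves(curves_csv, meta_csv) -> dict:
    """Read drying curves; returns {sample_id: (DryingCurve, meta dict)}."""
    curves = pd.read_csv(curves_csv)
    meta = pd.read_csv(meta_csv)
    _require(curves, ["sample_id", "time_s", "mass_g", "temp_c", "rh_pct"], "drying curve file")
    _require(meta, ["sample_id", "species", "organ", "area_m2", "dry_mass_g"], "drying metadata")
    meta = meta.set_index("sample_id")
    out = {}
    for sid, grp in curves.groupby("sample_id"):
        if sid not in meta.index:
            raise InputError(f"sample {sid!r} has no metadata row")
        m = meta.loc[sid]
        grp = grp.sort_values("time_s")
        curve = DryingCurve(
            times=grp["time_s"].to_numpy(),
            masses=grp["mass_g"].to_numpy(),
            temps=grp["temp_c"].to_numpy(),
            rhs=grp["rh_pct"].to_numpy(),
            projected_area=float(m["area_m2"]),
            dry_mass=float(m["dry_mass_g"]),
            p_atm=float(m.get("p_atm_kpa", 101.3)),
        )
        out[sid] = (curve, {"species": m["species"], "organ": m["organ"]})
    return out


def read_pv_curves(pv_csv, meta_csv) -> dict:
    """Read PV curves; returns {sample_id: (PVCurve, meta dict)}."""
    pv = pd.read_csv(pv_csv)
    meta = pd.read_csv(meta_csv)
    _require(pv, ["sample_id", "step", "mass_g", "psi_mpa"], "PV curve file")
    _require(meta, ["sample_id", "species", "organ", "dry_mass_g"], "PV metadata")
    meta = meta.set_index("sample_id")
    out = {}
    for sid, grp in pv.groupby("sample_id"):
        if sid not in meta.index:
            raise InputError(f"sample {sid!r} has no metadata row")
        m = meta.loc[sid]
        grp = grp.sort_values("step")
        curve = PVCurve(
            masses=grp["mass_g"].to_numpy(),
            psis=grp["psi_mpa"].to_numpy(),
            dry_mass=float(m["dry_mass_g"]),
        )
        out[sid] = (curve, {"species": m["species"], "organ": m["organ"]})
    return out


def read_vessel_sections(vessels_csv, sections_csv) -> dict:
    """Read vessel measurements; returns {sample_id: VesselSection}.

    ``vessels_csv`` has one row per vessel with either ``diameter_um`` or
    the pair ``d_long_um, d_short_um`` (converted with the area-preserving
    equivalent circular diameter).  ``sections_csv`` has one row per
    sample: ``sample_id, image_area_mm2`` and optionally a ``t_w_um``
    column listing wall thicknesses in a separate per-row file layout.
    """
    vessels = pd.read_csv(vessels_csv)
    sections = pd.read_csv(sections_csv)
    _require(sections, ["sample_id", "image_area_mm2"], "sections file")
    sections = sections.set_index("sample_id")
    out = {}
    for sid, grp in vessels.groupby("sample_id"):
        if "diameter_um" in grp.columns and grp["diameter_um"].notna().any():
            d = grp["diameter_um"].dropna().to_numpy()
        else:
            _require(grp, ["d_long_um", "d_short_um"], "vessels file")
            d = equivalent_circular_diameter(grp["d_long_um"].to_numpy(), grp["d_short_um"].to_numpy())
        tw = grp["t_w_um"].dropna().to_numpy() if "t_w_um" in grp.columns else []
        out[sid] = VesselSection(
            vessel_diameters=d,
            image_area=float(sections.loc[sid, "image_area_mm2"]),
            wall_thickness_pairs=tw,
        )
    return out


def read_pits(pits_csv, counts_csv=None) -> dict:
    """Read per-pit SEM measurements; returns {sample_id: PitMorphology}."""
    pits = pd.read_csv(pits_csv)
    cols = ["sample_id", "d_pml_um", "d_pms_um", "d_pal_um", "d_pas_um", "a_pit_um2", "a_pa_um2"]
    _require(pits, cols, "pits file")
    counts = None
    if counts_csv is not None:
        counts = pd.read_csv(counts_csv)
        _require(counts, ["sample_id", "n_pits", "wall_area_um2"], "pit counts file")
    out = {}
    for sid, grp in pits.groupby("sample_id"):
        pc = []
        if counts is not None:
            sub = counts[counts["sample_id"] == sid]
            pc = list(zip(sub["n_pits"], sub["wall_area_um2"]))
        out[sid] = PitMorphology(
            d_pml=grp["d_pml_um"].to_numpy(), d_pms=grp["d_pms_um"].to_numpy(),
            d_pal=grp["d_pal_um"].to_numpy(), d_pas=grp["d_pas_um"].to_numpy(),
            a_pit=grp["a_pit_um2"].to_numpy(), a_pa=grp["a_pa_um2"].to_numpy(),
            pit_counts=pc,
        )
    return out


def read_stomatal_fields(stomata_csv, fields_csv) -> dict:
    """Read stomatal annotations; returns {sample_id: StomatalField}."""
    stomata = pd.read_csv(stomata_csv)
    fields = pd.read_csv(fields_csv)
    _require(stomata, ["sample_id", "x_um", "y_um"], "stomata file")
    _require(fields, ["sample_id", "field_width_um", "field_height_um"], "fields file")
    fields = fields.set_index("sample_id")
    out = {}
    for sid in fields.index:
        grp = stomata[stomata["sample_id"] == sid]
        areas = grp["area_um2"].dropna().to_numpy() if "area_um2" in grp.columns else []
        out[sid] = StomatalField(
            centroids=grp[["x_um", "y_um"]].to_numpy(),
            field_width=float(fields.loc[sid, "field_width_um"]),
            field_height=float(fields.loc[sid, "field_height_um"]),
            stomatal_areas=areas,
        )
    return out
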
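"""Synthetic study generator with known ground truth.

Emulates a flower-vs-leaf hydraulic trait study: 10 species on an
ultrametric phylogeny, two organs per species, a 24-trait panel,
bench drying curves (~10 timed weighings) and pressure-volume curves
(~8-15 points with a pre/post turgor-loss regime change).  Every
generator is deterministic under a fixed seed and returns the generating
parameters alongside the data, so each analysis stage can be tested as a
parameter-recovery problem.

Traits are generated on the log scale (positivity-constrained traits are
lognormal; water potentials are negated lognormal magnitudes).  Species
effects evolve under correlated Brownian motion on the tree and are
shared between organs; organ identity adds a fixed log-scale offset plus
an independent organ-specific deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .drying import MOLAR_MASS_WATER, DryingCurve, vpd
from .exceptions import InputError
from .phylo import Phylogeny
from .pvcurve import PVCurve
from .comparative import TraitTable

__all__ = [
    "TRAIT_MEANS",
    "NEGATIVE_TRAITS",
    "StudyDesign",
    "StudyData",
    "simulate_tree",
    "simulate_traits",
    "simulate_drying_curve",
    "simulate_pv_curve",
    "simulate_study",
    "write_study",
]

# Illustrative per-organ trait centers (natural units), loosely matching
# the magnitudes reported for subtropical angiosperm flowers and leaves.
# These are study-condition defaults, not measured ground truth.
TRAIT_MEANS: dict = {
    #                     flower   leaf
    "gmin_area":         (12.0,    4.0),    # mmol m^-2 s^-1
    "gmin_mass":         (0.35,    0.06),   # mmol g^-1 s^-1
    "k_th":              (0.30,    0.50),   # kg m^-1 MPa^-1 s^-1
    "c_t":               (3.5,     0.6),    # mol kg^-1 MPa^-1
    "swc":               (5.0,     1.5),    # g g^-1
    "psi_sft":           (-0.8,   -1.5),    # MPa
    "psi_tlp":           (-1.0,   -1.9),    # MPa
    "d_pml":             (4.0,     4.5),    # um
    "d_pms":             (3.0,     3.4),    # um
    "d_pal":             (1.7,     1.8),    # um
    "d_pas":             (1.05,    1.1),    # um
    "a_pit":             (9.4,     13.3),   # um^2
    "a_pa":              (1.5,     1.6),    # um^2
    "r_pa":              (1.65,    1.7),
    "r_pit":             (1.35,    1.35),
    "d_p":               (0.052,   0.045),  # no. um^-2
    "s_s":               (500.0,   450.0),  # um^2
    "d_s":               (15.0,    250.0),  # no. mm^-2
    "d_v":               (2.0,     6.0),    # mm mm^-2
    "thickness":         (400.0,   250.0),  # um (FT / LT)
    "d_h":               (16.0,    18.0),   # um
    "t_w":               (2.2,     2.5),    # um
    "vf":                (45.0,    60.0),   # no. mm^-2
}

NEGATIVE_TRAITS = ("psi_sft", "psi_tlp")


@dataclass
class StudyDesign:
    """Study-condition parameters for the synthetic trait generator.

    ``sigma_phylo`` is the log-scale Brownian-motion standard deviation
    across species at the tips of a depth-1 tree (shared between organs);
    ``sigma_organ`` is the log-scale organ-specific deviation; ``noise_sd``
    is log-scale measurement noise on species-organ means.
    ``trait_correlations`` lists (trait_a, trait_b, rho) entries overlaid
    on an identity correlation matrix for the Brownian component.
    """

    n_species: int = 10
    organs: tuple = ("flower", "leaf")
    trait_means: Mapping[str, tuple] = dc_field(default_factory=lambda: dict(TRAIT_MEANS))
    sigma_phylo: float = 0.25
    sigma_organ: float = 0.12
    noise_sd: float = 0.05
    trait_correlations: Sequence[tuple] = dc_field(
        default_factory=lambda: [("gmin_mass", "c_t", 0.7), ("gmin_area", "c_t", 0.6),
                                 ("a_pit", "a_pa", 0.8), ("d_p", "a_pit", -0.6)]
    )
    astomatous_flowers: int = 2

    @property
    def traits(self) -> list:
        return list(self.trait_means)

    def correlation_matrix(self) -> np.ndarray:
        traits = self.traits
        idx = {t: i for i, t in enumerate(traits)}
        R = np.eye(len(traits))
        for a, b, rho in self.trait_correlations:
            if a not in idx or b not in idx:
                raise InputError(f"correlation names unknown trait: {(a, b)}")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = float(rho)
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise InputError("trait correlation matrix is not positive semidefinite")
        return R


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# tree


def simulate_tree(n_tips: int, seed=None, birth_rate: float = 1.0) -> Phylogeny:
    """Simulate an ultrametric pure-birth (Yule) tree with labeled tips.

    Lineages split at rate ``birth_rate`` each; after the last split the
    process runs for one more exponential waiting time so terminal
    branches are strictly positive.  Tips are labeled ``sp01``, ``sp02``,
    ... in left-to-right order.  Deterministic under ``seed``.
    """
    if n_tips < 2:
        raise InputError("need at least 2 tips")
    rng = _rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0

    t = 0.0
    birth = {}
    c1 = tree.seed_node.new_child()
    c2 = tree.seed_node.new_child()
    birth[c1] = birth[c2] = 0.0
    active = [c1, c2]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth[node]
        k1 = node.new_child()
        k2 = node.new_child()
        birth[k1] = birth[k2] = t
        active.extend([k1, k2])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.edge.length = t_end - birth[node]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:02d}")
    return Phylogeny(tree)


# ----------------------------------------------------------------------
# traits


def simulate_traits(design: StudyDesign, tree: Phylogeny, seed=None):
    """Simulate a species × organ trait table on a tree.

    Returns ``(TraitTable, truth)``.  ``truth`` records the log-scale
    organ offsets, the Brownian species deviations, and the generator
    settings needed for recovery tests.
    """
    rng = _rng(seed)
    labels, C = tree.vcv()
    if len(labels) != design.n_species:
        raise InputError(
            f"tree has {len(labels)} tips but design expects {design.n_species} species"
        )
    depth = float(np.max(np.diag(C)))
    C_norm = C / depth  # unit-depth tree so sigma_phylo is the tip-level sd
    R = design.correlation_matrix()
    traits = design.traits
    n_sp, n_tr = len(labels), len(traits)

    L_C = np.linalg.cholesky(C_norm + 1e-12 * np.eye(n_sp))
    # eigendecomposition handles PSD-but-singular correlation matrices
    w, V = np.linalg.eigh(R)
    L_R = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Z = rng.standard_normal((n_sp, n_tr))
    species_dev = design.sigma_phylo * (L_C @ Z @ L_R.T)  # shared between organs

    astomatous = []
    if design.astomatous_flowers:
        astomatous = sorted(
            rng.choice(labels, size=min(design.astomatous_flowers, n_sp), replace=False).tolist()
        )

    rows = []
    for oi, organ in enumerate(design.organs):
        organ_dev = design.sigma_organ * rng.standard_normal((n_sp, n_tr))
        noise = design.noise_sd * rng.standard_normal((n_sp, n_tr))
        for si, sp in enumerate(labels):
            row = {"species": sp, "organ": organ}
            for ti, trait in enumerate(traits):
                center = design.trait_means[trait][0 if organ == "flower" else 1]
                log_val = (
                    np.log(abs(center))
                    + species_dev[si, ti] + organ_dev[si, ti] + noise[si, ti]
                )
                val = float(np.exp(log_val))
                if trait in NEGATIVE_TRAITS:
                    val = -val
                if organ == "flower" and sp in astomatous and trait in ("s_s", "d_s"):
                    val = float("nan")
                row[trait] = val
            rows.append(row)
    wide = pd.DataFrame(rows).set_index(["species", "organ"])
    truth = {
        "traits": traits,
        "species": labels,
        "sigma_phylo": design.sigma_phylo,
        "sigma_organ": design.sigma_organ,
        "noise_sd": design.noise_sd,
        "astomatous_flowers": astomatous,
        "log_offsets": {
            t: float(np.log(abs(design.trait_means[t][0])) - np.log(abs(design.trait_means[t][1])))
            for t in traits
        },
    }
    return TraitTable(wide), truth


# ----------------------------------------------------------------------
# drying curves


def simulate_drying_curve(
    g_true: float,
    area: float,
    dry_mass: float,
    temp: float = 25.0,
    rh: float = 50.0,
    n_points: int = 10,
    noise_sd: float = 1e-4,
    seed=None,
    dt: float = 600.0,
    p_atm: float = 101.3,
    initial_water_ratio: float = 2.0,
) -> DryingCurve:
    """Invert the g_min equation to produce a drying curve.

    Mass declines linearly at WL = g_true·area·VPD/P_atm (converted from
    mmol s⁻¹ to g s⁻¹), sampled every ``dt`` seconds with Gaussian
    weighing noise.  ``g_true`` is the area-normalized conductance in
    mmol m⁻² s⁻¹.  If the series would dip below dry mass it is
    truncated with a warning.
    """
    if g_true <= 0:
        raise InputError("g_true must be positive")
    if not (0 <= rh < 100):
        raise InputError("RH must be in [0, 100) for a drying curve")
    rng = _rng(seed)
    times = np.arange(n_points) * dt
    v = vpd(temp, rh)
    wl_g_s = g_true * area * (v / p_atm) * MOLAR_MASS_WATER / 1000.0
    m0 = dry_mass * (1.0 + initial_water_ratio)
    masses = m0 - wl_g_s * times + rng.normal(0.0, noise_sd, size=n_points)
    ok = masses > dry_mass
    if not np.all(ok):
        n_keep = int(np.argmin(ok))  # first failure index
        if n_keep < 3:
            raise InputError("parameters exhaust the sample's water within 3 weighings")
        warnings.warn("drying curve truncated before reaching dry mass", stacklevel=2)
        times, masses = times[:n_keep], masses[:n_keep]
    n = len(times)
    return DryingCurve(
        times=times, masses=masses,
        temps=np.full(n, float(temp)), rhs=np.full(n, float(rh)),
        projected_area=area, dry_mass=dry_mass, p_atm=p_atm,
    )


# ----------------------------------------------------------------------
# PV curves


def simulate_pv_curve(
    psi_sft: float = -1.5,
    swc: float = 1.5,
    apoplastic_frac: float = 0.2,
    elastic_modulus: float | None = None,
    elastic_exponent: float = 1.0,
    n_points: int = 12,
    noise_sd: float = 0.02,
    dry_mass: float = 1.0,
    seed=None,
):
    """Generate a PV curve from the standard osmotic + turgor model.

    Symplastic relative water content R_s declines from ~1; the osmotic
    component follows the van't Hoff dilution law Ψ_s = psi_sft / R_s,
    while turgor declines from −psi_sft at saturation to zero at the
    turgor loss point R_tlp = 1 + psi_sft/ε (ε = ``elastic_modulus``,
    default 5·|psi_sft|), with shape Ψ_p = −psi_sft·((R_s−R_tlp)/(1−R_tlp))^k
    where k = ``elastic_exponent``.  The apoplastic fraction holds water
    that does not dilute the symplast.  Gaussian noise of ``noise_sd``
    MPa is added to the water potentials.

    Returns ``(PVCurve, truth)`` with the generating psi_sft, psi_tlp,
    saturated mass and R_tlp in ``truth``.
    """
    if psi_sft >= 0:
        raise InputError("psi_sft must be negative")
    if not (0 <= apoplastic_frac < 1):
        raise InputError("apoplastic fraction must lie in [0, 1)")
    if elastic_modulus is None:
        elastic_modulus = 5.0 * abs(psi_sft)
    if elastic_modulus <= abs(psi_sft):
        raise InputError("elastic modulus must exceed |psi_sft| (R_tlp must be < 1)")
    rng = _rng(seed)
    r_tlp = 1.0 + psi_sft / elastic_modulus
    # sample well past the TLP, but keep potentials finite even for nearly
    # rigid (r_tlp -> 1) or very soft (small r_tlp) tissues
    r_end = min(r_tlp - 0.6 * (1.0 - r_tlp), 0.75)
    r_end = max(r_end, 0.5 * r_tlp, 0.2)
    r_s = np.linspace(0.99, r_end, n_points)
    psi_s = psi_sft / r_s
    turgor = np.where(
        r_s > r_tlp,
        -psi_sft * np.clip((r_s - r_tlp) / (1.0 - r_tlp), 0.0, None) ** elastic_exponent,
        0.0,
    )
    psi = psi_s + turgor + rng.normal(0.0, noise_sd, size=n_points)
    psi = np.minimum(psi, -0.01)  # keep potentials strictly negative
    r_tot = apoplastic_frac + (1.0 - apoplastic_frac) * r_s
    masses = dry_mass * (1.0 + swc * r_tot)
    curve = PVCurve(masses=masses, psis=psi, dry_mass=dry_mass)
    truth = {
        "psi_sft": psi_sft,
        "psi_tlp": psi_sft / r_tlp,
        "r_tlp": r_tlp,
        "swc": swc,
        "sat_mass": dry_mass * (1.0 + swc),
        "apoplastic_frac": apoplastic_frac,
        "elastic_modulus": elastic_modulus,
        "elastic_exponent": elastic_exponent,
    }
    return curve, truth


# ----------------------------------------------------------------------
# full study


ORGAN_GEOMETRY = {
    # projected area (m^2) and dry mass (g) used for simulated samples
    "flower": {"area": 20e-4, "dry_mass": 0.45},
    "leaf": {"area": 15e-4, "dry_mass": 0.25},
}


@dataclass
class StudyData:
    """In-memory bundle of one synthetic study."""

    tree: Phylogeny
    traits: TraitTable
    drying_curves: dict          # (species, organ) -> DryingCurve
    pv_curves: dict              # (species, organ) -> PVCurve
    truth: dict
    seed: int | None = None


def simulate_study(design: StudyDesign | None = None, seed=None) -> StudyData:
    """Simulate a complete study: tree, trait table, drying and PV curves.

    Drying and PV curves are generated per species-organ sample from the
    trait table's own gmin_area, psi_sft and SWC values, so the pipeline
    can re-derive those traits from raw curves and reproduce the
    generating organ contrasts.
    """
    design = design or StudyDesign()
    ss = np.random.SeedSequence(seed)
    tree_seed, trait_seed, curve_seed = [int(s) for s in ss.generate_state(3) >> 1]
    tree = simulate_tree(design.n_species, seed=tree_seed)
    traits, truth = simulate_traits(design, tree, seed=trait_seed)
    rng = _rng(curve_seed)

    drying_curves, pv_curves = {}, {}
    sample_truth = {}
    for (sp, organ), row in traits.wide.iterrows():
        geom = ORGAN_GEOMETRY[organ]
        g_true = float(row["gmin_area"])
        drying_curves[(sp, organ)] = simulate_drying_curve(
            g_true=g_true, area=geom["area"], dry_mass=geom["dry_mass"],
            seed=int(rng.integers(2**31)),
        )
        psi_sft = float(row["psi_sft"])
        swc_val = float(row["swc"])
        pv_curves[(sp, organ)], pv_truth = simulate_pv_curve(
            psi_sft=psi_sft, swc=swc_val, apoplastic_frac=0.2,
            dry_mass=geom["dry_mass"], seed=int(rng.integers(2**31)),
        )
        sample_truth[f"{sp}:{organ}"] = {"gmin_area": g_true, **pv_truth}
    truth = {**truth, "samples": sample_truth}
    return StudyData(
        tree=tree, traits=traits, drying_curves=drying_curves,
        pv_curves=pv_curves, truth=truth, seed=seed,
    )


def write_study(study: StudyData, outdir) -> dict:
    """Write a study bundle as plain-text files; returns the path map.

    Files: ``tree.nwk``, ``traits.csv`` (long format), ``curves.csv`` +
    ``curves_meta.csv`` (drying), ``pv.csv`` + ``pv_meta.csv``,
    ``truth.json``.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("tree", "tree.nwk"), ("traits", "traits.csv"),
        ("curves", "curves.csv"), ("curves_meta", "curves_meta.csv"),
        ("pv", "pv.csv"), ("pv_meta", "pv_meta.csv"), ("truth", "truth.json"),
    ]}
    study.tree.write(paths["tree"])

    long_rows = []
    for (sp, organ), row in study.traits.wide.iterrows():
        for trait, val in row.items():
            long_rows.append({"species": sp, "organ": organ, "trait": trait, "mean": val})
    pd.DataFrame(long_rows).to_csv(paths["traits"], index=False)

    crows, cmeta = [], []
    for (sp, organ), curve in study.drying_curves.items():
        sid = f"{sp}:{organ}"
        for t, m, T, rh in zip(curve.times, curve.masses, curve.temps, curve.rhs):
            crows.append({"sample_id": sid, "time_s": t, "mass_g": m, "temp_c": T, "rh_pct": rh})
        cmeta.append({
            "sample_id": sid, "species": sp, "organ": organ,
            "area_m2": curve.projected_area, "dry_mass_g": curve.dry_mass,
            "p_atm_kpa": curve.p_atm,
        })
    pd.DataFrame(crows).to_csv(paths["curves"], index=False)
    pd.DataFrame(cmeta).to_csv(paths["curves_meta"], index=False)

    prows, pmeta = [], []
    for (sp, organ), curve in study.pv_curves.items():
        sid = f"{sp}:{organ}"
        for step, (m, psi) in enumerate(zip(curve.masses, curve.psis)):
            prows.append({"sample_id": sid, "step": step, "mass_g": m, "psi_mpa": psi})
        pmeta.append({
            "sample_id": sid, "species": sp, "organ": organ, "dry_mass_g": curve.dry_mass,
        })
    pd.DataFrame(prows).to_csv(paths["pv"], index=False)
    pd.DataFrame(pmeta).to_csv(paths["pv_meta"], index=False)

    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True, default=float)
    return paths
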
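"""Full-study analysis pipeline.

Given a trait table (supplied directly or re-derived from raw drying/PV
curve files) and optionally a phylogeny, the pipeline computes:

1. per-organ trait means ± SE,
2. the flower-vs-leaf paired-t table,
3. OLS and SMA fits for configured trait pairs within each organ,
4. phylogenetic independent contrast correlations — within-organ trait
   pairs and the between-organ correlation of each trait,
5. PCA variance fractions, loadings, scores and the flower/leaf convex
   hull overlap in PC1-PC2.

Outputs are written as TSV tables plus a machine-readable JSON report
(floats serialized at 6 significant digits; byte-identical across reruns
with the same config, timestamps only in the side log).
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import comparative, io as htio
from .exceptions import InputError
from .phylo import Phylogeny, pic_correlation

__all__ = ["RunConfig", "run_pipeline", "round_sig"]

REPORT_SCHEMA_VERSION = "1.0"

DEFAULT_REGRESSION_PAIRS = [
    ("gmin_mass", "psi_sft"), ("gmin_mass", "psi_tlp"), ("gmin_mass", "c_t"),
    ("gmin_area", "c_t"), ("gmin_area", "swc"),
    ("d_p", "a_pit"), ("d_p", "d_pml"), ("d_p", "d_pms"),
    ("d_p", "d_pal"), ("d_p", "d_pas"), ("d_p", "a_pa"),
    ("a_pit", "a_pa"), ("a_pit", "k_th"), ("a_pit", "t_w"), ("a_pit", "d_h"),
    ("k_th", "d_pas"), ("k_th", "d_pal"), ("d_pal", "d_h"), ("d_pal", "t_w"),
    ("r_pa", "d_h"), ("r_pa", "k_th"), ("r_pa", "swc"), ("r_pit", "d_v"),
]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    traits_csv: str | None = None
    tree_file: str | None = None
    curves_csv: str | None = None
    curves_meta_csv: str | None = None
    pv_csv: str | None = None
    pv_meta_csv: str | None = None
    out_dir: str = "hydrotrait_run"
    alpha: float = 0.05
    window: str = "full"
    plateau_correct: bool = False
    seed: int = 0
    analyses: Sequence[str] = ("means", "paired_t", "regressions", "pic", "pca")
    regression_pairs: Sequence[tuple] | None = None
    pca_traits: Sequence[str] | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must lie in (0, 1)")
        for path in (self.traits_csv, self.tree_file, self.curves_csv,
                     self.curves_meta_csv, self.pv_csv, self.pv_meta_csv):
            if path is not None and not os.path.exists(path):
                raise InputError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "regression_pairs" in data and data["regression_pairs"] is not None:
            data["regression_pairs"] = [tuple(p) for p in data["regression_pairs"]]
        return cls(**data)


def round_sig(x, digits: int = 6):
    """Round a float (or nested structure) to ``digits`` significant figures."""
    if isinstance(x, dict):
        return {k: round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [round_sig(v, digits) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if not math.isfinite(x) or x == 0.0:
            return x
        return float(f"{x:.{digits}g}")
    return x


def _derive_gmin_traits(wide: pd.DataFrame, config: RunConfig, notices: list) -> pd.DataFrame:
    samples = htio.read_drying_curves(config.curves_csv, config.curves_meta_csv)
    rows = []
    for sid, (curve, meta) in samples.items():
        res = curve.fit(window=config.window)
        rows.append({
            "species": meta["species"], "organ": meta["organ"],
            "gmin_area": res.g_min_area, "gmin_mass": res.g_min_mass,
        })
    agg = pd.DataFrame(rows).groupby(["species", "organ"]).mean()
    notices.append(f"gmin traits re-derived from {len(samples)} drying curves")
    return wide.drop(columns=agg.columns, errors="ignore").join(agg, how="outer")


def _derive_pv_traits(wide: pd.DataFrame, config: RunConfig, notices: list) -> pd.DataFrame:
    samples = htio.read_pv_curves(config.pv_csv, config.pv_meta_csv)
    rows = []
    for sid, (curve, meta) in samples.items():
        res = curve.fit(plateau_correct=config.plateau_correct)
        rows.append({
            "species": meta["species"], "organ": meta["organ"],
            "swc": res.swc, "psi_sft": res.psi_sft,
            "psi_tlp": res.psi_tlp, "c_t": res.c_t,
        })
    agg = pd.DataFrame(rows).groupby(["species", "organ"]).mean()
    notices.append(f"PV traits re-derived from {len(samples)} pressure-volume curves")
    return wide.drop(columns=agg.columns, errors="ignore").join(agg, how="outer")


def run_pipeline(config: RunConfig, data=None) -> dict:
    """Run the configured analyses and write the report bundle.

    ``data`` may be a :class:`hydrotrait.synthetic.StudyData` to run
    fully in memory (file inputs in ``config`` are then ignored).
    Returns the report dictionary that is also written to
    ``out_dir/report.json``.
    """
    notices: list = []
    failures: dict = {}

    tree = None
    if data is not None:
        wide = data.traits.wide.copy()
        tree = data.tree
        if getattr(data, "drying_curves", None):
            rows = [
                {"species": sp, "organ": organ,
                 "gmin_area": (res := curve.fit(window=config.window)).g_min_area,
                 "gmin_mass": res.g_min_mass}
                for (sp, organ), curve in data.drying_curves.items()
            ]
            agg = pd.DataFrame(rows).groupby(["species", "organ"]).mean()
            wide = wide.drop(columns=agg.columns, errors="ignore").join(agg, how="outer")
            notices.append(f"gmin traits re-derived from {len(rows)} drying curves")
        if getattr(data, "pv_curves", None):
            rows = []
            for (sp, organ), curve in data.pv_curves.items():
                res = curve.fit(plateau_correct=config.plateau_correct)
                rows.append({"species": sp, "organ": organ, "swc": res.swc,
                             "psi_sft": res.psi_sft, "psi_tlp": res.psi_tlp,
                             "c_t": res.c_t})
            agg = pd.DataFrame(rows).groupby(["species", "organ"]).mean()
            wide = wide.drop(columns=agg.columns, errors="ignore").join(agg, how="outer")
            notices.append(f"PV traits re-derived from {len(rows)} pressure-volume curves")
    else:
        if config.traits_csv is not None:
            wide = comparative.TraitTable.from_csv(config.traits_csv).wide
        else:
            wide = pd.DataFrame(
                index=pd.MultiIndex.from_arrays([[], []], names=["species", "organ"])
            )
        if config.curves_csv is not None and config.curves_meta_csv is not None:
            wide = _derive_gmin_traits(wide, config, notices)
        if config.pv_csv is not None and config.pv_meta_csv is not None:
            wide = _derive_pv_traits(wide, config, notices)
        if config.tree_file is not None:
            tree = Phylogeny.from_file(config.tree_file)
    if wide.empty:
        raise InputError("no trait data: supply traits_csv or curve files")
    wide.index = pd.MultiIndex.from_tuples(wide.index, names=["species", "organ"])
    table = comparative.TraitTable(wide)
    organs = table.organs
    paired_possible = len(organs) == 2
    if not paired_possible:
        notices.append(
            f"only organs {organs} present: paired and between-organ analyses skipped"
        )

    if tree is not None:
        tree_sp = set(tree.tip_labels)
        table_sp = set(table.species)
        if tree_sp != table_sp:
            raise InputError(
                "species mismatch between tree and trait table; "
                f"only in tree: {sorted(tree_sp - table_sp)}, "
                f"only in table: {sorted(table_sp - tree_sp)}"
            )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "alpha": config.alpha,
        "notices": notices,
        "failures": failures,
    }
    from . import __version__

    report["package_version"] = __version__
    tables: dict = {}

    # 1. organ means
    if "means" in config.analyses:
        means = table.organ_means()
        tables["organ_means"] = means
        report["organ_means"] = means.to_dict(orient="records")

    # 2. paired t
    if "paired_t" in config.analyses and paired_possible:
        rows = []
        for trait in table.traits:
            try:
                res = comparative.paired_t(table, trait, organs[0], organs[1])
                rows.append({
                    "trait": trait, "t": res.t, "p": res.p, "n": res.n,
                    "mean_diff": res.mean_diff,
                    "significant": res.p < config.alpha,
                })
            except Exception as exc:
                failures[f"paired_t:{trait}"] = str(exc)
        pt = pd.DataFrame(rows)
        tables["paired_t"] = pt
        report["paired_t"] = pt.to_dict(orient="records")
        report["paired_t_organs"] = list(organs)

    # 3. OLS + SMA regressions per organ
    if "regressions" in config.analyses:
        pairs = config.regression_pairs or [
            p for p in DEFAULT_REGRESSION_PAIRS
            if p[0] in table.traits and p[1] in table.traits
        ]
        rows = []
        for organ in organs:
            for xt, yt in pairs:
                try:
                    x = table.organ_values(xt, organ)
                    y = table.organ_values(yt, organ)
                    o = comparative.ols(x, y)
                    s = comparative.sma(x, y)
                    rows.append({
                        "organ": organ, "x": xt, "y": yt, "n": o.n,
                        "ols_slope": o.slope, "ols_intercept": o.intercept,
                        "ols_r2": o.r2, "ols_p": o.p,
                        "sma_slope": s.slope, "sma_intercept": s.intercept,
                        "sma_p": s.p,
                    })
                except Exception as exc:
                    failures[f"regression:{organ}:{xt}~{yt}"] = str(exc)
        reg = pd.DataFrame(rows)
        tables["regressions"] = reg
        report["regressions"] = reg.to_dict(orient="records")

    # 4. PIC correlations
    if "pic" in config.analyses and tree is not None:
        pairs = config.regression_pairs or [
            p for p in DEFAULT_REGRESSION_PAIRS
            if p[0] in table.traits and p[1] in table.traits
        ]
        rows = []
        for organ in organs:
            for xt, yt in pairs:
                try:
                    x = table.organ_values(xt, organ).dropna()
                    y = table.organ_values(yt, organ).dropna()
                    common = x.index.intersection(y.index)
                    if set(common) != set(tree.tip_labels):
                        raise InputError("incomplete trait values for PIC")
                    res = pic_correlation(tree, x.to_dict(), y.to_dict())
                    rows.append({
                        "organ": organ, "x": xt, "y": yt,
                        "slope": res.slope, "r2": res.r2, "p": res.p,
                        "n_contrasts": res.n_contrasts,
                        "significant": res.p < config.alpha,
                    })
                except Exception as exc:
                    failures[f"pic:{organ}:{xt}~{yt}"] = str(exc)
        pw = pd.DataFrame(rows)
        tables["pic_within"] = pw
        report["pic_within_organ"] = pw.to_dict(orient="records")

        if paired_possible:
            rows = []
            for trait in table.traits:
                try:
                    pairs_df = table.organ_pairs(trait)
                    if set(pairs_df.index) != set(tree.tip_labels):
                        raise InputError("incomplete organ pairs for PIC")
                    res = pic_correlation(
                        tree,
                        pairs_df[organs[0]].to_dict(),
                        pairs_df[organs[1]].to_dict(),
                    )
                    rows.append({
                        "trait": trait, "slope": res.slope, "r2": res.r2,
                        "p": res.p, "n_contrasts": res.n_contrasts,
                        "significant": res.p < config.alpha,
                    })
                except Exception as exc:
                    failures[f"pic_between:{trait}"] = str(exc)
            pb = pd.DataFrame(rows)
            tables["pic_between"] = pb
            report["pic_between_organ"] = pb.to_dict(orient="records")

    # 5. PCA + hull overlap
    if "pca" in config.analyses:
        try:
            res = comparative.pca(table, traits=config.pca_traits)
            tables["pca_loadings"] = res.loadings.reset_index(names="trait")
            scores = res.scores.reset_index()
            tables["pca_scores"] = scores
            report["pca"] = {
                "explained": res.explained.tolist(),
                "dropped_rows": [list(map(str, t)) for t in res.dropped],
                "loadings": {
                    t: res.loadings.loc[t, ["PC1", "PC2"]].tolist()
                    for t in res.loadings.index
                },
            }
            if paired_possible:
                labels = res.scores.index.get_level_values("organ").to_numpy()
                counts = pd.Series(labels).value_counts()
                if len(counts) == 2 and counts.min() >= 3:
                    hov = comparative.hull_overlap(
                        res.scores[["PC1", "PC2"]].to_numpy(), labels
                    )
                    report["pca"]["hull_overlap"] = {
                        "iou": hov.iou, "hull_areas": hov.hull_areas,
                        "degenerate": hov.degenerate,
                    }
        except Exception as exc:
            failures["pca"] = str(exc)

    # -- write bundle --------------------------------------------------
    os.makedirs(config.out_dir, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(os.path.join(config.out_dir, f"{name}.tsv"), sep="\t", index=False)
    payload = round_sig(report, 6)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    import datetime
    import sys

    with open(os.path.join(config.out_dir, "log.txt"), "w") as fh:
        fh.write(f"hydrotrait {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"timestamp {datetime.datetime.now().isoformat()}\n")
        for line in notices:
            fh.write(f"notice: {line}\n")
        for key, msg in failures.items():
            fh.write(f"failure: {key}: {msg}\n")
    return payload
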
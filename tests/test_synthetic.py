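"""Ground-truth generators: determinism, structure, and recoverability."""

import numpy as np
import pandas as pd
import pytest

from hydrotrait import phylo
from hydrotrait.comparative import paired_t
from hydrotrait.exceptions import InputError
from hydrotrait.synthetic import (
    StudyDesign,
    simulate_drying_curve,
    simulate_pv_curve,
    simulate_study,
    simulate_traits,
    simulate_tree,
)


class TestTree:
    def test_two_tips_is_a_cherry(self):
        t = simulate_tree(2, seed=0)
        assert t.n_tips == 2 and len(t.tree.internal_nodes()) == 1

    def test_deterministic_under_seed(self):
        assert simulate_tree(10, seed=5).to_newick() == simulate_tree(10, seed=5).to_newick()
        assert simulate_tree(10, seed=5).to_newick() != simulate_tree(10, seed=6).to_newick()

    def test_bifurcating_ten_tips(self):
        t = simulate_tree(10, seed=1)
        assert t.n_tips == 10
        assert len(t.tree.internal_nodes()) == 9

    def test_ultrametric_positive_branches(self):
        t = simulate_tree(12, seed=3)
        _, C = t.vcv()
        assert np.allclose(np.diag(C), np.diag(C)[0])  # equal root-to-tip depths
        for node in t.tree.preorder_node_iter():
            if node is not t.tree.seed_node:
                assert node.edge.length > 0

    def test_too_few_tips(self):
        with pytest.raises(InputError):
            simulate_tree(1, seed=0)


class TestTraits:
    def test_zero_rates_collapse_species(self):
        design = StudyDesign(sigma_phylo=0.0, sigma_organ=0.0, noise_sd=0.0,
                             astomatous_flowers=0)
        tree = simulate_tree(design.n_species, seed=2)
        table, _ = simulate_traits(design, tree, seed=2)
        for organ in ("flower", "leaf"):
            sub = table.wide.xs(organ, level="organ")
            assert np.allclose(sub.std(ddof=0), 0.0)

    def test_deterministic_and_seed_sensitive(self):
        design = StudyDesign()
        tree = simulate_tree(10, seed=0)
        a, _ = simulate_traits(design, tree, seed=4)
        b, _ = simulate_traits(design, tree, seed=4)
        c, _ = simulate_traits(design, tree, seed=5)
        pd.testing.assert_frame_equal(a.wide, b.wide)
        assert not a.wide.equals(c.wide)

    def test_sign_conventions(self):
        tree = simulate_tree(10, seed=1)
        table, _ = simulate_traits(StudyDesign(astomatous_flowers=0), tree, seed=1)
        assert (table.wide["psi_sft"] < 0).all() and (table.wide["psi_tlp"] < 0).all()
        positives = [t for t in table.traits if t not in ("psi_sft", "psi_tlp")]
        assert (table.wide[positives] > 0).all().all()

    def test_astomatous_flowers_missing(self):
        tree = simulate_tree(10, seed=1)
        table, truth = simulate_traits(StudyDesign(astomatous_flowers=2), tree, seed=1)
        flowers = table.wide.xs("flower", level="organ")
        assert flowers.loc[truth["astomatous_flowers"], ["s_s", "d_s"]].isna().all().all()
        assert table.wide.xs("leaf", level="organ")[["s_s", "d_s"]].notna().all().all()

    def test_organ_offset_detected_by_paired_t(self):
        """A 2-sd organ effect is detected with high power at n = 10 species.

        The paired difference has sd sqrt(2)*sigma_organ (phylogenetic
        deviations are shared between organs and cancel); the g_min
        offsets built into the default trait centers exceed twice that.
        """
        detections = 0
        reps = 40
        for seed in range(reps):
            tree = simulate_tree(10, seed=1000 + seed)
            table, _ = simulate_traits(StudyDesign(), tree, seed=seed)
            logged = table.wide.copy()
            logged["gmin_mass"] = np.log(logged["gmin_mass"])
            res = paired_t(
                type(table)(logged), "gmin_mass"
            )
            if res.p < 0.05 and res.mean_diff > 0:
                detections += 1
        assert detections / reps > 0.9

    def test_pic_correlation_recovered_at_200_tips(self):
        design = StudyDesign(
            n_species=200, sigma_phylo=0.4, sigma_organ=0.0, noise_sd=0.0,
            astomatous_flowers=0,
            trait_correlations=[("gmin_mass", "c_t", 0.8)],
        )
        tree = simulate_tree(200, seed=9)
        rs = []
        for seed in range(8):
            table, _ = simulate_traits(design, tree, seed=seed)
            x = np.log(table.organ_values("gmin_mass", "leaf")).to_dict()
            y = np.log(table.organ_values("c_t", "leaf")).to_dict()
            cx = phylo.pic(tree, x).contrasts
            cy = phylo.pic(tree, y).contrasts
            rs.append(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))
        assert abs(np.mean(rs) - 0.8) < 0.05


class TestCurveGenerators:
    def test_drying_noiseless_round_trip(self):
        curve = simulate_drying_curve(12.0, 2e-3, 0.4, noise_sd=0.0, seed=0)
        assert curve.fit().g_min_area == pytest.approx(12.0, rel=1e-9)

    def test_drying_deterministic(self):
        a = simulate_drying_curve(10.0, 1e-3, 0.1, seed=3)
        b = simulate_drying_curve(10.0, 1e-3, 0.1, seed=3)
        assert np.array_equal(a.masses, b.masses)

    def test_drying_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            curve = simulate_drying_curve(
                12.0, 2e-3, 0.4, initial_water_ratio=0.05, noise_sd=0.0,
                n_points=10, seed=0,
            )
        assert curve.n_obs >= 3

    def test_pv_tlp_more_negative_than_sft(self):
        for psi in (-0.8, -1.5, -3.0):
            _, truth = simulate_pv_curve(psi_sft=psi, seed=0)
            assert truth["psi_tlp"] < truth["psi_sft"]

    def test_pv_osmotic_only_limit(self):
        """Zero apoplast + no turgor: -1/psi exactly linear in deficit."""
        curve, truth = simulate_pv_curve(
            psi_sft=-1.5, apoplastic_frac=0.0,
            elastic_modulus=1e12, noise_sd=0.0, seed=0,
        )
        # enormous elastic modulus puts the TLP at full hydration
        deficit = truth["sat_mass"] - curve.masses
        y = -1.0 / curve.psis
        r = np.corrcoef(deficit, y)[0, 1]
        assert r**2 > 0.999999

    def test_pv_invalid_fraction(self):
        with pytest.raises(InputError):
            simulate_pv_curve(apoplastic_frac=1.2)


class TestStudyBundle:
    def test_end_to_end_direction_recovery(self):
        """Full synthetic studies reproduce the generating organ contrast.

        Flowers are generated leakier (higher g_min) and more capacitive
        than leaves; the paired-t direction must be recovered from raw
        curves in nearly all replicates.
        """
        from hydrotrait.pipeline import RunConfig, run_pipeline

        hits = 0
        reps = 25
        for seed in range(reps):
            study = simulate_study(seed=seed)
            import tempfile

            with tempfile.TemporaryDirectory() as d:
                rep = run_pipeline(RunConfig(out_dir=d, seed=seed), data=study)
            pt = {r["trait"]: r for r in rep["paired_t"]}
            ok = (
                pt["gmin_area"]["mean_diff"] > 0 and pt["gmin_area"]["significant"]
                and pt["c_t"]["mean_diff"] > 0
            )
            hits += ok
        assert hits / reps >= 0.95
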
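"""The synthetic-data generator: tree shape, Brownian shape structure,
stress ordering, and bundle integrity."""

import numpy as np
import pytest

from taloco.fea import mwm
from taloco.phylo import kmult, phylo_cov
from taloco.shape import gpa
from taloco.synthetic import (
    GROUPS,
    SynthConfig,
    make_dataset,
    simulate_shapes,
    simulate_stress_field,
    simulate_tree,
)


def tip_depths(tree):
    depths = {}
    out = []
    for node in tree.preorder_node_iter():
        d = (depths[node.parent_node] if node.parent_node else 0.0) + (
            node.edge.length or 0.0
        )
        depths[node] = d
        if node.is_leaf():
            out.append(d)
    return np.array(out)


class TestSimulateTree:
    def test_tip_count_and_unit_depth(self):
        tree = simulate_tree(3, 0)
        d = tip_depths(tree)
        assert d.size == 3
        assert d.max() == pytest.approx(1.0)

    def test_ultrametric(self):
        d = tip_depths(simulate_tree(25, 4))
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_deterministic_newick(self):
        a = simulate_tree(12, 5).as_string(schema="newick")
        b = simulate_tree(12, 5).as_string(schema="newick")
        assert a == b

    def test_terminal_branches_strictly_positive(self):
        tree = simulate_tree(30, 1)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length > 1e-6


class TestSimulateShapes:
    def test_no_variation_collapses_to_template(self):
        cfg = SynthConfig(
            n_species=6,
            group_counts={"arboreal_quadruped": 2, "leaper": 2, "clamber_suspensory": 2},
            bm_rate=0.0,
            group_shape_offset=0.0,
            landmark_noise_sd=0.0,
            seed=3,
        )
        tree = simulate_tree(6, 3)
        shapes = simulate_shapes(tree, cfg)
        aligned = gpa(shapes)
        spread = aligned.procrustes_coords.std(axis=0).max()
        assert spread < 1e-8

    def test_brownian_shapes_have_unit_scale_kmult(self):
        # pure Brownian variant (no group offsets): K should average ~1
        ks = []
        for seed in range(25):
            cfg = SynthConfig(group_shape_offset=0.0, landmark_noise_sd=0.0, seed=seed)
            tree = simulate_tree(cfg.n_species, seed)
            shapes = simulate_shapes(tree, cfg)
            aligned = gpa(shapes)
            labels = [lm.specimen_id for lm in shapes]
            res = kmult(aligned.flat(), tree, labels, n_perm=0)
            ks.append(res.statistic)
        assert 0.8 <= np.mean(ks) <= 1.2

    def test_group_offsets_make_groups_separable(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        cfg = SynthConfig(seed=11)
        tree = simulate_tree(cfg.n_species, 11)
        shapes = simulate_shapes(tree, cfg)
        aligned = gpa(shapes)
        from taloco.shape import shape_pca

        pca = shape_pca(aligned)
        groups = []
        i = 0
        for g, cnt in cfg.group_counts.items():
            groups += [g] * cnt
        scores = pca.scores[:, : max(pca.retained, 2)]
        lda = LinearDiscriminantAnalysis().fit(scores, groups)
        assert lda.score(scores, groups) > 0.95


class TestSimulateStress:
    def test_degenerate_dispersion_recovers_group_median(self):
        cfg = SynthConfig(stress_logsd=1e-9, stress_species_logsd=0.0, seed=0)
        for group in GROUPS:
            fld = simulate_stress_field(group, cfg, specimen_seed=42)
            assert mwm(fld) == pytest.approx(cfg.stress_logmedian[group], rel=0.01)

    def test_group_mwm_ordering_across_replicates(self):
        cfg = SynthConfig(n_elements=300, seed=0)
        ordered = 0
        n_rep = 40
        rng = np.random.default_rng(123)
        for _ in range(n_rep):
            means = {}
            for group in GROUPS:
                vals = [
                    mwm(simulate_stress_field(group, cfg, int(rng.integers(2**31))))
                    for _ in range(12)
                ]
                means[group] = np.mean(vals)
            ordered += (
                means["clamber_suspensory"] > means["arboreal_quadruped"] > means["leaper"]
            )
        assert ordered >= 0.95 * n_rep

    def test_same_seed_identical_field(self):
        cfg = SynthConfig(seed=0)
        a = simulate_stress_field("leaper", cfg, 77)
        b = simulate_stress_field("leaper", cfg, 77)
        assert np.array_equal(a.sigma, b.sigma) and np.array_equal(a.vol, b.vol)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            simulate_stress_field("swimmer", SynthConfig(), 1)


class TestMakeDataset:
    def test_default_bundle_shape(self, small_bundle):
        meta = small_bundle.metadata
        assert (~meta["is_fossil"]).sum() == 40
        assert meta["is_fossil"].sum() == 10
        assert len(small_bundle.landmarks) == 50
        assert set(small_bundle.fossil_truth) == set(
            meta.loc[meta["is_fossil"], "specimen_id"]
        )
        assert meta.loc[meta["is_fossil"], "locomotor_class"].isna().all()

    def test_group_counts_match_config(self, small_bundle):
        counts = small_bundle.metadata.loc[
            ~small_bundle.metadata["is_fossil"], "locomotor_class"
        ].value_counts()
        assert counts["arboreal_quadruped"] == 19
        assert counts["leaper"] == 14
        assert counts["clamber_suspensory"] == 7

    def test_extant_species_all_on_tree(self, small_bundle):
        labels = {leaf.taxon.label for leaf in small_bundle.tree.leaf_node_iter()}
        extant = small_bundle.metadata.loc[
            ~small_bundle.metadata["is_fossil"], "species"
        ]
        assert set(extant) <= labels

    def test_groups_are_clade_contiguous(self, small_bundle):
        # group labels follow the leaf traversal order in blocks
        meta = small_bundle.metadata.set_index("species")
        order = [leaf.taxon.label for leaf in small_bundle.tree.leaf_node_iter()]
        seq = [meta.loc[sp, "locomotor_class"] for sp in order]
        changes = sum(a != b for a, b in zip(seq, seq[1:]))
        assert changes == 2

    def test_reproducible(self):
        cfg = dict(n_elements=50, seed=13)
        a = make_dataset(SynthConfig(**cfg))
        b = make_dataset(SynthConfig(**cfg))
        assert a.metadata.equals(b.metadata)
        assert np.array_equal(
            a.landmarks[0].coords, b.landmarks[0].coords
        )
        sid = a.metadata["specimen_id"].iloc[0]
        assert np.array_equal(a.stress_fields[sid].sigma, b.stress_fields[sid].sigma)

    def test_bad_group_counts_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_species=10)
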
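"""The synthetic homolog-family generator and its truth bundle."""

import numpy as np
import pytest
from scipy.stats import binom

from pbscope.pb_core import PB_LABELS, encode_structure
from pbscope.synthetic import (
    GeneratorConfig,
    build_backbone,
    default_substitution_process,
    generate_dataset,
    generate_homolog_pair,
    perturbed_process,
    stable_pb_string,
    windowed_pair_distances,
)

BOND_LENGTHS = {"n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329}


class TestBuildBackbone:
    def test_empty_string_raises(self):
        with pytest.raises(ValueError):
            build_backbone("")

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError):
            build_backbone("mmqm")

    def test_ideal_bond_geometry(self):
        s = build_backbone("mdkfp")
        assert np.allclose(np.linalg.norm(s.ca - s.n, axis=1), BOND_LENGTHS["n_ca"], atol=1e-9)
        assert np.allclose(np.linalg.norm(s.c - s.ca, axis=1), BOND_LENGTHS["ca_c"], atol=1e-9)
        assert np.allclose(np.linalg.norm(s.n[1:] - s.c[:-1], axis=1), BOND_LENGTHS["c_n"], atol=1e-9)

    def test_helical_string_encodes_back_to_m(self):
        assert encode_structure(build_backbone("m" * 9)) == "ZZ" + "m" * 5 + "ZZ"

    def test_extended_vs_helical_span(self):
        span = lambda s: np.linalg.norm(s.ca[-1] - s.ca[0])
        assert span(build_backbone("d" * 10)) > span(build_backbone("m" * 10))


class TestStableStrings:
    def test_fixed_point_of_encoder(self, rng):
        w = stable_pb_string(50, rng)
        assert encode_structure(build_backbone(w))[2:-2] == w[2:-2]


class TestGenerateHomologPair:
    def _noise_free(self, **kw):
        defaults = dict(substitution_rate=0.0, torsion_noise_deg=0.0,
                        identity_range=(100.0, 100.0), indel_targets=())
        defaults.update(kw)
        return GeneratorConfig(**defaults)

    def test_zero_rate_zero_noise_is_identical(self, rng):
        w = stable_pb_string(60, rng)
        pair, truth = generate_homolog_pair(w, self._noise_free(), rng)
        assert pair.pb1 == pair.pb2
        aligned = [d for d in pair.distances if not np.isnan(d)]
        assert np.allclose(aligned, 0.0, atol=1e-9)
        assert pair.identity == 100.0
        assert truth.substituted_positions == []

    def test_substitution_count_follows_binomial(self, rng):
        w = stable_pb_string(1000, rng)
        cfg = self._noise_free(substitution_rate=0.1)
        _, truth = generate_homolog_pair(w, cfg, np.random.default_rng(77))
        n = len(truth.substituted_positions)
        sd = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(n - 100) <= 3 * sd

    def test_planted_indels_only_at_target_context(self, rng):
        cfg = self._noise_free(indel_targets=(("p", "a"),), indel_rate=1.0)
        found_any = False
        for seed in range(8):
            r = np.random.default_rng(seed)
            w = stable_pb_string(300, r)
            pair, truth = generate_homolog_pair(w, cfg, r)
            for site in truth.indels:
                found_any = True
                assert site.di_pb == ("p", "a")
                li = site.left_index
                assert (truth.realized1[li], truth.realized1[li + 1]) == ("p", "a")
            if truth.indels:
                # gaps appear in domain 1's row exactly where planted
                gap_cols = [(i, j) for i, j in pair.columns if i < 0]
                assert len(gap_cols) == sum(s.length for s in truth.indels)
        assert found_any

    def test_template_too_short_for_indels_raises(self, rng):
        cfg = self._noise_free(indel_targets=(("p", "a"),))
        with pytest.raises(ValueError):
            generate_homolog_pair("mmdpammdpamm"[:12], cfg, rng)

    def test_emitted_pb_strings_are_realized_encodings(self, rng):
        """The alignment's PB sequences equal the encoder's view of the
        emitted coordinates (full generator/encoder consistency)."""
        w = stable_pb_string(80, rng)
        cfg = GeneratorConfig(substitution_rate=0.2, torsion_noise_deg=3.0)
        pair, truth = generate_homolog_pair(w, cfg, rng)
        assert pair.pb1 == encode_structure(pair.structure1) == truth.realized1
        assert pair.pb2 == encode_structure(pair.structure2) == truth.realized2

    def test_non_substituted_interior_positions_reproduce_template(self, rng):
        w = stable_pb_string(100, rng)
        cfg = self._noise_free(substitution_rate=0.15)
        pair, truth = generate_homolog_pair(w, cfg, rng)
        skip = set(truth.substituted_positions)
        near = {p + d for p in skip for d in (-2, -1, 0, 1, 2)}
        for i in range(2, 98):
            if i not in near:
                assert pair.pb2[i] == w[i]


class TestGenerateDataset:
    def test_same_seed_is_deterministic(self):
        cfg = GeneratorConfig(seed=3, n_families=3, pairs_per_family=(2,),
                              template_length=60)
        pairs1, truth1 = generate_dataset(cfg)
        pairs2, truth2 = generate_dataset(cfg)
        for p1, p2 in zip(pairs1, pairs2):
            assert p1.pb1 == p2.pb1 and p1.pb2 == p2.pb2
            assert np.array_equal(p1.structure1.ca, p2.structure1.ca)
            assert np.array_equal(p1.distances, p2.distances, equal_nan=True)
        for t1, t2 in zip(truth1.pairs, truth2.pairs):
            assert t1.intended2 == t2.intended2

    def test_family_sizes_cycle(self):
        cfg = GeneratorConfig(seed=0, n_families=4, pairs_per_family=(1, 2, 3, 4),
                              template_length=40)
        pairs, _ = generate_dataset(cfg)
        assert len(pairs) == 10

    def test_class_labels_cycle_through_config(self):
        cfg = GeneratorConfig(seed=0, n_families=4, pairs_per_family=(1,),
                              template_length=40, classes=("all-alpha", "all-beta"))
        pairs, _ = generate_dataset(cfg)
        assert [p.scop_class for p in pairs] == ["all-alpha", "all-beta"] * 2

    def test_core_distance_calibration_under_cartesian_jitter(self):
        """With sigma = 0.5 A coordinate jitter and no conformational change,
        at least 99% of core columns stay within 3 A."""
        cfg = GeneratorConfig(seed=21, n_families=4, pairs_per_family=(2,),
                              template_length=150, substitution_rate=0.0,
                              torsion_noise_deg=0.0, cartesian_noise=0.5,
                              identity_range=(100.0, 100.0))
        pairs, _ = generate_dataset(cfg)
        d = np.concatenate([p.distances[~np.isnan(p.distances)] for p in pairs])
        assert (d <= 3.0).mean() >= 0.99

    def test_identity_targets_respected(self):
        cfg = GeneratorConfig(seed=2, n_families=4, pairs_per_family=(2,),
                              template_length=200, identity_range=(15.0, 35.0))
        pairs, _ = generate_dataset(cfg)
        for p in pairs:
            assert 5.0 < p.identity < 45.0  # targets plus sampling slack


class TestProcesses:
    def test_default_process_is_stochastic_with_zero_diagonal(self):
        P = default_substitution_process()
        assert P.shape == (16, 16)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(np.diag(P), 0.0)

    def test_perturbed_process_moves_mass(self):
        P = perturbed_process(default_substitution_process(), "p", "j", 1.0)
        i, j = PB_LABELS.index("p"), PB_LABELS.index("j")
        assert P[i, j] == pytest.approx(1.0)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(substitution_rate=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(torsion_noise_deg=-1)
        with pytest.raises(ValueError):
            GeneratorConfig(processes={"all-alpha": np.ones((16, 16))})


class TestWindowedDistances:
    def test_identical_coordinates_give_zero(self, rng):
        ca = rng.normal(size=(30, 3)) * 5
        assert np.allclose(windowed_pair_distances(ca, ca.copy()), 0.0, atol=1e-9)

    def test_rigid_motion_gives_zero(self, rng):
        from scipy.spatial.transform import Rotation

        ca = rng.normal(size=(30, 3)) * 5
        R = Rotation.random(random_state=5).as_matrix()
        moved = ca @ R.T + np.array([4.0, -7.0, 1.0])
        assert np.allclose(windowed_pair_distances(ca, moved), 0.0, atol=1e-8)

    def test_segments_do_not_bridge_indels(self, rng):
        """A rigid hinge between two segments is invisible when windows
        respect segment boundaries, but contaminates bridged windows."""
        from scipy.spatial.transform import Rotation

        ca1 = np.cumsum(rng.normal(size=(40, 3)), axis=0) + np.arange(40)[:, None]
        R = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        ca2 = ca1.copy()
        ca2[20:] = (ca2[20:] - ca2[20]) @ R.T + ca2[20]
        seg = windowed_pair_distances(ca1, ca2, segments=[(0, 20), (20, 40)])
        bridged = windowed_pair_distances(ca1, ca2)
        assert seg[5:15].max() < 1e-8 and seg[25:35].max() < 1e-8
        assert bridged[15:25].max() > seg[15:25].max()
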
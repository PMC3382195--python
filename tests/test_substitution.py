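"""Substitution counting, family normalization, log-odds, comparison, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbscope.pb_core import PB_LABELS
from pbscope.substitution import (
    SubstitutionCounts,
    SubstitutionMatrix,
    class_matrices,
    cluster_pbs,
    compare_rows,
    count_substitutions,
    filter_dataset,
    log_odds,
    normalize_by_family,
    outlier_substitutions,
)

from .conftest import make_pair

LIDX = {lab: k for k, lab in enumerate(PB_LABELS)}


class TestFilterDataset:
    def test_identity_cutoff_is_strict(self):
        at_cutoff = make_pair("mmm", "mmm", identity=40.0)
        below = make_pair("mmm", "mmm", identity=39.9)
        assert filter_dataset([at_cutoff], 40.0) == []
        assert filter_dataset([below], 40.0) == [below]

    def test_analytic_count(self):
        pairs = [make_pair("mmm", "mmm", identity=i) for i in (10, 30, 50, 80)]
        assert len(filter_dataset(pairs, 40.0)) == 2

    def test_resolution_better_than_cutoff(self):
        good = make_pair("mmm", "mmm", resolution=1.5)
        bad = make_pair("mmm", "mmm", resolution=2.0)
        missing = make_pair("mmm", "mmm", resolution=None)
        kept = filter_dataset([good, bad, missing], 40.0, min_resolution=2.0)
        kept_ids = {id(p) for p in kept}
        assert id(good) in kept_ids and id(bad) not in kept_ids and id(missing) in kept_ids


class TestCountSubstitutions:
    def test_identical_sequences_give_diagonal_counts(self):
        c = count_substitutions([make_pair("mmdd", "mmdd")])
        expect = np.zeros((16, 16))
        expect[LIDX["m"], LIDX["m"]] = 2
        expect[LIDX["d"], LIDX["d"]] = 2
        assert np.array_equal(c.counts, expect)

    def test_single_column_off_diagonal(self):
        c = count_substitutions([make_pair("m", "n", distances=[2.5])])
        assert c.counts[LIDX["m"], LIDX["n"]] == 1
        assert c.total == 1

    def test_distance_cutoff_hand_enumeration(self):
        # 10 columns; 3 beyond 3 A -> exactly 7 counted ("within 3 A" inclusive)
        dists = [0.5, 1.0, 3.0, 3.01, 2.9, 4.2, 0.1, 9.9, 1.5, 2.2]
        c = count_substitutions([make_pair("m" * 10, "m" * 10, distances=dists)])
        assert c.total == 7

    def test_z_columns_never_count(self):
        c = count_substitutions([make_pair("ZZmZZ", "ZZmZZ")])
        assert c.total == 1

    def test_gap_columns_skipped(self):
        cols = [(0, 0), (1, -1), (2, 1)]
        c = count_substitutions(
            [make_pair("mmd", "md", columns=cols, distances=[0.1, np.nan, 0.2])]
        )
        assert c.total == 2

    def test_missing_distances_raise_with_pair_name(self):
        p = make_pair("mm", "mm", distances=[0.1, np.nan])
        with pytest.raises(ValueError, match=p.pair_id):
            count_substitutions([p])


class TestNormalizeByFamily:
    def test_single_family_proportional_to_raw(self):
        pairs = [make_pair("mm", "mm", family="f1"), make_pair("dd", "dd", family="f1")]
        raw = count_substitutions(pairs)
        normed = normalize_by_family(raw)
        assert np.allclose(normed.counts, raw.counts / 2)

    def test_family_sizes_one_and_ten_contribute_equally(self):
        small = [make_pair("mmmm", "mmmm", family="small")]
        big = [make_pair("mmmm", "mmmm", family="big") for _ in range(10)]
        normed = normalize_by_family(count_substitutions(small + big))
        per_fam = {f: mat[LIDX["m"], LIDX["m"]] for f, (mat, _) in normed.per_family.items()}
        assert per_fam["small"] == pytest.approx(per_fam["big"])

    def test_two_family_arithmetic_oracle(self):
        # family A: 2 pairs all (d,d); family B: 1 pair all (m,m); equal per-pair totals
        fam_a = [make_pair("ddd", "ddd", family="A") for _ in range(2)]
        fam_b = [make_pair("mmm", "mmm", family="B")]
        pooled = normalize_by_family(count_substitutions(fam_a + fam_b)).counts
        assert pooled[LIDX["d"], LIDX["d"]] == pytest.approx(pooled[LIDX["m"], LIDX["m"]])

    def test_duplicating_pairs_within_family_is_invariant(self):
        base = [make_pair("mdk", "mdk", family="f")]
        doubled = base + [make_pair("mdk", "mdk", family="f")]
        n1 = normalize_by_family(count_substitutions(base)).counts
        n2 = normalize_by_family(count_substitutions(doubled)).counts
        assert np.allclose(n1, n2)


class TestLogOdds:
    def test_uniform_counts_give_zero_scores(self):
        c = SubstitutionCounts(labels=list(PB_LABELS), counts=np.full((16, 16), 5.0))
        m = log_odds(c)
        assert np.allclose(m.scores, 0.0, atol=1e-12)

    def test_diagonal_concentration_gives_positive_diagonal(self):
        counts = np.ones((16, 16))
        np.fill_diagonal(counts, 500.0)
        m = log_odds(SubstitutionCounts(labels=list(PB_LABELS), counts=counts))
        diag = np.diag(m.scores)
        off = m.scores[~np.eye(16, dtype=bool)]
        assert diag.min() > off.max()

    def test_two_letter_matrix_matches_hand_computation(self):
        # raw counts [[6, 2], [4, 8]], pseudocount 1:
        # symmetrized + pc: [[13, 7], [7, 17]]; total 44
        # q = [[13/44, 7/44], [7/44, 17/44]]; p = (20/44, 24/44)
        # S_aa = log2((13/44)/(20/44)^2); S_ab = log2((7/44)/(20*24/44^2)); ...
        c = SubstitutionCounts(labels=["a", "b"], counts=np.array([[6.0, 2], [4, 8]]))
        m = log_odds(c, pseudocount=1.0)
        assert m.scores[0, 0] == pytest.approx(np.log2((13 / 44) / (20 / 44) ** 2))
        assert m.scores[0, 1] == pytest.approx(np.log2((7 / 44) / (20 * 24 / 44**2)))
        assert m.scores[1, 0] == pytest.approx(m.scores[0, 1])
        assert m.scores[1, 1] == pytest.approx(np.log2((17 / 44) / (24 / 44) ** 2))

    def test_negative_counts_raise(self):
        c = SubstitutionCounts(labels=["a", "b"], counts=np.array([[1.0, -1], [0, 1]]))
        with pytest.raises(ValueError):
            log_odds(c)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_and_finite_for_any_counts(self, seed):
        r = np.random.default_rng(seed)
        counts = r.integers(0, 50, (16, 16)).astype(float)
        m = log_odds(SubstitutionCounts(labels=list(PB_LABELS), counts=counts))
        assert np.isfinite(m.scores).all()
        assert np.allclose(m.scores, m.scores.T)


class TestClassMatrices:
    def test_single_class_equals_global_pipeline(self):
        pairs = [make_pair("mmdd", "mmdd", family=f"f{i}", scop_class="all-beta")
                 for i in range(3)]
        per_class = class_matrices(pairs)
        direct = log_odds(normalize_by_family(count_substitutions(pairs)))
        assert list(per_class) == ["all-beta"]
        assert np.allclose(per_class["all-beta"].scores, direct.scores)

    def test_disjoint_classes_are_independent(self):
        alpha = [make_pair("mmmm", "mmmm", family="fa", scop_class="all-alpha")]
        beta = [make_pair("dddd", "dddd", family="fb", scop_class="all-beta")]
        both = class_matrices(alpha + beta)
        alone = class_matrices(alpha)
        assert np.allclose(both["all-alpha"].scores, alone["all-alpha"].scores)


class TestCompareRows:
    def _mat(self, scores):
        return SubstitutionMatrix(labels=list(PB_LABELS), scores=np.asarray(scores, float))

    def test_identity_signature(self, rng):
        a = self._mat(rng.normal(size=(16, 16)))
        corr, diff = compare_rows(a, a)
        assert np.allclose(corr, 1.0)
        assert np.allclose(diff, 0.0)

    def test_constant_shift_keeps_correlation_one(self, rng):
        a = self._mat(rng.normal(size=(16, 16)))
        b = self._mat(a.scores + 3.25)
        corr, diff = compare_rows(a, b)
        assert np.allclose(corr, 1.0)
        assert np.allclose(diff, -3.25)

    def test_negated_rows_give_minus_one(self, rng):
        a = self._mat(rng.normal(size=(16, 16)))
        corr, _ = compare_rows(a, self._mat(-a.scores))
        assert np.allclose(corr, -1.0)

    def test_constant_row_reported_as_nan(self, rng):
        scores = rng.normal(size=(16, 16))
        scores[4] = 7.0
        corr, _ = compare_rows(self._mat(scores), self._mat(scores + 0.0))
        assert np.isnan(corr[4]) and np.isfinite(np.delete(corr, 4)).all()


class TestOutlierSubstitutions:
    def test_all_equal_flags_nothing(self):
        assert not outlier_substitutions(np.full(16, 2.0)).any()

    def test_single_extreme_value_flagged(self):
        vals = np.zeros(16)
        vals[7] = 10.0
        mask = outlier_substitutions(vals)
        assert mask[7] and mask.sum() == 1

    def test_matches_percentile_oracle(self):
        vals = np.array(list(range(1, 16)) + [100], dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])  # type-7 interpolation
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expect = (vals < lo) | (vals > hi)
        assert np.array_equal(outlier_substitutions(vals), expect)
        assert expect.sum() == 1 and expect[-1]


class TestClusterPbs:
    def test_identical_rows_merge_first_at_height_zero(self, rng):
        scores = rng.normal(size=(16, 16))
        scores[5] = scores[9]  # PBs 'f' and 'j' identical substitution patterns
        dend = cluster_pbs(SubstitutionMatrix(labels=list(PB_LABELS), scores=scores))
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {5, 9}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_block_structure_top_split(self):
        # two perfectly correlated groups of rows -> top split separates them
        base1 = np.arange(16, dtype=float)
        base2 = base1[::-1].copy()
        scores = np.array([base1 * (1 + 0.01 * i) if i < 8 else base2 * (1 + 0.01 * i)
                           for i in range(16)])
        dend = cluster_pbs(SubstitutionMatrix(labels=list(PB_LABELS), scores=scores))
        from scipy.cluster.hierarchy import fcluster

        groups = fcluster(dend.linkage, t=2, criterion="maxclust")
        assert len(set(groups[:8])) == 1 and len(set(groups[8:])) == 1
        assert groups[0] != groups[15]

    def test_four_label_manual_trace(self):
        """Merge order equals a hand-executed complete-linkage agglomeration.

        Rows engineered so the correlation distances are, approximately:
        d(a,b) small, d(c,d) medium, with both groups far apart; complete
        linkage then merges (a,b), then (c,d), then everything.
        """
        rows = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.1, 2.9, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [4.0, 2.8, 2.2, 1.0],
        ])
        m = SubstitutionMatrix(labels=["a", "b", "c", "d"], scores=rows)
        dend = cluster_pbs(m)
        merges = [set(map(int, row[:2])) for row in dend.linkage]
        assert merges[0] == {0, 1}
        assert merges[1] == {2, 3}
        assert merges[2] == {4, 5}
        assert np.all(np.diff(dend.merge_heights()) >= -1e-12)

    def test_permutation_invariance(self, rng):
        scores = rng.normal(size=(16, 16))
        scores = (scores + scores.T) / 2
        m1 = SubstitutionMatrix(labels=list(PB_LABELS), scores=scores)
        perm = rng.permutation(16)
        m2 = SubstitutionMatrix(
            labels=[PB_LABELS[k] for k in perm], scores=scores[np.ix_(perm, perm)]
        )
        h1 = cluster_pbs(m1).merge_heights()
        h2 = cluster_pbs(m2).merge_heights()
        assert np.allclose(np.sort(h1), np.sort(h2))

    def test_constant_row_raises_with_label(self, rng):
        scores = rng.normal(size=(16, 16))
        scores[2] = 0.0
        with pytest.raises(ValueError, match="'c'"):
            cluster_pbs(SubstitutionMatrix(labels=list(PB_LABELS), scores=scores))

    def test_newick_export_parses_to_sixteen_leaves(self, rng, tmp_path):
        from io import StringIO

        from Bio import Phylo

        scores = rng.normal(size=(16, 16))
        newick = cluster_pbs(
            SubstitutionMatrix(labels=list(PB_LABELS), scores=scores)
        ).to_newick()
        tree = Phylo.read(StringIO(newick), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(PB_LABELS)
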
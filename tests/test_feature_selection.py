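"""Mutual information, recurrence filtering, GMT parsing and
pathway-representative selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import mutual_info_score

from mutfm.feature_selection import (
    FeatureScore,
    FeatureSet,
    GmtFormatError,
    PathwayCollection,
    PathwayRepresentativeSelector,
    mutual_information,
    read_gmt,
    recurrence_filter,
    select_pathway_representatives,
    stability_analysis,
)
from mutfm.maf_io import BinaryMutationMatrix


def naive_mi(x, y):
    """Direct two-loop evaluation of the plug-in double sum (oracle)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px = np.mean(x == xv)
            py = np.mean(y == yv)
            total += pxy * math.log(pxy / (px * py))
    return total


class TestReadGmt:
    def test_minimal_line(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tA\tB\n")
        pw = read_gmt(p)
        assert pw.pathways == {"P1": ("A", "B")}

    def test_duplicate_gene_collapsed(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tA\tA\tB\n")
        assert read_gmt(p).pathways["P1"] == ("A", "B")

    def test_short_line_reports_lineno(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tA\nP2\tdesc\n")
        with pytest.raises(GmtFormatError, match=":2:"):
            read_gmt(p)

    def test_five_pathways_shared_gene(self, tmp_path):
        lines = [f"P{i}\tdesc\tSHARED\tU{i}a\tU{i}b" for i in range(5)]
        p = tmp_path / "p.gmt"
        p.write_text("\n".join(lines) + "\n")
        pw = read_gmt(p)
        assert len(pw) == 5
        assert len(pw.gene_universe()) == 11  # 5*2 unique + 1 shared


class TestRecurrenceFilter:
    def test_boundary_is_inclusive(self):
        values = np.zeros((200, 1), dtype=np.int8)
        values[0, 0] = 1  # frequency exactly 1/200 = 0.005
        m = BinaryMutationMatrix(values, [f"S{i}" for i in range(200)], ["G1"])
        assert recurrence_filter(m, 0.005) == ["G1"]

    def test_zero_frequency_always_removed(self):
        m = BinaryMutationMatrix(np.zeros((10, 1), dtype=np.int8), [f"S{i}" for i in range(10)], ["G1"])
        assert recurrence_filter(m, 1e-6) == []

    def test_planted_frequencies(self):
        n = 1000
        values = np.zeros((n, 4), dtype=np.int8)
        for j, k in enumerate([1, 4, 20, 300]):  # frequencies .001 .004 .02 .3
            values[:k, j] = 1
        m = BinaryMutationMatrix(values, [f"S{i}" for i in range(n)], list("ABCD"))
        assert recurrence_filter(m, 0.005) == ["C", "D"]

    def test_invalid_threshold(self, small_cohort):
        with pytest.raises(ValueError):
            recurrence_filter(small_cohort.matrix, 0.0)


class TestMutualInformation:
    def test_constant_x_gives_zero(self):
        assert mutual_information([1] * 8, list("AABBAABB")) == 0.0

    def test_identity_coupling_is_log2(self):
        y = ["A"] * 4 + ["B"] * 4
        x = [1] * 4 + [0] * 4
        assert mutual_information(x, y) == pytest.approx(math.log(2), abs=1e-12)
        assert mutual_information(x, y, log_base=2) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_joint_counts(self):
        # joint counts over n=8: (1,A)=3, (0,A)=1, (1,B)=1, (0,B)=3
        x = [1, 1, 1, 0, 1, 0, 0, 0]
        y = ["A", "A", "A", "A", "B", "B", "B", "B"]
        expected = naive_mi(x, y)  # independent summation oracle
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)
        # the oracle itself evaluates the closed form: sum of p log p/(pq)
        manual = sum(
            p * math.log(p / (px * py))
            for p, px, py in [
                (3 / 8, 4 / 8, 4 / 8),
                (1 / 8, 4 / 8, 4 / 8),
                (1 / 8, 4 / 8, 4 / 8),
                (3 / 8, 4 / 8, 4 / 8),
            ]
        )
        assert expected == pytest.approx(manual, abs=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], ["A"])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_matches_two_loop_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 4, n)
        got = mutual_information(x, y)
        assert got == pytest.approx(naive_mi(x, y), abs=1e-12)
        assert got == pytest.approx(mutual_info_score(y, x), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_nonnegative_and_entropy_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 80))
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 4, n)

        def entropy(v):
            _, c = np.unique(v, return_counts=True)
            p = c / c.sum()
            return -np.sum(p * np.log(p))

        mi = mutual_information(x, y)
        assert mi >= 0
        assert mi <= min(entropy(x), entropy(y)) + 1e-12

    def test_relabeling_invariance(self, rng):
        x = rng.integers(0, 2, 50)
        y = rng.integers(0, 3, 50)
        relabeled = np.array(["XX", "YY", "ZZ"])[y]
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(x, relabeled), abs=1e-15
        )

    def test_permuted_labels_give_near_zero_mi(self, rng):
        """Breaking the x-y pairing should drive MI toward 0."""
        n = 2000
        y = rng.integers(0, 4, n)
        x = (rng.random(n) < np.where(y == 0, 0.6, 0.1)).astype(int)
        real = mutual_information(x, y)
        null = [mutual_information(x, rng.permutation(y)) for _ in range(50)]
        assert np.mean(null) < np.percentile(null, 95)
        assert real > np.percentile(null, 95)


def _matrix_from_columns(cols: dict[str, np.ndarray]) -> BinaryMutationMatrix:
    genes = list(cols)
    values = np.column_stack([cols[g] for g in genes]).astype(np.int8)
    return BinaryMutationMatrix(values, [f"S{i}" for i in range(values.shape[0])], genes)


class TestSelectPathwayRepresentatives:
    def _toy(self, rng):
        n = 200
        y = np.array(["A"] * 100 + ["B"] * 100)
        informative = (rng.random(n) < np.where(y == "A", 0.7, 0.1)).astype(int)
        weak = (rng.random(n) < np.where(y == "A", 0.3, 0.2)).astype(int)
        noise = rng.integers(0, 2, n)
        m = _matrix_from_columns({"INF": informative, "WEAK": weak, "NOISE": noise})
        return m, y

    def test_argmax_within_pathway(self, rng):
        m, y = self._toy(rng)
        pw = PathwayCollection({"P1": ("INF", "WEAK")})
        fs = select_pathway_representatives(m, y, pw, threshold=0.01)
        assert fs.genes == ["INF"]
        assert fs.provenance["INF"] == ["P1"]

    def test_shared_representative_deduplicated(self, rng):
        m, y = self._toy(rng)
        pw = PathwayCollection({"P1": ("INF", "WEAK"), "P2": ("INF", "NOISE")})
        fs = select_pathway_representatives(m, y, pw, threshold=0.01)
        assert fs.genes == ["INF"]
        assert sorted(fs.provenance["INF"]) == ["P1", "P2"]

    def test_tie_breaks_frequency_then_symbol(self):
        # identical columns (equal MI, equal frequency): lexicographically
        # smaller symbol wins
        n = 40
        y = np.array(["A"] * 20 + ["B"] * 20)
        col = np.zeros(n, dtype=np.int8)
        col[:10] = 1
        m = _matrix_from_columns({"ZZ": col, "AA": col.copy()})
        fs = select_pathway_representatives(
            m, y, PathwayCollection({"P": ("ZZ", "AA")}), threshold=0.01
        )
        assert fs.genes == ["AA"]

        # equal MI but different frequency: MI(x, y) == MI(1-x, y), so the
        # class-A indicator (freq .75) ties the class-B indicator (freq .25)
        # and must win on frequency despite its larger symbol
        y2 = np.array(["A"] * 30 + ["B"] * 10)
        ind_a = np.array([1] * 30 + [0] * 10, dtype=np.int8)
        m2 = _matrix_from_columns({"AA": 1 - ind_a, "ZZ": ind_a})
        fs2 = select_pathway_representatives(
            m2, y2, PathwayCollection({"P": ("AA", "ZZ")}), threshold=0.01
        )
        assert fs2.genes == ["ZZ"]

    def test_pathway_without_survivors_skipped(self, rng):
        m, y = self._toy(rng)
        pw = PathwayCollection({"P1": ("ABSENT",), "P2": ("INF",)})
        fs = select_pathway_representatives(m, y, pw, threshold=0.01)
        assert fs.genes == ["INF"]

    def test_empty_selection_warns(self, rng):
        m, y = self._toy(rng)
        pw = PathwayCollection({"P1": ("ABSENT",)})
        with pytest.warns(UserWarning, match="empty"):
            fs = select_pathway_representatives(m, y, pw, threshold=0.01)
        assert len(fs) == 0

    def test_deterministic(self, small_cohort):
        a = select_pathway_representatives(
            small_cohort.matrix, small_cohort.labels, small_cohort.pathways, 0.01
        )
        b = select_pathway_representatives(
            small_cohort.matrix, small_cohort.labels, small_cohort.pathways, 0.01
        )
        assert a.genes == b.genes
        assert a.scores == b.scores

    def test_recovers_planted_informative_genes(self, small_cohort):
        fs = select_pathway_representatives(
            small_cohort.matrix, small_cohort.labels, small_cohort.pathways, 0.01
        )
        recovered = set(fs.genes) & set(small_cohort.informative_genes)
        assert len(recovered) >= 0.8 * len(small_cohort.informative_genes)

    def test_transformer_api(self, small_cohort):
        sel = PathwayRepresentativeSelector(
            pathways=small_cohort.pathways, gene_ids=small_cohort.matrix.gene_ids
        )
        X = small_cohort.matrix.values
        Xt = sel.fit_transform(X, small_cohort.labels)
        assert Xt.shape == (X.shape[0], len(sel.feature_set_))
        assert list(sel.get_feature_names_out()) == sel.feature_set_.genes
        np.testing.assert_array_equal(Xt, X[:, sel.support_])

    def test_stricter_winners_persist_at_looser_threshold(self, small_cohort):
        """A gene that wins its pathway under the strict filter and still
        passes the loose filter must remain selected."""
        strict = select_pathway_representatives(
            small_cohort.matrix, small_cohort.labels, small_cohort.pathways, 0.05
        )
        loose = select_pathway_representatives(
            small_cohort.matrix, small_cohort.labels, small_cohort.pathways, 0.01
        )
        freqs = dict(
            zip(small_cohort.matrix.gene_ids, small_cohort.matrix.gene_frequencies())
        )
        for g in strict.genes:
            # the strict winner competes against a superset at the loose
            # threshold; it persists unless a newly admitted gene beats it
            if g not in loose.genes:
                new_winner_mi = max(
                    loose.scores[w].mi
                    for w in loose.genes
                    if set(loose.provenance[w]) & set(strict.provenance[g])
                )
                assert new_winner_mi >= strict.scores[g].mi


class TestStabilityAnalysis:
    def _fs(self, genes, mi=None):
        mi = mi or {g: 1.0 for g in genes}
        scores = {g: FeatureScore(g, mi[g], 0.5) for g in genes}
        return FeatureSet(list(genes), scores, {g: ["P"] for g in genes}, 0.005)

    def test_identical_sets(self):
        fs = self._fs(["g1", "g2", "g3"], {"g1": 0.3, "g2": 0.2, "g3": 0.1})
        r = stability_analysis(fs, fs, rank_depth=3)
        assert (r.jaccard, r.inclusion_rate, r.spearman_rho) == (1.0, 1.0, 1.0)

    def test_disjoint_sets(self):
        a = self._fs(["g1", "g2"])
        b = self._fs(["g3", "g4"])
        r = stability_analysis(a, b, rank_depth=2)
        assert r.jaccard == 0.0 and r.inclusion_rate == 0.0

    def test_nested_subset(self):
        a = self._fs([f"g{i}" for i in range(1, 5)])
        b = self._fs([f"g{i}" for i in range(1, 9)])
        r = stability_analysis(a, b, rank_depth=4)
        assert r.jaccard == pytest.approx(0.5)
        assert r.inclusion_rate == pytest.approx(1.0)
        assert r.jaccard <= r.inclusion_rate

    def test_rank_depth_validation(self):
        a = self._fs(["g1", "g2"])
        with pytest.raises(ValueError):
            stability_analysis(a, a, rank_depth=1)
        with pytest.raises(ValueError):
            stability_analysis(a, a, rank_depth=5)
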
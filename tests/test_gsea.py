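"""Association ranking, running-sum enrichment score, permutation GSEA."""

import numpy as np
import pandas as pd
import pytest

from speccount.gsea import (
    GeneSetCollection,
    enrichment_score,
    filter_sets,
    gsea_significance,
    rank_by_association,
    read_gmt,
    write_gmt,
)
from speccount.ingest import SpectralCountMatrix
from speccount.synth import simulate_gene_sets, simulate_spectral_counts


def brute_force_es(ranked: pd.Series, gene_set, weight: float):
    """Step the running sum through every rank explicitly."""
    names = list(ranked.index)
    hits = [g in set(gene_set) for g in names]
    w = [abs(s) ** weight if h else 0.0 for s, h in zip(ranked.to_numpy(), hits)]
    w_total = sum(w)
    g = sum(hits)
    miss = 1.0 / (len(names) - g)
    running, best = 0.0, 0.0
    for i in range(len(names)):
        if hits[i]:
            running += (w[i] / w_total) if w_total > 0 else 1.0 / g
        else:
            running -= miss
        if abs(running) > abs(best) + 1e-12 or (
            abs(running) > abs(best) - 1e-12 and running > best
        ):
            best = running
    return best


def matrix_from_counts(counts: pd.DataFrame, id_missing=None) -> SpectralCountMatrix:
    feats = pd.DataFrame(
        {
            "gene_symbol": counts.index,
            "gene_id": np.arange(1.0, len(counts) + 1),
            "id_missing": id_missing if id_missing is not None else False,
        },
        index=counts.index,
    )
    return SpectralCountMatrix(counts, feats)


COLS = ["N_b1_t1", "N_b1_t2", "N_b2_t1", "T_b1_t1", "T_b1_t2", "T_b2_t1"]


class TestRankByAssociation:
    def test_shifted_gene_outranks_constant_gene(self):
        counts = pd.DataFrame(
            [[1, 2, 1, 9, 8, 9], [5, 5, 5, 5, 5, 5]],
            index=["SHIFTED", "CONST"], columns=COLS, dtype=float,
        )
        ranked = rank_by_association(matrix_from_counts(counts))
        assert list(ranked.index) == ["SHIFTED", "CONST"]
        assert ranked["SHIFTED"] > 0

    def test_constant_gene_scores_zero_under_difference_of_means(self):
        counts = pd.DataFrame(
            [[5, 5, 5, 5, 5, 5]], index=["CONST"], columns=COLS, dtype=float
        )
        ranked = rank_by_association(
            matrix_from_counts(counts), metric="difference_of_means"
        )
        assert ranked["CONST"] == 0.0

    def test_hand_computed_signal_to_noise(self):
        counts = pd.DataFrame(
            [
                [1, 2, 3, 7, 8, 9],
                [10, 10, 10, 10, 10, 10],
                [9, 8, 7, 3, 2, 1],
            ],
            index=["UP", "FLAT", "DOWN"], columns=COLS, dtype=float,
        )
        ranked = rank_by_association(matrix_from_counts(counts))
        # per class: mu=(8,2) resp (2,8); sd=1 both, floored at 0.2*|mu|=1.6
        expected = (8 - 2) / (1.6 + 1.0)  # malignant sd floor binds at mu=8
        assert list(ranked.index) == ["UP", "FLAT", "DOWN"]
        assert ranked["UP"] == pytest.approx(expected)
        assert ranked["DOWN"] == pytest.approx(-expected)

    def test_label_reversal_negates_scores(self):
        matrix, _ = simulate_spectral_counts(n_genes=30, seed=9)
        flipped_cols = {
            c: c.replace("N_", "X_").replace("T_", "N_").replace("X_", "T_")
            for c in matrix.counts.columns
        }
        flipped = matrix.counts.rename(columns=flipped_cols)
        reversed_matrix = SpectralCountMatrix(flipped, matrix.features.copy())
        a = rank_by_association(matrix).sort_index()
        b = rank_by_association(reversed_matrix).sort_index()
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_unmapped_genes_excluded(self):
        counts = pd.DataFrame(
            [[1, 2, 1, 9, 8, 9], [5, 5, 5, 5, 5, 5]],
            index=["MAPPED", "UNMAPPED"], columns=COLS, dtype=float,
        )
        m = matrix_from_counts(counts, id_missing=[False, True])
        ranked = rank_by_association(m)
        assert list(ranked.index) == ["MAPPED"]

    def test_variance_metric_needs_two_samples_per_class(self):
        counts = pd.DataFrame(
            [[1, 2]], index=["G"], columns=["N_b1_t1", "T_b1_t1"], dtype=float
        )
        with pytest.raises(ValueError):
            rank_by_association(matrix_from_counts(counts))


class TestEnrichmentScore:
    def test_maximal_clustering_equal_scores_gives_one(self):
        # all set genes at the very top with equal scores
        ranked = pd.Series(
            [2.0, 2.0, 2.0, -1.0, -1.0, -1.0],
            index=["a", "b", "c", "d", "e", "f"],
        )
        es, leading = enrichment_score(ranked, {"a", "b", "c"})
        assert es == pytest.approx(1.0)
        assert leading == ["a", "b", "c"]

    def test_unweighted_boundary_cases(self):
        ranked = pd.Series(
            [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            index=["a", "b", "c", "d", "e", "f"],
        )
        es_top, _ = enrichment_score(ranked, {"a", "b"}, weight_exponent=0)
        assert es_top == pytest.approx(1.0)  # 2/2 - 0
        es_bottom, leading = enrichment_score(ranked, {"e", "f"}, weight_exponent=0)
        assert es_bottom == pytest.approx(-1.0)  # symmetric: -4/4
        assert leading == ["e", "f"]

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(100):
            L = int(rng.integers(8, 51))
            genes = [f"g{i:02d}" for i in range(L)]
            scores = np.sort(rng.normal(0, 2, L))[::-1]
            ranked = pd.Series(scores, index=genes)
            g = int(rng.integers(2, max(3, L // 2)))
            gene_set = set(rng.choice(genes, size=g, replace=False))
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            es, _ = enrichment_score(ranked, gene_set, weight)
            assert es == pytest.approx(
                brute_force_es(ranked, gene_set, weight), abs=1e-12
            ), f"trial {trial}"

    def test_es_bounded(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            L = int(rng.integers(6, 30))
            ranked = pd.Series(
                np.sort(rng.normal(size=L))[::-1],
                index=[f"g{i}" for i in range(L)],
            )
            gene_set = set(rng.choice(ranked.index, size=3, replace=False))
            es, _ = enrichment_score(ranked, gene_set)
            assert -1.0 <= es <= 1.0

    def test_empty_intersection_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"zz"})


class TestFilterSets:
    @pytest.mark.parametrize(
        "size,kept", [(4, False), (5, True), (500, True), (501, False)]
    )
    def test_inclusive_bounds_on_effective_size(self, size, kept):
        universe = [f"g{i}" for i in range(600)]
        coll = GeneSetCollection({"S": frozenset(universe[:size])})
        out = filter_sets(coll, universe, min_size=5, max_size=500)
        assert ("S" in out.sets) is kept

    def test_effective_size_uses_data_overlap(self):
        coll = GeneSetCollection({"S": frozenset(f"g{i}" for i in range(10))})
        # only 4 members present in the data -> dropped at min_size=5
        out = filter_sets(coll, [f"g{i}" for i in range(4)])
        assert len(out) == 0


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"SET_A": frozenset({"g1", "g2"}), "SET_B": frozenset({"g3"})},
            source="unit",
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ONLY_NAME\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(path)


class TestGseaSignificance:
    def test_reproducible_and_nes_sign_matches_es(self):
        matrix, truth = simulate_spectral_counts(n_genes=150, seed=21)
        coll = simulate_gene_sets(truth.table["gene_symbol"], n_sets=8, seed=22)
        a = gsea_significance(matrix, coll, n_perm=200, seed=5)
        b = gsea_significance(matrix, coll, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (np.sign(a["nes"]) == np.sign(a["es"])).all()
        assert ((a["es"] >= 0) == (a["direction"] == "malignant")).all()

    def test_planted_set_recovered(self):
        """A set of coherently shifted genes reaches q < 0.25, positive NES."""
        recovered = 0
        for rep in range(5):
            matrix, truth = simulate_spectral_counts(
                n_genes=200, frac_dep=0.15, effect_log2=2.0, dropout_frac=0.0,
                seed=100 + rep,
            )
            up = truth.table.loc[truth.table["status"] == "up", "gene_symbol"]
            planted = list(up[:12])
            coll = simulate_gene_sets(
                truth.table.loc[truth.table["status"] == "null", "gene_symbol"],
                n_sets=10, planted={"PLANTED": planted}, seed=200 + rep,
            )
            res = gsea_significance(matrix, coll, n_perm=300, seed=rep)
            row = res.set_index("set_name").loc["PLANTED"]
            if row["q_value"] < 0.25 and row["nes"] > 0:
                recovered += 1
        assert recovered >= 4  # >= 95% in expectation; allow one MC failure

    def test_permutation_p_invariant_to_gene_relabeling(self):
        matrix, truth = simulate_spectral_counts(n_genes=80, seed=31)
        genes = list(truth.table["gene_symbol"])
        coll = simulate_gene_sets(genes, n_sets=4, seed=32)
        res = gsea_significance(matrix, coll, n_perm=150, seed=9)

        relabel = {g: f"X{i:04d}" for i, g in enumerate(genes)}
        counts = matrix.counts.rename(index=relabel)
        feats = matrix.features.rename(index=relabel)
        feats["gene_symbol"] = [relabel[g] for g in matrix.features["gene_symbol"]]
        matrix2 = SpectralCountMatrix(counts, feats)
        coll2 = GeneSetCollection(
            {n: frozenset(relabel[g] for g in m) for n, m in coll.sets.items()}
        )
        res2 = gsea_significance(matrix2, coll2, n_perm=150, seed=9)
        merged = res.merge(res2, on="set_name", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"])

    def test_zero_permutations_rejected(self):
        matrix, truth = simulate_spectral_counts(n_genes=30, seed=41)
        coll = simulate_gene_sets(truth.table["gene_symbol"], n_sets=2, seed=42)
        with pytest.raises(ValueError):
            gsea_significance(matrix, coll, n_perm=0)

    def test_small_permutation_count_warns(self):
        matrix, truth = simulate_spectral_counts(n_genes=30, seed=43)
        coll = simulate_gene_sets(truth.table["gene_symbol"], n_sets=2, seed=44)
        with pytest.warns(UserWarning):
            gsea_significance(matrix, coll, n_perm=50, seed=1)
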
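import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crbnsplice.diffexpr import log_cpm
from crbnsplice.enrichment import (
    RankedList,
    enrichment_score,
    gsea_significance,
    gsva_scores,
)
from crbnsplice.errors import ValidationError
from crbnsplice.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection
from crbnsplice.synthetic_data import (
    SimulationConfig,
    make_gene_sets,
    simulate_cohorts,
)


def brute_force_es(genes, stats, members, weight):
    """Independent O(N) reference: explicit walk with the positive-wins tie rule."""
    order = sorted(range(len(genes)), key=lambda i: (-stats[i], genes[i]))
    hits = [genes[i] in members for i in order]
    n, m = len(order), sum(hits)
    denom = sum(abs(stats[i]) ** weight for i in order if genes[i] in members)
    running = 0.0
    vmax, vmin = 0.0, 0.0
    for pos, i in enumerate(order):
        if hits[pos]:
            running += (abs(stats[i]) ** weight / denom) if denom > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        vmax = max(vmax, running)
        vmin = min(vmin, running)
    return vmax if vmax >= -vmin else vmin


def ranked(stats_by_gene):
    return RankedList.from_stats(pd.Series(stats_by_gene))


class TestRankedList:
    def test_orders_descending_with_gene_tiebreak(self):
        r = ranked({"b": 1.0, "a": 1.0, "c": 2.0})
        assert r.genes == ("c", "a", "b")

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValidationError):
            RankedList(("a", "a"), np.array([2.0, 1.0]))


class TestEnrichmentScore:
    def test_full_universe_set_scores_one(self):
        r = ranked({"a": 3.0, "b": 2.0, "c": 1.0})
        es, _ = enrichment_score(r, GeneSet("S", "", ("a", "b", "c")))
        assert es == pytest.approx(1.0)

    def test_top_two_of_four(self):
        r = ranked({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
        es, running = enrichment_score(r, GeneSet("S", "", ("a", "b")), 1.0)
        # hits contribute 3/5 then 2/5; peak of 1.0 after the second hit
        assert es == pytest.approx(1.0)
        assert running[1] == pytest.approx(1.0)

    def test_bottom_two_of_four(self):
        r = ranked({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
        es, _ = enrichment_score(r, GeneSet("S", "", ("c", "d")), 1.0)
        # two leading misses at -1/2 each reach -1.0 before any hit
        assert es == pytest.approx(-1.0)

    def test_no_overlap_is_error(self):
        r = ranked({"a": 1.0, "b": 0.5})
        with pytest.raises(ValidationError, match="no overlap"):
            enrichment_score(r, GeneSet("S", "", ("x",)))

    def test_weight_zero_invariant_to_monotone_transform(self, rng):
        stats = rng.normal(size=30)
        genes = [f"g{i}" for i in range(30)]
        members = tuple(rng.choice(genes, size=8, replace=False))
        s = GeneSet("S", "", members)
        r1 = ranked(dict(zip(genes, stats)))
        r2 = ranked(dict(zip(genes, np.exp(stats))))  # rank-preserving
        es1, _ = enrichment_score(r1, s, 0.0)
        es2, _ = enrichment_score(r2, s, 0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(4, 40),
        m=st.integers(1, 8),
        weight=st.sampled_from([0.0, 1.0, 1.5]),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_and_is_bounded(self, n, m, weight, seed):
        rng = np.random.default_rng(seed)
        m = min(m, n - 1)
        genes = [f"g{i}" for i in range(n)]
        stats = np.round(rng.normal(size=n), 2)  # rounding induces ties
        members = tuple(rng.choice(genes, size=m, replace=False))
        r = ranked(dict(zip(genes, stats)))
        es, _ = enrichment_score(r, GeneSet("S", "", members), weight)
        oracle = brute_force_es(genes, list(stats), members, weight)
        assert abs(es) <= 1.0 + 1e-12
        assert es == pytest.approx(oracle, abs=1e-12)


class TestGseaSignificance:
    def _ranked(self, rng, n=400):
        return ranked({f"g{i}": float(s) for i, s in enumerate(rng.normal(size=n))})

    def test_seed_required(self, rng):
        r = self._ranked(rng)
        sets = GeneSetCollection([GeneSet("S", "", r.genes[:10])])
        with pytest.raises(ValueError, match="seed"):
            gsea_significance(r, sets, n_perm=100)

    def test_determinism(self, rng):
        r = self._ranked(rng)
        sets = GeneSetCollection(
            [GeneSet(f"S{i}", "", tuple(r.genes[i * 13 : i * 13 + 10])) for i in range(5)]
        )
        t1 = gsea_significance(r, sets, n_perm=200, seed=5)
        t2 = gsea_significance(r, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_leading_set_is_significant(self):
        stats = {f"g{i}": 10.0 - i * 0.01 for i in range(500)}
        r = ranked(stats)
        planted = GeneSet("LEAD", "", tuple(r.genes[:20]))
        decoys = [
            GeneSet(f"D{i}", "", tuple(r.genes[i::23][:20])) for i in range(1, 8)
        ]
        table = gsea_significance(
            r, GeneSetCollection([planted, *decoys]), n_perm=1000, seed=11
        )
        assert table.loc["LEAD", "q"] < 0.05
        assert table.index[0] == "LEAD"

    def test_nonoverlapping_set_skipped_with_warning(self, rng, caplog):
        r = self._ranked(rng)
        sets = GeneSetCollection(
            [GeneSet("S", "", r.genes[:10]), GeneSet("MISS", "", ("zz",))]
        )
        with caplog.at_level(logging.WARNING):
            table = gsea_significance(r, sets, n_perm=100, seed=1)
        assert "MISS" not in table.index
        assert any("MISS" in rec.message for rec in caplog.records)

    def test_nperm_floor(self, rng):
        r = self._ranked(rng)
        sets = GeneSetCollection([GeneSet("S", "", r.genes[:10])])
        with pytest.raises(ValueError, match="n_perm"):
            gsea_significance(r, sets, n_perm=50, seed=1)


class TestGsvaScores:
    def _matrix(self, values, genes=None, samples=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log")

    def test_directionality(self, rng):
        n_genes = 60
        base = rng.normal(size=(n_genes, 3))
        members = [f"g{i}" for i in range(10)]
        base[:10, 0] += 5.0  # set members top-ranked in sample s0
        base[:10, 1] -= 5.0  # and bottom-ranked in sample s1
        m = self._matrix(base)
        scores = gsva_scores(m, GeneSetCollection([GeneSet("S", "", tuple(members))]))
        assert scores.loc["S", "s0"] > 0 > scores.loc["S", "s1"]

    def test_scores_bounded(self, rng):
        m = self._matrix(rng.normal(size=(40, 8)))
        sets = GeneSetCollection([GeneSet("S", "", tuple(f"g{i}" for i in range(12)))])
        scores = gsva_scores(m, sets)
        assert (scores.abs() <= 1.0).all().all()

    def test_duplicate_samples_get_identical_scores(self, rng):
        vals = rng.normal(size=(40, 4))
        vals[:, 3] = vals[:, 0]
        m = self._matrix(vals)
        sets = GeneSetCollection([GeneSet("S", "", tuple(f"g{i}" for i in range(8)))])
        scores = gsva_scores(m, sets)
        assert scores["s0"].equals(scores["s3"])

    def test_gene_order_invariance(self, rng):
        vals = rng.normal(size=(50, 5))
        m = self._matrix(vals)
        perm = rng.permutation(50)
        m_perm = ExpressionMatrix(m.data.iloc[perm], "log")
        sets = GeneSetCollection([GeneSet("S", "", tuple(f"g{i}" for i in range(3, 20)))])
        pd.testing.assert_frame_equal(gsva_scores(m, sets), gsva_scores(m_perm, sets))

    def test_too_few_samples_rejected(self, rng):
        m = self._matrix(rng.normal(size=(40, 2)))
        sets = GeneSetCollection([GeneSet("S", "", ("g0", "g1", "g2", "g3", "g4"))])
        with pytest.raises(ValidationError, match="3 samples"):
            gsva_scores(m, sets)

    def test_small_set_skipped_with_warning(self, rng, caplog):
        m = self._matrix(rng.normal(size=(40, 5)))
        sets = GeneSetCollection(
            [
                GeneSet("OK", "", tuple(f"g{i}" for i in range(8))),
                GeneSet("TINY", "", ("g0", "zz")),
            ]
        )
        with caplog.at_level(logging.WARNING):
            scores = gsva_scores(m, sets, min_size=5)
        assert list(scores.index) == ["OK"]
        assert any("TINY" in rec.message for rec in caplog.records)

    def test_planted_pathway_separates_groups(self):
        config = SimulationConfig(
            n_cohorts=1,
            n_samples=100,
            n_genes=600,
            prevalence_high=0.3,
            pathway_effects={"SET001": 1.5},
            seed=21,
        )
        from crbnsplice.synthetic_data import default_genes

        genes = default_genes(600)
        sets = make_gene_sets(genes, 3, 30, seed=8)
        cohort = simulate_cohorts(config, gene_sets=sets)[0]
        scores = gsva_scores(log_cpm(cohort.counts), sets)
        s = scores.loc["SET001"]
        high = np.array(
            [cohort.truth["group"][c] == "HIGH" for c in scores.columns]
        )
        x, y = s[high].to_numpy(), s[~high].to_numpy()
        # rank-based AUC
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(x, y, alternative="two-sided").statistic
        auc = u / (len(x) * len(y))
        assert auc >= 0.9
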
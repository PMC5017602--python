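"""Running-sum enrichment score, permutation null, NES and p-value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stagescan import (
    ExpressionMatrix,
    GeneSignature,
    SampleAnnotation,
    enrichment_score,
    gsea,
    nes_and_p,
    permutation_null,
)
from stagescan.signatures import RankedList


def _ranked(n: int) -> RankedList:
    return RankedList([f"g{i}" for i in range(n)], np.linspace(3, -3, n))


def _cohort(seed, n_genes=200, n_per_group=10, delta=0.0, set_size=20):
    """Two-group Gaussian matrix with the first set_size genes shifted by
    delta in the target group."""
    rng = np.random.default_rng(seed)
    values = rng.normal(6.0, 1.0, size=(n_genes, 2 * n_per_group))
    values[:set_size, :n_per_group] += delta
    m = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(2 * n_per_group)],
        )
    )
    anns = [
        SampleAnnotation(s, "T" if i < n_per_group else "R")
        for i, s in enumerate(m.sample_ids)
    ]
    sig = GeneSignature("planted", [f"g{i:04d}" for i in range(set_size)])
    return m, anns, sig


class TestEnrichmentScore:
    def test_set_of_top_gene_scores_one(self):
        es, _, edge = enrichment_score(_ranked(5), GeneSignature("s", ["g0"]))
        assert es == pytest.approx(1.0)
        assert edge == ["g0"]

    def test_set_of_bottom_gene_scores_minus_one(self):
        es, _, edge = enrichment_score(_ranked(5), GeneSignature("s", ["g4"]))
        assert es == pytest.approx(-1.0)
        assert edge == ["g4"]

    def test_four_gene_walk_hand_enumeration(self):
        # N=4, set = {rank-2 gene}: running sum -1/3, 2/3, 1/3, 0
        es, running, edge = enrichment_score(
            _ranked(4), GeneSignature("s", ["g1"])
        )
        assert np.allclose(running, [-1 / 3, 2 / 3, 1 / 3, 0.0])
        assert es == pytest.approx(2 / 3)
        assert edge == ["g1"]

    def test_running_sum_ends_at_zero(self):
        es, running, _ = enrichment_score(
            _ranked(50), GeneSignature("s", [f"g{i}" for i in range(3, 20, 4)])
        )
        assert abs(running[-1]) < 1e-12
        assert abs(es) <= 1.0

    @given(st.integers(2, 40), st.data())
    def test_reversed_ranking_negates_es(self, n, data):
        """Reversing the list flips the ES sign (and always its magnitude).

        When the positive and negative extrema tie exactly — a walk
        symmetric under reversal — only the magnitude is well defined, so
        the sign assertion is restricted to unique extrema.
        """
        members = data.draw(
            st.sets(st.integers(0, n - 1), min_size=1, max_size=n - 1)
        )
        sig = GeneSignature("s", [f"g{i}" for i in sorted(members)])
        fwd = _ranked(n)
        rev = RankedList(fwd.gene_ids[::-1], -fwd.statistic[::-1])
        es_f, run_f, _ = enrichment_score(fwd, sig)
        es_r, _, _ = enrichment_score(rev, sig)
        assert abs(es_f) == pytest.approx(abs(es_r), abs=1e-12)
        if abs(run_f.max() + run_f.min()) > 1e-9:  # unique extremum
            assert es_f == pytest.approx(-es_r, abs=1e-12)

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(_ranked(5), GeneSignature("s", ["absent"]))

    def test_whole_universe_errors(self):
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(
                _ranked(3), GeneSignature("s", ["g0", "g1", "g2"])
            )


class TestPermutationNull:
    def test_exhaustive_three_vs_three_enumerates_twenty(self):
        m, anns, sig = _cohort(0, n_genes=30, n_per_group=3, set_size=5)
        null = permutation_null(
            m, anns, "T", sig, n_perm=20, seed=0, mode="phenotype",
            exhaustive=True,
        )
        assert null.size == 20  # C(6,3)

    def test_same_seed_reproduces_null(self):
        m, anns, sig = _cohort(1, n_genes=50, n_per_group=5, set_size=8)
        a = permutation_null(m, anns, "T", sig, n_perm=50, seed=7)
        b = permutation_null(m, anns, "T", sig, n_perm=50, seed=7)
        assert np.array_equal(a, b)

    def test_gene_label_singleton_null_on_support(self):
        m, anns, _ = _cohort(2, n_genes=10, n_per_group=5)
        from stagescan import rank_genes

        ranked = rank_genes(m, anns, "T")
        support = set()
        for g in ranked.gene_ids:
            es, _, _ = enrichment_score(ranked, GeneSignature("x", [g]))
            support.add(round(es, 12))
        null = permutation_null(
            m, anns, "T", GeneSignature("s", [m.gene_ids[0]]),
            n_perm=100, seed=3, mode="gene_label",
        )
        assert {round(v, 12) for v in null} <= support

    def test_too_few_samples_falls_back_to_gene_label(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(20, 5)),
                index=[f"g{i}" for i in range(20)],
                columns=[f"s{i}" for i in range(5)],
            )
        )
        anns = [
            SampleAnnotation(s, "T" if i < 1 else "R")
            for i, s in enumerate(m.sample_ids)
        ]
        sig = GeneSignature("s", ["g0", "g1"])
        with pytest.warns(UserWarning, match="falling back"):
            null = permutation_null(m, anns, "T", sig, n_perm=10, seed=0)
        assert null.size == 10


class TestNesAndP:
    def test_self_normalisation(self):
        nes, p = nes_and_p(0.5, np.full(10, 0.5))
        assert nes == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_add_one_floor(self):
        null = np.array([0.1] * 9 + [-0.2])
        nes, p = nes_and_p(0.9, null)
        assert p == pytest.approx(1 / 10)  # 9 same-sign nulls, none as extreme

    def test_worked_example(self):
        nes, p = nes_and_p(0.6, np.array([0.2, 0.4, -0.3]))
        assert nes == pytest.approx(2.0)
        assert p == pytest.approx(1 / 3)

    def test_p_respects_support_floor(self):
        null = np.linspace(-0.5, 0.5, 101)
        _, p = nes_and_p(0.9, null)
        assert p >= 1 / (null.size + 1)


class TestGsea:
    def test_planted_signal_is_significant(self):
        m, anns, sig = _cohort(0, delta=2.0)
        res = gsea(m, anns, "T", sig, n_perm=999, seed=0)
        assert res.es > 0
        assert res.p_perm <= 0.05
        assert set(res.leading_edge) <= set(sig.genes)

    def test_disjoint_signature_errors(self):
        m, anns, _ = _cohort(1)
        with pytest.raises(ValueError, match="no overlap"):
            gsea(m, anns, "T", GeneSignature("s", ["nope"]), n_perm=10, seed=0)

    def test_null_p_values_calibrated(self):
        """Type-I error of the permutation p over 200 no-signal replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            m, anns, sig = _cohort(1000 + rep, n_genes=120, n_per_group=8,
                                   delta=0.0, set_size=15)
            res = gsea(m, anns, "T", sig, n_perm=199, seed=rep)
            hits += res.p_perm <= 0.05
        assert 0.02 <= hits / n_rep <= 0.09
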
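"""Tests for interlaboratory agreement coefficients and reference-RNA
reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from tgxddi.calls import ChemicalCall
from tgxddi.classify import DDI, INCONCLUSIVE, NON_DDI
from tgxddi.concordance import (
    AgreementTable,
    agreement_table,
    cohen_kappa,
    concordance_stats,
    gwet_ac1,
    interpret_agreement,
    pabak,
    pairwise_concordance,
    reference_rna_correlations,
)
from tgxddi.errors import (
    InsufficientDataError,
    NoOverlapError,
    UndefinedCoefficientError,
)


class TestAgreementTable:
    def test_observed_agreement(self):
        t = AgreementTable(n11=5, n10=1, n01=0, n00=4)
        assert t.po == pytest.approx(0.9)
        assert t.marginals == (0.6, 0.5)

    def test_from_pairs_drops_inconclusive_pairwise(self):
        a = {"c1": DDI, "c2": NON_DDI, "c3": INCONCLUSIVE, "c4": DDI}
        b = {"c1": DDI, "c2": DDI, "c3": NON_DDI, "c5": NON_DDI}
        t = agreement_table(a, b)
        # c3 dropped (inconclusive in a), c4/c5 not shared -> c1, c2 remain
        assert t.total == 2
        assert (t.n11, t.n01) == (1, 1)

    def test_chemical_call_inputs_respect_validity(self):
        def cc(comp, call, valid):
            return ChemicalCall(comp, "L", call, valid, "")

        a = [cc("c1", DDI, False), cc("c2", NON_DDI, False), cc("c3", NON_DDI, True)]
        b = [cc("c1", DDI, True), cc("c2", NON_DDI, True), cc("c3", NON_DDI, True)]
        t = agreement_table(a, b)
        # c2 excluded: a's non-DDI call came from an invalid test.
        # c1 kept: DDI calls do not require validity.
        assert t.total == 2 and t.n11 == 1 and t.n00 == 1

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            agreement_table({"c1": DDI}, {"c2": DDI})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AgreementTable(n11=-1, n10=0, n01=0, n00=2)


class TestCoefficients:
    def test_perfect_agreement_gives_all_ones(self):
        """Agreement over 14 compounds with no disagreement yields
        kappa = PABAK = AC1 = 1 exactly."""
        t = AgreementTable(n11=10, n10=0, n01=0, n00=4)
        stats = concordance_stats(t)
        assert stats.kappa == 1.0
        assert stats.pabak == 1.0
        assert stats.ac1 == 1.0
        assert (stats.kappa_band, stats.pabak_band, stats.ac1_band) == (
            "very good",
        ) * 3

    def test_kappa_textbook_value(self):
        # Po = 0.8, marginals 0.5/0.5 -> Pe = 0.5 -> kappa = 0.6
        t = AgreementTable(n11=4, n10=1, n01=1, n00=4)
        assert cohen_kappa(t) == pytest.approx(0.6)

    def test_kappa_complete_disagreement_balanced(self):
        t = AgreementTable(n11=0, n10=5, n01=5, n00=0)
        assert cohen_kappa(t) == pytest.approx(-1.0)

    def test_kappa_undefined_when_both_raters_constant(self):
        with pytest.raises(UndefinedCoefficientError):
            cohen_kappa(AgreementTable(n11=7, n10=0, n01=0, n00=0))

    def test_pabak_is_linear_in_po(self):
        assert pabak(AgreementTable(n11=9, n10=1, n01=0, n00=0)) == pytest.approx(0.8)
        assert pabak(AgreementTable(n11=0, n10=1, n01=1, n00=0)) == pytest.approx(-1.0)

    def test_ac1_hand_computed_example(self):
        # n = 10, Po = 0.9, marginals (0.9, 0.8), pi = 0.85,
        # Pe = 2 * 0.85 * 0.15 = 0.255 -> AC1 = 0.645 / 0.745
        t = AgreementTable(n11=8, n10=1, n01=0, n00=1)
        assert gwet_ac1(t) == pytest.approx(0.645 / 0.745)

    def test_ac1_robust_where_kappa_collapses(self):
        """At extreme prevalence with high observed agreement, kappa is
        near zero while AC1 stays high (the paradox AC1 is built for)."""
        t = AgreementTable(n11=18, n10=1, n01=1, n00=0)
        assert cohen_kappa(t) < 0.1
        assert gwet_ac1(t) > 0.8

    def test_balanced_marginals_make_kappa_equal_pabak(self):
        """When both marginals are 0.5, Pe = 0.5 for both kappa and PABAK,
        so the coefficients coincide."""
        t = AgreementTable(n11=4, n10=1, n01=1, n00=4)
        assert cohen_kappa(t) == pytest.approx(pabak(t))
        assert gwet_ac1(t) == pytest.approx(pabak(t))

    def test_unity_iff_no_disagreement(self, rng):
        for _ in range(100):
            n11, n10, n01, n00 = rng.integers(0, 6, size=4)
            if n11 + n00 == 0 or n11 + n10 + n01 + n00 == 0:
                continue
            t = AgreementTable(int(n11), int(n10), int(n01), int(n00))
            assert (pabak(t) == 1.0) == (n10 + n01 == 0)


class TestBands:
    @pytest.mark.parametrize(
        "value, band",
        [
            (1.0, "very good"),
            (0.81, "very good"),
            (0.8, "good"),
            (0.61, "good"),
            (0.5, "moderate"),
            (0.41, "moderate"),
            (0.3, "fair"),
            (0.20, "fair"),
            (0.15, "poor"),
            (-0.5, "poor"),
            # values inside the printed micro-gaps map to the band below
            (0.405, "fair"),
            (0.605, "moderate"),
            (0.805, "good"),
        ],
    )
    def test_band_boundaries(self, value, band):
        assert interpret_agreement(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_agreement(1.5)


class TestPairwise:
    def test_all_pairs_reported(self):
        calls = {f"L{i}": {"c1": DDI, "c2": NON_DDI} for i in range(1, 5)}
        df = pairwise_concordance(calls)
        assert len(df) == 6  # C(4, 2)
        assert (df["kappa"] == 1.0).all()
        assert (df["kappa_band"] == "very good").all()


class TestReferenceRna:
    def _counts(self, rng, n_genes=64, n_labs=4):
        base = rng.lognormal(6, 1, size=n_genes)
        data = {
            f"L{i}": np.round(base * rng.lognormal(0, 0.05, size=n_genes))
            for i in range(n_labs)
        }
        return pd.DataFrame(data, index=[f"g{j}" for j in range(n_genes)])

    def test_identical_profiles_correlate_perfectly(self, rng):
        counts = self._counts(rng, n_labs=1)
        counts["L1"] = counts["L0"] * 2  # pure depth difference
        pearson, spearman = reference_rna_correlations(counts)
        assert pearson.loc["L0", "L1"] == pytest.approx(1.0)
        assert spearman.loc["L0", "L1"] == pytest.approx(1.0)

    def test_monotone_distortion_preserves_spearman_only(self, rng):
        counts = self._counts(rng, n_labs=1)
        counts["L1"] = np.round(counts["L0"] ** 1.6)
        pearson, spearman = reference_rna_correlations(counts)
        assert spearman.loc["L0", "L1"] == pytest.approx(1.0, abs=1e-6)
        assert pearson.loc["L0", "L1"] < spearman.loc["L0", "L1"] + 1e-12

    def test_matches_direct_formula_on_toy(self):
        counts = pd.DataFrame(
            {"A": [10, 200, 3000, 50, 400], "B": [12, 150, 2800, 70, 350]},
            index=list("abcde"),
        )
        pearson, spearman = reference_rna_correlations(counts)
        logged = np.log2((counts + 0.5) / counts.sum(axis=0))
        assert pearson.loc["A", "B"] == pytest.approx(
            pearsonr(logged["A"], logged["B"]).statistic
        )
        assert spearman.loc["A", "B"] == pytest.approx(
            spearmanr(logged["A"], logged["B"]).statistic
        )

    def test_matrices_are_symmetric_with_unit_diagonal(self, rng):
        counts = self._counts(rng)
        pearson, spearman = reference_rna_correlations(counts)
        for m in (pearson, spearman):
            assert np.allclose(m.to_numpy(), m.to_numpy().T)
            assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_insufficient_data_rejected(self, rng):
        counts = self._counts(rng)
        with pytest.raises(InsufficientDataError):
            reference_rna_correlations(counts[["L0"]])
        with pytest.raises(InsufficientDataError):
            reference_rna_correlations(counts.head(2))
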
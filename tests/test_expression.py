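"""TPM arithmetic, fold change, the built-in DE test, and biased-set selection."""

import numpy as np
import pandas as pd
import pytest

import sexscan as sx
from sexscan import expression as ex
from sexscan import simulate


def _matrix(counts, lengths, sexes):
    genes = [f"g{i}" for i in range(len(lengths))]
    samples = [f"s{i}" for i in range(len(sexes))]
    return ex.ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        eff_length=pd.Series(lengths, index=genes, dtype=float),
        sex=pd.Series(sexes, index=samples),
    )


class TestComputeTpm:
    def test_forced_arithmetic(self):
        em = _matrix([[10], [10]], [1000, 2000], ["M"])
        tpm = em.tpm
        assert tpm.iloc[0, 0] == pytest.approx(666666.6667, abs=0.01)
        assert tpm.iloc[1, 0] == pytest.approx(333333.3333, abs=0.01)

    def test_single_expressed_gene_takes_the_million(self):
        em = _matrix([[0], [7]], [500, 500], ["M"])
        assert em.tpm.iloc[1, 0] == pytest.approx(1e6)

    def test_scale_invariance(self):
        a = _matrix([[10], [20], [5]], [100, 200, 300], ["M"]).tpm
        b = _matrix([[20], [40], [10]], [100, 200, 300], ["M"]).tpm
        pd.testing.assert_frame_equal(a, b)

    def test_columns_sum_to_a_million(self, xy_result):
        sums = xy_result.expr.tpm.sum(axis=0)
        assert np.allclose(sums, 1e6, atol=1e-3)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            _matrix([[0], [0]], [100, 100], ["M"]).tpm

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[1], [1]], [100, 0], ["M"]).tpm


class TestFoldChange:
    def test_equal_means_give_zero(self):
        em = _matrix([[5, 5]], [100], ["M", "F"])
        assert ex.fold_change(em.tpm, em.sex).iloc[0] == pytest.approx(0.0)

    def test_zero_female_expression(self):
        tpm = pd.DataFrame({"m1": [100.0], "f1": [0.0]}, index=["g0"])
        sex = pd.Series({"m1": "M", "f1": "F"})
        assert ex.fold_change(tpm, sex).iloc[0] == pytest.approx(np.log2(100.1 / 0.1), abs=1e-6)

    def test_swapping_sexes_negates(self):
        tpm = pd.DataFrame({"a": [30.0, 1.0], "b": [2.0, 50.0]}, index=["g0", "g1"])
        fwd = ex.fold_change(tpm, pd.Series({"a": "M", "b": "F"}))
        rev = ex.fold_change(tpm, pd.Series({"a": "F", "b": "M"}))
        assert np.allclose(fwd, -rev)

    def test_missing_sex_errors(self):
        tpm = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError, match="no samples"):
            ex.fold_change(tpm, pd.Series({"a": "M"}))


class TestDeTest:
    def test_identical_sexes_no_noise_nothing_significant(self):
        counts = np.tile([[50], [80], [20]], (1, 6))
        em = _matrix(counts, [100, 100, 100], ["M"] * 3 + ["F"] * 3)
        table = ex.de_test(em)
        assert not table["significant"].any()
        assert (table["pvalue"] == 1.0).all()

    def test_needs_two_samples_per_sex(self):
        em = _matrix([[1, 2], [3, 4]], [100, 100], ["M", "F"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            ex.de_test(em)

    def test_recovers_truth_on_synthetic_data(self):
        cfg = sx.SimConfig(
            seed=21, architecture="NONE", n_autosomes=2,
            scaffold_length_bp=1_000_000, n_genes_per_scaffold=250,
            frac_biased_male=0.05, frac_biased_female=0.05, nb_dispersion=0.05,
        )
        _, annotation, truth = simulate.simulate_genome(cfg)
        em = simulate.simulate_expression(annotation, truth, cfg)
        table = ex.de_test(em)
        biased = truth.biased_gene_ids["M"] | truth.biased_gene_ids["F"]
        called = set(table.loc[table["significant"], "gene_id"])
        sensitivity = len(called & biased) / len(biased)
        fdr = len(called - biased) / max(1, len(called))
        assert sensitivity >= 0.8
        assert fdr <= 0.10

    def test_table_invariants(self, xy_result):
        t = xy_result.de_table
        assert ((t["fdr"] >= t["pvalue"]) | np.isclose(t["fdr"], t["pvalue"])).all()
        assert (t["significant"] == (t["fdr"] < 0.05)).all()


class TestSelectBiased:
    @staticmethod
    def _table(rows):
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc_mf", "fdr"])
        df["pvalue"] = df["fdr"]
        df["significant"] = df["fdr"] < 0.05
        return df.set_index("gene_id", drop=False)

    def test_threshold_gates(self):
        table = self._table(
            [
                ("above", 3.4, 0.04),     # > log2(10): in
                ("at_edge", 3.3, 0.04),   # below log2(10) ~ 3.3219: out
                ("not_sig", 6.0, 0.06),   # fails the FDR gate: out
                ("female", -4.0, 0.01),   # female side
            ]
        )
        sets = ex.select_biased(table)
        assert sets.male_biased == {"above"}
        assert sets.female_biased == {"female"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        table = self._table(
            [(f"g{i}", fc, q) for i, (fc, q) in enumerate(
                zip(rng.normal(0, 4, 200), rng.random(200) * 0.1))]
        )
        sizes = []
        for thr in (2, 5, 10, 20, 50):
            s = ex.select_biased(table, fc_threshold=thr)
            sizes.append((len(s.male_biased), len(s.female_biased)))
        assert sizes == sorted(sizes, reverse=True)


class TestCrossSexFraction:
    def test_counting(self):
        genes = [f"g{i}" for i in range(100)]
        male_tpm = np.full(100, 500.0)
        female_tpm = np.zeros(100)
        female_tpm[:2] = 50.0  # exactly 2 of 100 leak above TPM 10
        tpm = pd.DataFrame({"m": male_tpm, "f": female_tpm}, index=genes)
        sex = pd.Series({"m": "M", "f": "F"})
        sets = ex.BiasedGeneSets(male_biased=set(genes), female_biased=set())
        frac = ex.cross_sex_fraction(sets, tpm, sex)
        assert frac["M"] == pytest.approx(0.02)
        assert np.isnan(frac["F"])  # empty set: missing, not zero

    def test_fully_specific_gives_zero(self):
        tpm = pd.DataFrame({"m": [100.0], "f": [0.0]}, index=["g0"])
        sex = pd.Series({"m": "M", "f": "F"})
        sets = ex.BiasedGeneSets(male_biased={"g0"}, female_biased=set())
        assert ex.cross_sex_fraction(sets, tpm, sex)["M"] == 0.0

    def test_sex_limited_simulation_leaks_little(self):
        # biased genes nearly silent in the opposite sex, as for sperm genes;
        # transcriptome-scale gene count so one stray read stays below TPM 10
        cfg = sx.SimConfig(
            seed=13, architecture="XY", biased_opposite_scale=0.001,
            frac_biased_male=0.1, frac_biased_female=0.03,
            n_autosomes=2, scaffold_length_bp=2_000_000,
            sex_scaffold_length_bp=2_000_000, n_genes_per_scaffold=500,
        )
        _, annotation, truth = simulate.simulate_genome(cfg)
        em = simulate.simulate_expression(annotation, truth, cfg)
        table = ex.de_test(em)
        sets = ex.select_biased(table)
        assert len(sets.male_biased) > 10
        frac = ex.cross_sex_fraction(sets, em.tpm, em.sex)
        assert frac["M"] < 0.05


def test_external_de_table_ingestion(tmp_path):
    df = pd.DataFrame(
        {"gene_id": ["a", "b", "c"], "log2fc_mf": [4.0, -4.0, 0.1],
         "pvalue": [0.001, 0.5, 0.9]}
    )
    path = tmp_path / "de.tsv"
    df.to_csv(path, sep="\t", index=False)
    table = ex.read_de_table(path)
    assert "fdr" in table.columns
    assert table.loc["a", "significant"]
    assert not table.loc["b", "significant"]
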
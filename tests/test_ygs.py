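"""The k-mer sex-specificity scan against naive string-set oracles."""

import numpy as np
import pandas as pd
import pytest

import sexscan as sx
from sexscan import kmers, simulate, ygs
from conftest import revcomp_str, table_to_string_set, ygs_oracle


@pytest.fixture(scope="module")
def toy_setup(toy_assembly):
    """Toy assembly where tigC exists only in males (a miniature Y)."""
    truth = sx.SimTruth(
        architecture="XY",
        sex_specific_scaffolds={"tigC"},
        hemizygous_scaffolds={"tigB"},
        copy_number={
            "tigA": {"M": 2, "F": 2},
            "tigB": {"M": 1, "F": 2},
            "tigC": {"M": 1, "F": 0},
        },
    )
    cfg = sx.SimConfig(seed=30, architecture="XY", kmer_error_rate=0.005)
    tables = simulate.simulate_read_kmers(toy_assembly, truth, cfg)
    index = ygs.count_assembly_kmers(toy_assembly, k=15)
    return toy_assembly, truth, tables, index


class TestCountAssemblyKmers:
    def test_per_contig_sets_are_unique_and_canonical(self, toy_setup):
        _, _, _, index = toy_setup
        for codes in index.per_contig.values():
            assert np.array_equal(codes, np.unique(codes))
            assert np.array_equal(codes, kmers.canonicalize(codes, 15))

    def test_contig_shorter_than_k_contributes_nothing(self):
        index = ygs.count_assembly_kmers(sx.Assembly({"t": "ACGT"}), k=15)
        assert index.per_contig["t"].size == 0


class TestPVscUk:
    def test_forced_percentage(self):
        contig = np.array([1, 2, 3], dtype=np.uint64)
        rec = ygs.p_vsc_uk(
            "c", 5000, contig,
            single_copy=contig,
            carrier_trusted=contig,
            opposite_trusted=np.array([3], dtype=np.uint64),
            direction="XY",
        )
        assert rec["p_vsc_uk"] == pytest.approx(100 * 2 / 3)
        assert (rec["n_sc"], rec["n_vsc"], rec["n_vsc_uk"]) == (3, 3, 2)

    def test_all_shared_gives_zero(self):
        contig = np.arange(10, dtype=np.uint64)
        rec = ygs.p_vsc_uk("c", 5000, contig, contig, contig, contig, "XY")
        assert rec["p_vsc_uk"] == 0.0

    def test_no_validated_kmers_reported_missing(self):
        contig = np.arange(10, dtype=np.uint64)
        empty = np.empty(0, dtype=np.uint64)
        rec = ygs.p_vsc_uk("c", 5000, contig, contig, empty, empty, "XY")
        assert np.isnan(rec["p_vsc_uk"])
        assert not rec["flagged"]

    def test_tiny_vsc_denominator_never_flagged(self):
        contig = np.arange(5, dtype=np.uint64)
        empty = np.empty(0, dtype=np.uint64)
        rec = ygs.p_vsc_uk("c", 5000, contig, contig, contig, empty, "XY")
        assert rec["p_vsc_uk"] == 100.0
        assert not rec["flagged"]  # < 20 validated k-mers


class TestRunDirection:
    def test_matches_string_oracle_exactly(self, toy_setup):
        assembly, truth, tables, index = toy_setup
        carrier = table_to_string_set(tables["M"], min_count=2)
        opposite = table_to_string_set(tables["F"], min_count=2)
        expected = ygs_oracle(assembly, 15, carrier, opposite)
        res = ygs.run_direction(index, tables["M"], tables["F"], "XY").set_index("contig_id")
        for contig, (n_sc, n_vsc, n_uk) in expected.items():
            row = res.loc[contig]
            assert (row["n_sc"], row["n_vsc"], row["n_vsc_uk"]) == (n_sc, n_vsc, n_uk)
            if n_vsc:
                assert row["p_vsc_uk"] == pytest.approx(100 * n_uk / n_vsc, abs=1e-9)

    def test_y_contig_flagged_only_in_xy_direction(self, toy_setup):
        _, truth, tables, index = toy_setup
        both = ygs.run_both_directions(index, tables["M"], tables["F"])
        flagged_xy = set(both["XY"].loc[both["XY"]["flagged"], "contig_id"])
        flagged_zw = set(both["ZW"].loc[both["ZW"]["flagged"], "contig_id"])
        assert flagged_xy == truth.sex_specific_scaffolds
        assert flagged_zw == set()

    def test_direction_swap_symmetry(self, toy_setup):
        _, _, tables, index = toy_setup
        xy = ygs.run_direction(index, tables["M"], tables["F"], "XY")
        zw_swapped = ygs.run_direction(index, tables["F"], tables["M"], "ZW")
        for col in ("n_sc", "n_vsc", "n_vsc_uk"):
            assert (xy[col] == zw_swapped[col]).all()

    def test_strand_invariance(self, toy_setup):
        assembly, _, tables, index = toy_setup
        flipped = sx.Assembly(
            {name: (revcomp_str(seq) if name == "tigC" else seq)
             for name, seq in assembly}
        )
        index2 = ygs.count_assembly_kmers(flipped, k=15)
        a = ygs.run_direction(index, tables["M"], tables["F"], "XY")
        b = ygs.run_direction(index2, tables["M"], tables["F"], "XY")
        pd.testing.assert_frame_equal(a, b)

    def test_opposite_set_growth_never_raises_p(self, toy_setup):
        _, _, tables, index = toy_setup
        carrier = ygs.trusted_kmers(tables["M"], 3)
        small_opp = ygs.trusted_kmers(tables["F"], 3)
        big_opp = ygs.trusted_kmers(tables["F"], 1)
        singles = index.table.codes[index.table.counts == 1]
        for cid, codes in index.per_contig.items():
            p_small = ygs.p_vsc_uk(cid, 1, codes, singles, carrier, small_opp, "XY")["p_vsc_uk"]
            p_big = ygs.p_vsc_uk(cid, 1, codes, singles, carrier, big_opp, "XY")["p_vsc_uk"]
            if not (np.isnan(p_small) or np.isnan(p_big)):
                assert p_big <= p_small + 1e-12

    def test_unknown_direction_rejected(self, toy_setup):
        _, _, tables, index = toy_setup
        with pytest.raises(ValueError, match="direction"):
            ygs.run_direction(index, tables["M"], tables["F"], "XO")

    def test_impossible_threshold_flags_nothing(self, toy_setup):
        _, _, tables, index = toy_setup
        res = ygs.run_direction(index, tables["M"], tables["F"], "XY", threshold=101)
        assert not res["flagged"].any()


class TestBidirectional:
    @staticmethod
    def _records(ps, direction):
        return pd.DataFrame(
            {
                "contig_id": [f"c{i}" for i in range(len(ps))],
                "contig_len_bp": 5000,
                "n_sc": 100, "n_vsc": 100,
                "n_vsc_uk": [int(p) for p in ps],
                "p_vsc_uk": ps,
                "direction": direction,
                "flagged": False,
            }
        )

    def test_all_zero_no_anomaly(self):
        joint, anomaly = ygs.bidirectional_stats(
            self._records([0.0] * 10, "XY"), self._records([0.0] * 10, "ZW")
        )
        assert not anomaly

    def test_thirty_percent_mid_band_triggers(self):
        ps = [50.0] * 3 + [0.0] * 7
        _, anomaly = ygs.bidirectional_stats(
            self._records(ps, "XY"), self._records(ps, "ZW")
        )
        assert anomaly

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="different contig"):
            ygs.bidirectional_stats(
                self._records([0.0], "XY"), self._records([0.0, 0.0], "ZW")
            )

    def test_private_variation_raises_both_directions(self, toy_assembly):
        """Injecting individual-private k-mers into both sexes' tables lifts
        P_VSC_UK in both directions above the error-free baseline."""
        truth = sx.SimTruth(
            architecture="NONE",
            copy_number={name: {"M": 2, "F": 2} for name in toy_assembly.sequences},
        )
        cfg = sx.SimConfig(seed=31, kmer_error_rate=0.0)
        tables = simulate.simulate_read_kmers(toy_assembly, truth, cfg)
        index = ygs.count_assembly_kmers(toy_assembly, k=15)
        base = ygs.run_both_directions(index, tables["M"], tables["F"])
        base_mean = pd.concat([base["XY"], base["ZW"]])["p_vsc_uk"].mean()
        assert base_mean == pytest.approx(0.0, abs=1e-9)

        # each sex's pool misses a private slice of the genome's k-mers,
        # as if some individuals carry divergent haplotypes
        rng = np.random.default_rng(99)
        varied = {}
        for sex, tab in tables.items():
            drop = rng.random(tab.codes.size) < 0.2
            varied[sex] = ygs.KmerCountTable(
                k=tab.k, codes=tab.codes[~drop], counts=tab.counts[~drop],
                source=tab.source,
            )
        res = ygs.run_both_directions(index, varied["M"], varied["F"])
        mean_p = pd.concat([res["XY"], res["ZW"]])["p_vsc_uk"].mean()
        assert mean_p > base_mean + 5.0
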
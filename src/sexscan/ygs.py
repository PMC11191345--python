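"""Genome-scan for sex-specific contigs from per-sex read k-mer tables.

The scan asks, per contig: of the contig's k-mers that occur exactly
once in the whole assembly (single copy, SC) and are confirmed by the
reads of the sex expected to carry the contig (validated, VSC), what
percentage is absent from the opposite sex's reads (unmatched,
VSC_UK)? That percentage — P_VSC_UK — approaches 100 for a contig
present in only one sex (a Y or W) and 0 for ordinary autosomal
sequence. The scan runs in two directions: XY (carrier = male reads,
opposite = female; flags Y candidates) and ZW (mirrored; flags W
candidates).

Read k-mers first pass a trusted filter (count >= 2 by default) to
strip sequencing-error singletons. Contigs are flagged when P_VSC_UK
exceeds a threshold (default 80) and the contig is at least 1,000 bp;
contigs with fewer than 20 validated k-mers are reported but never
flagged, since a percentage on a tiny denominator is unstable.

A diagnostic joint table of (P_XY, P_ZW) per contig flags the anomaly
where many contigs sit near 50% in BOTH directions — the signature of
individual variability / heterozygosity rather than sex linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import KmerCountTable, encode_kmers
from .simulate import Assembly

P_THRESHOLD = 80.0
MIN_CONTIG_LEN = 1000
MIN_TRUSTED_COUNT = 2
MIN_VSC = 20

RESULT_COLUMNS = [
    "contig_id", "contig_len_bp", "n_sc", "n_vsc", "n_vsc_uk",
    "p_vsc_uk", "direction", "flagged",
]


@dataclass
class AssemblyKmerIndex:
    """Whole-assembly canonical k-mer counts plus per-contig distinct k-mer sets."""

    table: KmerCountTable
    per_contig: dict  # contig id -> sorted unique uint64 codes
    contig_lengths: dict

    @property
    def k(self) -> int:
        return self.table.k


def count_assembly_kmers(assembly: Assembly, k: int = 15) -> AssemblyKmerIndex:
    """Canonical k-mer counts over the assembly and per-contig k-mer sets.

    Windows containing non-ACGT characters contribute nothing; contigs
    shorter than k contribute no k-mers.
    """
    per_contig = {}
    parts = []
    for name, seq in assembly:
        codes = encode_kmers(seq, k)
        parts.append(codes)
        per_contig[name] = np.unique(codes)
    allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    return AssemblyKmerIndex(
        table=KmerCountTable.from_code_multiset(allcodes, k, source="assembly"),
        per_contig=per_contig,
        contig_lengths=assembly.lengths(),
    )


def trusted_kmers(table: KmerCountTable, min_count: int = MIN_TRUSTED_COUNT) -> np.ndarray:
    """Sorted codes of read k-mers with count >= ``min_count`` (error filter)."""
    return table.filter_min_count(min_count)


def p_vsc_uk(
    contig_id: str,
    contig_len_bp: int,
    contig_codes: np.ndarray,
    single_copy: np.ndarray,
    carrier_trusted: np.ndarray,
    opposite_trusted: np.ndarray,
    direction: str,
    threshold: float = P_THRESHOLD,
    min_len: int = MIN_CONTIG_LEN,
    min_vsc: int = MIN_VSC,
) -> dict:
    """One contig's record: SC -> VSC -> VSC_UK counts and the percentage.

    SC = contig k-mers single-copy in the whole assembly; VSC = SC
    confirmed by the carrier sex's trusted read k-mers; VSC_UK = VSC
    absent from the opposite sex's trusted read k-mers;
    p_vsc_uk = 100 * |VSC_UK| / |VSC| (NaN when |VSC| = 0).
    """
    sc = contig_codes[np.isin(contig_codes, single_copy, assume_unique=True)]
    vsc = sc[np.isin(sc, carrier_trusted, assume_unique=True)]
    uk = vsc[~np.isin(vsc, opposite_trusted, assume_unique=True)]
    n_vsc = int(vsc.size)
    p = 100.0 * uk.size / n_vsc if n_vsc else float("nan")
    return {
        "contig_id": contig_id,
        "contig_len_bp": int(contig_len_bp),
        "n_sc": int(sc.size),
        "n_vsc": n_vsc,
        "n_vsc_uk": int(uk.size),
        "p_vsc_uk": p,
        "direction": direction,
        "flagged": bool(
            n_vsc >= min_vsc and contig_len_bp >= min_len and p > threshold
        ),
    }


def run_direction(
    index: AssemblyKmerIndex,
    reads_m: KmerCountTable,
    reads_f: KmerCountTable,
    direction: str,
    threshold: float = P_THRESHOLD,
    min_len: int = MIN_CONTIG_LEN,
    min_count: int = MIN_TRUSTED_COUNT,
    min_vsc: int = MIN_VSC,
) -> pd.DataFrame:
    """Per-contig P_VSC_UK records in one direction.

    XY: carrier = male reads, opposite = female reads (Y candidates).
    ZW: carrier = female reads, opposite = male reads (W candidates).
    """
    if direction == "XY":
        carrier, opposite = reads_m, reads_f
    elif direction == "ZW":
        carrier, opposite = reads_f, reads_m
    else:
        raise ValueError(f"direction must be 'XY' or 'ZW', got {direction!r}")
    single_copy = index.table.codes[index.table.counts == 1]
    carrier_t = trusted_kmers(carrier, min_count)
    opposite_t = trusted_kmers(opposite, min_count)
    records = [
        p_vsc_uk(
            cid, index.contig_lengths[cid], codes, single_copy, carrier_t,
            opposite_t, direction, threshold, min_len, min_vsc,
        )
        for cid, codes in index.per_contig.items()
    ]
    return pd.DataFrame(records, columns=RESULT_COLUMNS)


def run_both_directions(
    index: AssemblyKmerIndex,
    reads_m: KmerCountTable,
    reads_f: KmerCountTable,
    **kwargs,
) -> dict:
    """Convenience: {'XY': records, 'ZW': records}."""
    return {
        d: run_direction(index, reads_m, reads_f, d, **kwargs) for d in ("XY", "ZW")
    }


def bidirectional_stats(
    records_xy: pd.DataFrame,
    records_zw: pd.DataFrame,
    band: tuple = (40.0, 60.0),
    anomaly_frac: float = 0.10,
) -> tuple[pd.DataFrame, bool]:
    """Joint (P_XY, P_ZW) per contig and the both-directions-~50% anomaly flag.

    When more than ``anomaly_frac`` of contigs (with defined values)
    have both percentages inside ``band``, the flag is raised: such
    contigs look partly specific to BOTH sexes, which sex linkage
    cannot produce — the usual cause is private variation among the
    sequenced individuals.
    """
    xy = records_xy.set_index("contig_id")["p_vsc_uk"]
    zw = records_zw.set_index("contig_id")["p_vsc_uk"]
    if set(xy.index) != set(zw.index):
        raise ValueError("XY and ZW records cover different contig sets")
    joint = pd.DataFrame({"p_xy": xy, "p_zw": zw.reindex(xy.index)})
    defined = joint.dropna()
    if len(defined):
        in_band = (
            defined["p_xy"].between(*band) & defined["p_zw"].between(*band)
        )
        frac = float(in_band.mean())
    else:
        frac = 0.0
    joint["both_mid"] = joint["p_xy"].between(*band) & joint["p_zw"].between(*band)
    return joint, frac > anomaly_frac
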
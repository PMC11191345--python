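"""Standard-format readers/writers for the report bundle.

FASTA via Biopython; BED6 with 0-based half-open intervals and a score
column of -log10(q) clipped at 300; TSV with a stable column order and
'.' for missing values; JSON sorted and indented. All writers are
byte-deterministic for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Assembly


def write_fasta(assembly: Assembly, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in assembly
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> Assembly:
    return Assembly(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_genes_bed(annotation: pd.DataFrame, path) -> None:
    """Gene annotation as BED6 (score 0)."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["scaffold"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["scaffold", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    return df[["gene_id", "scaffold", "start", "end", "strand"]]


def write_intervals_bed(intervals: pd.DataFrame, path, qvalues=None) -> None:
    """Intervals as BED6; score = -log10(q) clipped at 300 when q given."""
    if qvalues is not None:
        q = np.clip(np.asarray(qvalues, dtype=float), 1e-300, None)
        score = np.minimum(300.0, -np.log10(q))
    else:
        score = np.zeros(len(intervals))
    bed = pd.DataFrame(
        {
            "chrom": intervals["scaffold"],
            "start": intervals["start"],
            "end": intervals["end"],
            "name": [f"region{i + 1}" for i in range(len(intervals))],
            "score": np.round(score, 4),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=".", float_format="%.6g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], **kwargs)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
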
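"""Sliding-window enrichment of sex-biased genes along the genome.

Fixed windows (default 200 kbp, 100 kbp steps) slide across every
scaffold; each window's count of strongly sex-biased genes versus the
genome-wide gene universe is tested with a one-sided Fisher exact test,
p-values are BH-corrected across all windows of one sex's analysis, and
windows at Q < 0.01 are called enriched. Overlapping enriched windows
merge into regions, and per-sex summaries count enriched bins and the
distinct scaffolds carrying them.

Conventions (all configurable): a window starts at every multiple of
the step below the scaffold length and is truncated at the scaffold
end; a gene belongs to every window it overlaps by >= 1 bp; the Fisher
"outside" margin is the de-duplicated gene universe minus the window's
genes, so each table sums to the universe size; windows with no genes
get p = 1 and stay in the BH family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, enrichment_pvalue

WINDOW_BP = 200_000
STEP_BP = 100_000
ENRICH_Q_THRESHOLD = 0.01


def make_windows(
    scaffold_lengths: dict, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP
) -> pd.DataFrame:
    """Sliding windows per scaffold: columns scaffold, start, end (0-based, half-open)."""
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    rows = []
    for name, length in scaffold_lengths.items():
        for start in range(0, int(length), step_bp):
            rows.append((name, start, min(start + window_bp, int(length))))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def assign_genes(annotation: pd.DataFrame, windows: pd.DataFrame) -> list[np.ndarray]:
    """Gene ids overlapping each window by >= 1 bp; one array per window row.

    A gene spanning several overlapping windows appears in each of them.
    Genes on scaffolds absent from the grid raise (the grid is built
    from the assembly, so such a gene is an annotation error).
    """
    known = set(windows["scaffold"])
    unknown = annotation.loc[~annotation["scaffold"].isin(known), "gene_id"]
    if len(unknown) and len(windows):
        raise ValueError(f"gene(s) on scaffold absent from the window grid: {list(unknown[:5])}")
    out: list[np.ndarray] = []
    by_scaffold = dict(tuple(annotation.groupby("scaffold", sort=False)))
    for scaffold, w_start, w_end in windows.itertuples(index=False):
        genes = by_scaffold.get(scaffold)
        if genes is None:
            out.append(np.empty(0, dtype=object))
            continue
        hit = (genes["start"].to_numpy() < w_end) & (genes["end"].to_numpy() > w_start)
        out.append(genes["gene_id"].to_numpy()[hit])
    return out


def window_fisher(
    windows: pd.DataFrame,
    assignments: list[np.ndarray],
    biased: set,
    universe: set,
    q_threshold: float = ENRICH_Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-window one-sided Fisher enrichment of ``biased`` within ``universe``.

    Each window's 2x2 table is [[biased_in, nonbiased_in],
    [biased_out, nonbiased_out]] with "out" counted over the
    de-duplicated universe minus the window's genes; the one-sided
    (greater) p is the hypergeometric tail. BH runs across all windows
    of this call; the ``enriched`` flag is qvalue < ``q_threshold``.
    """
    if len(assignments) != len(windows):
        raise ValueError("one gene list per window required")
    extra = set().union(*map(set, assignments)) - universe if assignments else set()
    if extra:
        raise ValueError(f"assigned gene(s) outside the universe: {sorted(extra)[:5]}")
    n_total = len(universe)
    n_marked = len(biased & universe)
    rows = []
    for genes in assignments:
        uniq = set(genes)
        n_in = len(uniq)
        n_biased_in = len(uniq & biased)
        rows.append(
            (
                n_biased_in,
                n_in,
                n_marked - n_biased_in,
                n_total - n_in,
                enrichment_pvalue(n_biased_in, n_in, n_marked, n_total),
            )
        )
    res = pd.DataFrame(
        rows, columns=["n_biased_in", "n_total_in", "n_biased_out", "n_total_out"
                       ] + ["pvalue"],
    )
    res = pd.concat([windows.reset_index(drop=True), res], axis=1)
    res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
    res["enriched"] = res["qvalue"] < q_threshold
    return res


def merge_regions(bins: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping or bookended intervals; columns scaffold, start, end."""
    merged = []
    ordered = bins.sort_values(["scaffold", "start", "end"])
    for scaffold, grp in ordered.groupby("scaffold", sort=True):
        cur_start = cur_end = None
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = row["start"], row["end"]
            elif row["start"] <= cur_end:
                cur_end = max(cur_end, row["end"])
            else:
                merged.append((scaffold, cur_start, cur_end))
                cur_start, cur_end = row["start"], row["end"]
        if cur_start is not None:
            merged.append((scaffold, cur_start, cur_end))
    return pd.DataFrame(merged, columns=["scaffold", "start", "end"])


@dataclass
class EnrichmentSummary:
    """Per-sex roll-up of one window-enrichment analysis."""

    n_enriched_bins: int
    n_scaffolds: int
    regions: pd.DataFrame  # merged maximal intervals

    @classmethod
    def from_result(cls, result: pd.DataFrame) -> "EnrichmentSummary":
        hits = result[result["enriched"]]
        return cls(
            n_enriched_bins=int(len(hits)),
            n_scaffolds=int(hits["scaffold"].nunique()),
            regions=merge_regions(hits[["scaffold", "start", "end"]]),
        )


def summarize(results_by_sex: dict) -> dict:
    """EnrichmentSummary per sex from the per-window Fisher results."""
    return {sx: EnrichmentSummary.from_result(df) for sx, df in results_by_sex.items()}
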
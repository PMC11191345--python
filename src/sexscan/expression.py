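"""Expression quantification, differential-expression calls, and sex-biased gene sets.

The pipeline needs, per gene: TPM, the pseudocount fold change
log2((mean TPM male + 0.1) / (mean TPM female + 0.1)), an FDR from a
differential-expression test, and from these the sets of genes more than
10-fold biased toward each sex at FDR < 0.05. The DE step is pluggable:
the built-in test is a Welch t on log2(TPM + 1) — adequate for
simulated data where truth is known — and a table produced by an
external NB-model fit (e.g. DESeq2) can be ingested instead, since
everything downstream consumes only (log2FC, FDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust

DE_FDR_THRESHOLD = 0.05
BIAS_FC_THRESHOLD = 10.0
FC_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionMatrix:
    """Raw counts plus effective lengths and sample sex labels.

    ``counts``: genes x samples integer DataFrame. ``eff_length``:
    per-gene effective length in bp (> 0). ``sex``: per-sample label,
    'M' or 'F'. TPM is computed lazily and cached.
    """

    counts: pd.DataFrame
    eff_length: pd.Series
    sex: pd.Series
    _tpm: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.eff_length.index):
            self.eff_length = self.eff_length.reindex(self.counts.index)
        if self.eff_length.isna().any() or (self.eff_length <= 0).any():
            raise ValueError("every gene needs a positive effective length")
        missing = set(self.counts.columns) - set(self.sex.index)
        if missing:
            raise ValueError(f"samples without sex labels: {sorted(missing)}")
        bad = set(self.sex) - {"M", "F"}
        if bad:
            raise ValueError(f"sex labels must be 'M' or 'F', got {sorted(bad)}")

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            self._tpm = compute_tpm(self.counts, self.eff_length)
        return self._tpm

    def samples_of(self, sex: str) -> list:
        return [s for s in self.counts.columns if self.sex[s] == sex]


@dataclass
class BiasedGeneSets:
    """Genes significantly biased more than ``fc_threshold``-fold toward one sex."""

    male_biased: set
    female_biased: set
    fc_threshold: float = BIAS_FC_THRESHOLD

    def __post_init__(self) -> None:
        if self.male_biased & self.female_biased:
            raise ValueError("a gene cannot be biased toward both sexes")

    def for_sex(self, sex: str) -> set:
        return self.male_biased if sex == "M" else self.female_biased


def compute_tpm(counts: pd.DataFrame, eff_length: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized counts scaled to 1e6 per sample.

    tpm[g, s] = 1e6 * r[g, s] / sum_g r[g, s] with r = counts / eff_length.
    """
    lengths = eff_length.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("effective lengths must be positive for all genes")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return rate.div(colsum, axis=1) * 1e6


def sex_mean_tpm(tpm: pd.DataFrame, sex: pd.Series) -> pd.DataFrame:
    """Arithmetic mean TPM per sex; columns 'M' and 'F'."""
    out = {}
    for sx in ("M", "F"):
        cols = [s for s in tpm.columns if sex[s] == sx]
        if not cols:
            raise ValueError(f"no samples of sex {sx!r}")
        out[sx] = tpm[cols].mean(axis=1)
    return pd.DataFrame(out)


def fold_change(
    tpm: pd.DataFrame, sex: pd.Series, pseudocount: float = FC_PSEUDOCOUNT
) -> pd.Series:
    """Per-gene log2((mean TPM male + c) / (mean TPM female + c)), c = 0.1."""
    means = sex_mean_tpm(tpm, sex)
    fc = np.log2((means["M"] + pseudocount) / (means["F"] + pseudocount))
    fc.name = "log2fc_mf"
    return fc


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors (geometric-mean reference).

    Computed over genes with nonzero counts in every sample and rescaled
    to geometric mean 1. Unlike total-count scaling, this is robust to a
    minority of strongly biased genes inflating one group's library —
    without it, composition shifts make every null gene look
    differentially expressed. Falls back to total counts when no gene is
    everywhere-nonzero.
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if allpos.any():
        logx = np.log(x[allpos])
        ratios = logx - logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(ratios, axis=0))
    else:
        sf = x.sum(axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def de_test(em: ExpressionMatrix) -> pd.DataFrame:
    """Built-in differential-expression call.

    Welch t per gene on log2(normalized count + 1), where counts are
    divided by median-of-ratios size factors (see :func:`size_factors`).
    Returns the standard DE table (``gene_id, log2fc_mf, pvalue, fdr,
    significant``) with BH-adjusted FDR and significance at FDR < 0.05;
    the reported fold change is the pseudocount TPM ratio, which also
    feeds the downstream 10x filter. Genes with zero variance in both
    sexes get p = 1 when the means are equal (constant gene) and p = 0
    when they differ exactly.
    """
    males, females = em.samples_of("M"), em.samples_of("F")
    if len(males) < 2 or len(females) < 2:
        raise ValueError("the built-in test needs >= 2 samples per sex")
    norm = em.counts.div(size_factors(em.counts), axis=1)
    x = np.log2(norm[males].to_numpy() + 1.0)
    y = np.log2(norm[females].to_numpy() + 1.0)
    res = _st.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    p[degenerate & (x.mean(axis=1) == y.mean(axis=1))] = 1.0
    p[degenerate & (x.mean(axis=1) != y.mean(axis=1))] = 0.0
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": em.counts.index,
            "log2fc_mf": fold_change(em.tpm, em.sex).to_numpy(),
            "pvalue": p,
            "fdr": fdr,
            "significant": fdr < DE_FDR_THRESHOLD,
        }
    ).set_index("gene_id", drop=False)


def read_de_table(path) -> pd.DataFrame:
    """Ingest an externally produced DE table (TSV: gene_id, log2fc_mf, pvalue[, fdr]).

    If the fdr column is missing it is BH-computed from pvalue. The
    significance flag is (re)derived at FDR < 0.05.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc_mf"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if "fdr" not in df.columns:
        if "pvalue" not in df.columns:
            raise ValueError("DE table needs either an fdr or a pvalue column")
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["fdr"] < DE_FDR_THRESHOLD
    return df.set_index("gene_id", drop=False)


def select_biased(
    de_table: pd.DataFrame, fc_threshold: float = BIAS_FC_THRESHOLD
) -> BiasedGeneSets:
    """Significant DEGs whose fold change exceeds ``fc_threshold`` either way.

    Male-biased: significant and log2fc_mf > log2(threshold); female-
    biased mirrored. The comparison is strict, so a gene at exactly
    10-fold is in neither set.
    """
    log_thr = np.log2(fc_threshold)
    sig = de_table[de_table["significant"]]
    male = set(sig.loc[sig["log2fc_mf"] > log_thr, "gene_id"])
    female = set(sig.loc[sig["log2fc_mf"] < -log_thr, "gene_id"])
    return BiasedGeneSets(male_biased=male, female_biased=female, fc_threshold=fc_threshold)


def cross_sex_fraction(
    sets: BiasedGeneSets,
    tpm: pd.DataFrame,
    sex: pd.Series,
    tpm_threshold: float = 10.0,
) -> dict:
    """Fraction of each sex's biased genes appreciably expressed in the other sex.

    For male-biased genes: the fraction whose mean female TPM exceeds
    ``tpm_threshold`` (and mirrored). A small value means the biased
    genes are close to sex-exclusive in expression. Empty sets yield
    NaN, not zero.
    """
    means = sex_mean_tpm(tpm, sex)
    out = {}
    for own, other in (("M", "F"), ("F", "M")):
        genes = sorted(sets.for_sex(own) & set(tpm.index))
        if not genes:
            out[own] = float("nan")
        else:
            out[own] = float((means.loc[genes, other] > tpm_threshold).mean())
    return out
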
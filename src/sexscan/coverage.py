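"""Sex-compared genome-sequencing coverage: normalization and bin classification.

Genome coverage is averaged in fixed bins (default 10 kbp), each
sample's bin values are divided by that sample's median over all bins,
and per-bin male and female means of the normalized depth are compared.
A diploid region sits near 1 in both sexes; a region hemizygous in one
sex (e.g. the X in XY males) sits near 0.5 there and near 1 in the
other; a sex-specific region (e.g. the Y) is near 0 in the sex that
lacks it. The classification bands are explicit, configurable, and wide
enough to absorb Poisson noise at ~15-20x depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HALF_BAND = (0.35, 0.65)
DIPLOID_BAND = (0.8, 1.2)
ABSENT_MAX = 0.1

BIN_LABELS = (
    "autosomal",
    "hemizygous_M",
    "hemizygous_F",
    "specific_M",
    "specific_F",
    "ambiguous",
)


@dataclass
class CoverageMatrix:
    """Median-normalized per-bin depth with per-sex means.

    ``bins``: (scaffold, start, end) rows tiling each scaffold.
    ``raw`` and ``norm``: bin x sample depth DataFrames; ``norm`` is raw
    divided by each sample's median over all bins. ``sex``: per-sample
    'M'/'F'. ``mean_m``/``mean_f``: per-bin arithmetic means of ``norm``.
    """

    bins: pd.DataFrame
    raw: pd.DataFrame
    norm: pd.DataFrame
    sex: pd.Series
    mean_m: pd.Series
    mean_f: pd.Series


def normalize_coverage(
    bins: pd.DataFrame, raw_depth: pd.DataFrame, sex: pd.Series
) -> CoverageMatrix:
    """Divide each sample column by its own median over all bins.

    Zero-depth bins are included in the median. A sample whose median
    depth is zero cannot be normalized and raises.
    """
    medians = raw_depth.median(axis=0)
    dead = medians[medians <= 0]
    if len(dead):
        raise ValueError(f"sample(s) with zero median depth: {list(dead.index)}")
    norm = raw_depth.div(medians, axis=1)
    m_cols = [s for s in norm.columns if sex[s] == "M"]
    f_cols = [s for s in norm.columns if sex[s] == "F"]
    if not m_cols or not f_cols:
        raise ValueError("need at least one sample per sex")
    return CoverageMatrix(
        bins=bins.reset_index(drop=True),
        raw=raw_depth.reset_index(drop=True),
        norm=norm.reset_index(drop=True),
        sex=sex,
        mean_m=norm[m_cols].mean(axis=1).rename("mean_M"),
        mean_f=norm[f_cols].mean(axis=1).rename("mean_F"),
    )


def classify_bins(
    cm: CoverageMatrix,
    half_band: tuple = HALF_BAND,
    diploid_band: tuple = DIPLOID_BAND,
    absent_max: float = ABSENT_MAX,
) -> pd.DataFrame:
    """Label each bin autosomal / hemizygous / sex-specific / ambiguous.

    specific_M: female mean <= ``absent_max`` while the male mean is in
    the half or diploid band (the region exists in males only);
    hemizygous_M: male mean in the half band with a diploid female mean
    (single male copy); autosomal: both means diploid; mirrored labels
    for females; anything else is ambiguous. Labels are exhaustive and
    exclusive, checked in the order specific > hemizygous > autosomal.
    """
    def _in(x: pd.Series, band: tuple) -> pd.Series:
        return (x >= band[0]) & (x <= band[1])

    m, f = cm.mean_m, cm.mean_f
    present_m = _in(m, half_band) | _in(m, diploid_band)
    present_f = _in(f, half_band) | _in(f, diploid_band)
    label = pd.Series("ambiguous", index=cm.bins.index, name="label")
    label[_in(m, diploid_band) & _in(f, diploid_band)] = "autosomal"
    label[_in(m, half_band) & _in(f, diploid_band)] = "hemizygous_M"
    label[_in(f, half_band) & _in(m, diploid_band)] = "hemizygous_F"
    label[(f <= absent_max) & present_m] = "specific_M"
    label[(m <= absent_max) & present_f] = "specific_F"
    out = cm.bins.copy()
    out["mean_M"] = m
    out["mean_F"] = f
    out["label"] = label
    return out


def coverage_of_regions(
    cm: CoverageMatrix, regions: pd.DataFrame, labels: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-region sex-mean normalized coverage over the constituent bins.

    ``regions`` has columns scaffold, start, end (e.g. merged enriched
    windows from the expression analysis). A bin belongs to a region if
    it overlaps it by >= 1 bp. When ``labels`` (from
    :func:`classify_bins`) is given, the fraction of the region's bins
    labeled autosomal is included — the "male-biased windows have
    normal coverage in both sexes" check.
    """
    known = set(cm.bins["scaffold"])
    rows = []
    for region in regions.itertuples(index=False):
        if region.scaffold not in known:
            raise ValueError(f"region on unknown scaffold: {region.scaffold!r}")
        hit = (
            (cm.bins["scaffold"] == region.scaffold)
            & (cm.bins["start"] < region.end)
            & (cm.bins["end"] > region.start)
        )
        row = {
            "scaffold": region.scaffold,
            "start": region.start,
            "end": region.end,
            "n_bins": int(hit.sum()),
            "mean_M": float(cm.mean_m[hit].mean()) if hit.any() else float("nan"),
            "mean_F": float(cm.mean_f[hit].mean()) if hit.any() else float("nan"),
        }
        if labels is not None:
            row["frac_autosomal"] = (
                float((labels.loc[hit, "label"] == "autosomal").mean()) if hit.any() else float("nan")
            )
        rows.append(row)
    cols = ["scaffold", "start", "end", "n_bins", "mean_M", "mean_F"]
    if labels is not None:
        cols.append("frac_autosomal")
    return pd.DataFrame(rows, columns=cols)
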
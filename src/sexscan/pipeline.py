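"""End-to-end orchestration and the final verdict on sex-linked regions.

The pipeline chains the three evidence channels — window enrichment of
strongly sex-biased transcripts, sex-compared normalized genome
coverage, and the bidirectional k-mer scan — and combines them into a
single architecture call:

* ``XY_candidate`` / ``ZW_candidate``: concordant k-mer flags and/or
  hemizygous or sex-specific coverage in the matching direction;
* ``no_sex_specific_regions``: no screened k-mer flags and no
  sex-specific coverage bins, regardless of how strongly expression is
  sex-biased — expression bias alone never implies a sex chromosome;
* ``inconclusive``: conflicting directions, or the genomic channels
  (coverage and k-mers) were both skipped.

K-mer flags are screened before use: a contig flagged in both
directions would have to be specific to both sexes at once, which sex
linkage cannot produce, so such contigs are discounted as
individual-variability artifacts (the same phenomenon the ~50%/50%
bidirectional anomaly flag reports).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as covmod
from . import enrich, expression, report_io, simulate, ygs

MIN_HEMIZYGOUS_FRAC = 0.01  # fraction of bins needed to count as coverage evidence

ARCHITECTURE_CALLS = (
    "XY_candidate",
    "ZW_candidate",
    "no_sex_specific_regions",
    "inconclusive",
)


def pca_profiles(matrix: pd.DataFrame, n_components: int = 2):
    """PCA of sample profiles (features x samples in, samples x PCs out).

    Columns are samples. Features are mean-centered; components use a
    deterministic sign convention (the largest-magnitude loading of
    each component is positive). Returns (coordinates DataFrame indexed
    by sample, explained-variance fractions).
    """
    x = matrix.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = x.shape
    if n_samples < 2 or n_features < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    n_components = min(n_components, n_samples, n_features)
    xc = x - x.mean(axis=0)
    total_var = float((xc**2).sum())
    cols = [f"PC{i + 1}" for i in range(n_components)]
    if total_var == 0:
        coords = pd.DataFrame(0.0, index=matrix.columns, columns=cols)
        return coords, np.zeros(n_components)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = pd.DataFrame(
        u[:, :n_components] * s[:n_components], index=matrix.columns, columns=cols
    )
    explained = (s[:n_components] ** 2) / total_var
    return coords, explained


@dataclass
class Verdict:
    """The pipeline's call plus the evidence behind it."""

    architecture_call: str
    evidence: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "architecture_call": self.architecture_call,
            "evidence": self.evidence,
            "provenance": self.provenance,
        }


def decide_verdict(
    enrich_summaries: dict | None = None,
    bin_labels: pd.DataFrame | None = None,
    records_xy: pd.DataFrame | None = None,
    records_zw: pd.DataFrame | None = None,
    anomaly: bool = False,
    min_hemizygous_frac: float = MIN_HEMIZYGOUS_FRAC,
    provenance: dict | None = None,
) -> Verdict:
    """Pure function from stage outputs to the architecture call.

    Coverage or k-mer outputs may be None (stage skipped); with both
    missing the call is always ``inconclusive``.
    """
    evidence: dict = {"anomaly_flag": bool(anomaly)}
    if enrich_summaries is not None:
        evidence["enriched_expression"] = {
            sx: {
                "n_bins": s.n_enriched_bins,
                "n_scaffolds": s.n_scaffolds,
                "n_regions": int(len(s.regions)),
            }
            for sx, s in enrich_summaries.items()
        }

    have_kmers = records_xy is not None and records_zw is not None
    flags_xy_clean: set = set()
    flags_zw_clean: set = set()
    if have_kmers:
        fx = set(records_xy.loc[records_xy["flagged"], "contig_id"])
        fz = set(records_zw.loc[records_zw["flagged"], "contig_id"])
        flags_xy_clean, flags_zw_clean = fx - fz, fz - fx
        evidence["ygs"] = {
            "flagged_XY": sorted(fx),
            "flagged_ZW": sorted(fz),
            "flagged_XY_screened": sorted(flags_xy_clean),
            "flagged_ZW_screened": sorted(flags_zw_clean),
        }

    have_cov = bin_labels is not None
    n_spec = {"M": 0, "F": 0}
    frac_hemi = {"M": 0.0, "F": 0.0}
    if have_cov:
        counts = bin_labels["label"].value_counts()
        n_bins = max(1, len(bin_labels))
        n_spec = {sx: int(counts.get(f"specific_{sx}", 0)) for sx in ("M", "F")}
        frac_hemi = {
            sx: float(counts.get(f"hemizygous_{sx}", 0)) / n_bins for sx in ("M", "F")
        }
        evidence["coverage"] = {
            "label_counts": {k: int(v) for k, v in sorted(counts.items())},
            "frac_hemizygous_M": frac_hemi["M"],
            "frac_hemizygous_F": frac_hemi["F"],
        }

    prov = dict(provenance or {})
    if not have_kmers and not have_cov:
        return Verdict("inconclusive", evidence, prov)

    xy_ev = bool(flags_xy_clean) or n_spec["M"] > 0 or frac_hemi["M"] >= min_hemizygous_frac
    zw_ev = bool(flags_zw_clean) or n_spec["F"] > 0 or frac_hemi["F"] >= min_hemizygous_frac
    if xy_ev and zw_ev:
        call = "inconclusive"
    elif xy_ev:
        call = "XY_candidate"
    elif zw_ev:
        call = "ZW_candidate"
    else:
        call = "no_sex_specific_regions"
    return Verdict(call, evidence, prov)


@dataclass
class PipelineResult:
    """Everything one end-to-end run produced."""

    config: simulate.SimConfig
    truth: simulate.SimTruth
    assembly: simulate.Assembly
    annotation: pd.DataFrame
    expr: expression.ExpressionMatrix
    de_table: pd.DataFrame
    biased: expression.BiasedGeneSets
    cross_sex: dict
    enrich_results: dict
    enrich_summaries: dict
    cov: covmod.CoverageMatrix | None
    bin_labels: pd.DataFrame | None
    region_coverage: pd.DataFrame | None
    ygs_records: dict | None
    ygs_joint: pd.DataFrame | None
    anomaly: bool
    verdict: Verdict


def _config_hash(config: simulate.SimConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(
    config: simulate.SimConfig,
    out_dir=None,
    bin_bp: int = 10_000,
    window_bp: int = enrich.WINDOW_BP,
    step_bp: int = enrich.STEP_BP,
    run_coverage: bool = True,
    run_kmers: bool = True,
) -> PipelineResult:
    """Simulate a study under ``config`` and run every analysis stage.

    With ``out_dir`` set, a deterministic report bundle (FASTA, BED,
    TSV tables, JSON truth/verdict) is written there. Coverage and
    k-mer stages can be skipped; the verdict then degrades to
    expression-only reporting and never calls a sex chromosome.
    """
    assembly, annotation, truth = simulate.simulate_genome(config)
    expr = simulate.simulate_expression(annotation, truth, config)

    de_table = expression.de_test(expr)
    biased = expression.select_biased(de_table)
    cross_sex = expression.cross_sex_fraction(biased, expr.tpm, expr.sex)

    windows = enrich.make_windows(assembly.lengths(), window_bp, step_bp)
    assignments = enrich.assign_genes(annotation, windows)
    universe = set(annotation["gene_id"])
    enrich_results = {
        sx: enrich.window_fisher(windows, assignments, biased.for_sex(sx), universe)
        for sx in ("M", "F")
    }
    summaries = enrich.summarize(enrich_results)

    cov = bin_labels = region_coverage = None
    if run_coverage:
        cov = simulate.simulate_coverage(assembly, truth, config, bin_bp=bin_bp)
        bin_labels = covmod.classify_bins(cov)
        region_coverage = covmod.coverage_of_regions(
            cov, summaries["M"].regions, labels=bin_labels
        )

    records = joint = None
    anomaly = False
    if run_kmers:
        index = ygs.count_assembly_kmers(assembly, k=config.kmer_k)
        tables = simulate.simulate_read_kmers(assembly, truth, config)
        records = ygs.run_both_directions(index, tables["M"], tables["F"])
        joint, anomaly = ygs.bidirectional_stats(records["XY"], records["ZW"])

    provenance = {
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "architecture_simulated": config.architecture,
        "stages_run": {
            "expression": True,
            "coverage": bool(run_coverage),
            "kmers": bool(run_kmers),
        },
    }
    verdict = decide_verdict(
        enrich_summaries=summaries,
        bin_labels=bin_labels,
        records_xy=None if records is None else records["XY"],
        records_zw=None if records is None else records["ZW"],
        anomaly=anomaly,
        provenance=provenance,
    )
    result = PipelineResult(
        config=config, truth=truth, assembly=assembly, annotation=annotation,
        expr=expr, de_table=de_table, biased=biased, cross_sex=cross_sex,
        enrich_results=enrich_results, enrich_summaries=summaries,
        cov=cov, bin_labels=bin_labels, region_coverage=region_coverage,
        ygs_records=records, ygs_joint=joint, anomaly=anomaly, verdict=verdict,
    )
    if out_dir is not None:
        write_report_bundle(result, out_dir)
    return result


def write_report_bundle(result: PipelineResult, out_dir) -> None:
    """Write the full on-disk report; byte-identical for identical runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_io.write_fasta(result.assembly, out / "assembly.fasta")
    report_io.write_genes_bed(result.annotation, out / "genes.bed")
    report_io.write_json(result.truth.to_dict(), out / "truth.json")
    report_io.write_tsv(
        result.expr.counts.rename_axis("gene_id").reset_index(), out / "counts.tsv"
    )
    report_io.write_tsv(
        result.expr.tpm.rename_axis("gene_id").reset_index(), out / "tpm.tsv"
    )
    report_io.write_tsv(
        result.de_table.reset_index(drop=True), out / "de_table.tsv"
    )
    for sx in ("M", "F"):
        res = result.enrich_results[sx]
        report_io.write_tsv(res, out / f"window_enrichment_{sx}.tsv")
        hits = res[res["enriched"]]
        report_io.write_intervals_bed(
            hits[["scaffold", "start", "end"]],
            out / f"enriched_bins_{sx}.bed",
            qvalues=hits["qvalue"],
        )
        report_io.write_intervals_bed(
            result.enrich_summaries[sx].regions, out / f"enriched_regions_{sx}.bed"
        )
    if result.bin_labels is not None:
        report_io.write_tsv(result.bin_labels, out / "coverage_bins.tsv")
        report_io.write_tsv(result.region_coverage, out / "region_coverage.tsv")
    if result.ygs_records is not None:
        for d in ("XY", "ZW"):
            report_io.write_tsv(result.ygs_records[d], out / f"ygs_{d}.tsv")
        report_io.write_tsv(
            result.ygs_joint.rename_axis("contig_id").reset_index(),
            out / "ygs_joint.tsv",
        )
    report_io.write_json(result.verdict.to_dict(), out / "verdict.json")
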
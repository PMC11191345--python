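"""Synthetic genomes, expression, coverage, and read k-mer tables with known truth.

The generator builds a small gonochoristic genome under a declared sex
determination architecture — ``XY`` (males carry one X and one Y), ``ZW``
(females carry one Z and one W), or ``NONE`` (no sex-linked sequence) —
and emits every downstream input the detection pipeline consumes:

* a FASTA-writable assembly of random-uniform nucleotide scaffolds,
* a non-overlapping gene annotation,
* negative-binomial RNA-Seq counts with a subset of genes strongly
  sex-biased (default 16-fold) and optionally clustered on chosen
  scaffolds,
* Poisson per-bin genome-sequencing depth scaled by each scaffold's
  copy number in each sex,
* per-sex canonical 15-mer count tables with a tunable admixture of
  singleton "error" k-mers.

Ground truth (which scaffolds are sex-specific or hemizygous, which
genes are biased toward which sex) is returned as a machine-readable
:class:`SimTruth` so each analysis stage can be scored by parameter
recovery.

All stages are deterministic given ``SimConfig.seed``; each stage draws
from its own child generator so results do not depend on call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coverage as _coverage
from .expression import ExpressionMatrix
from .kmers import KmerCountTable, canonicalize, encode_kmers

_GENE_LEN_RANGE = (300, 3000)  # bp; exercises length normalization in TPM

# per-stage RNG stream ids (children of the config seed)
_STREAM_GENOME = 0
_STREAM_EXPRESSION = 1
_STREAM_COVERAGE = 2
_STREAM_KMERS = 3


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror a small tardigrade-like design: four male and three
    female RNA-Seq replicates, ~15-20x genome sequencing depth, 15-mers,
    and a 16-fold expression effect for sex-biased genes.
    """

    seed: int = 0
    architecture: str = "NONE"  # XY | ZW | NONE
    n_autosomes: int = 4
    scaffold_length_bp: int = 200_000
    sex_scaffold_length_bp: int = 200_000
    n_genes_per_scaffold: int = 30
    frac_biased_male: float = 0.08
    frac_biased_female: float = 0.03
    bias_fold: float = 16.0
    biased_opposite_scale: float = 1.0
    bias_cluster_scaffolds: tuple = ()
    n_male_samples: int = 4
    n_female_samples: int = 3
    mean_depth: float = 20.0
    nb_dispersion: float = 0.05
    kmer_k: int = 15
    kmer_error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.architecture not in ("XY", "ZW", "NONE"):
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        for name in ("frac_biased_male", "frac_biased_female", "kmer_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bias_fold <= 1:
            raise ValueError("bias_fold must be > 1")
        if not 0.0 <= self.biased_opposite_scale <= 1.0:
            raise ValueError("biased_opposite_scale must be in [0, 1]")
        if self.n_male_samples < 1 or self.n_female_samples < 1:
            raise ValueError("need at least one sample per sex")
        min_len = 10 * self.kmer_k
        if self.scaffold_length_bp < min_len or self.sex_scaffold_length_bp < min_len:
            raise ValueError(f"scaffold lengths must be >= {min_len} bp")
        if self.kmer_k % 2 == 0 or not (1 <= self.kmer_k <= 31):
            raise ValueError("kmer_k must be odd and in [1, 31]")
        if self.n_autosomes < 1:
            raise ValueError("need at least one autosome")
        object.__setattr__(self, "bias_cluster_scaffolds", tuple(self.bias_cluster_scaffolds))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bias_cluster_scaffolds"] = list(d["bias_cluster_scaffolds"])
        return d


@dataclass
class SimTruth:
    """Ground truth of one simulated genome."""

    architecture: str
    sex_specific_scaffolds: set = field(default_factory=set)  # present in one sex only
    hemizygous_scaffolds: set = field(default_factory=set)  # single copy in the heterogametic sex
    biased_gene_ids: dict = field(default_factory=lambda: {"M": set(), "F": set()})
    copy_number: dict = field(default_factory=dict)  # scaffold -> {"M": int, "F": int}

    def __post_init__(self) -> None:
        if self.sex_specific_scaffolds & self.hemizygous_scaffolds:
            raise ValueError("a scaffold cannot be both sex-specific and hemizygous")

    def scaffolds_present(self, sex: str) -> list:
        return [s for s, cn in self.copy_number.items() if cn[sex] > 0]

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "sex_specific_scaffolds": sorted(self.sex_specific_scaffolds),
            "hemizygous_scaffolds": sorted(self.hemizygous_scaffolds),
            "biased_gene_ids": {s: sorted(g) for s, g in self.biased_gene_ids.items()},
            "copy_number": {s: dict(cn) for s, cn in sorted(self.copy_number.items())},
        }


@dataclass
class Assembly:
    """Scaffold sequences; coordinates everywhere are 0-based, half-open."""

    sequences: dict  # scaffold id -> uppercase ACGT string

    def lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __iter__(self):
        return iter(self.sequences.items())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.integers(0, 4, size=length, dtype=np.uint8).choose(
        np.frombuffer(b"ACGT", dtype=np.uint8)
    ).tobytes().decode("ascii")


def _place_genes(
    rng: np.random.Generator, scaffold: str, length: int, n_genes: int, start_index: int
) -> list[dict]:
    """Non-overlapping genes with uniform lengths in 300-3000 bp."""
    lo, hi = _GENE_LEN_RANGE
    lens = rng.integers(lo, hi + 1, size=n_genes)
    slack = length - int(lens.sum())
    if slack < 0:
        raise ValueError(
            f"cannot pack {n_genes} genes (>= {lo} bp each) into {length} bp on {scaffold}"
        )
    # distribute the free space as inter-gene gaps (n_genes + 1 slots)
    gaps = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = []
    pos = 0
    for j in range(n_genes):
        pos += int(gaps[j])
        genes.append(
            {
                "gene_id": f"gene{start_index + j:05d}",
                "scaffold": scaffold,
                "start": pos,
                "end": pos + int(lens[j]),
                "strand": strands[j],
            }
        )
        pos += int(lens[j])
    return genes


def _assign_biased(
    rng: np.random.Generator,
    annotation: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
) -> None:
    """Pick male- and female-biased gene sets, clustered if requested.

    Each biased gene lands on a ``bias_cluster_scaffolds`` member with
    probability 0.9 (when any are declared), otherwise uniformly among
    the remaining scaffolds. Sex-specific scaffolds are excluded from
    the pool: their genes are single-sex by construction already.
    """
    both_sexes = {
        s for s, cn in truth.copy_number.items() if cn["M"] > 0 and cn["F"] > 0
    }
    pool = annotation[annotation["scaffold"].isin(both_sexes)]
    cluster = set(config.bias_cluster_scaffolds) & both_sexes
    in_cluster = pool[pool["scaffold"].isin(cluster)]["gene_id"].to_numpy()
    outside = pool[~pool["scaffold"].isin(cluster)]["gene_id"].to_numpy()
    in_cluster = list(rng.permutation(in_cluster))
    outside = list(rng.permutation(outside))

    n_pool = len(pool)
    wanted = {
        "M": int(round(config.frac_biased_male * n_pool)),
        "F": int(round(config.frac_biased_female * n_pool)),
    }
    for sex in ("M", "F"):
        chosen: set = set()
        for _ in range(wanted[sex]):
            use_cluster = bool(cluster) and rng.random() < 0.9
            src = in_cluster if (use_cluster and in_cluster) else outside
            if not src:
                src = in_cluster or outside
            if not src:
                break
            chosen.add(src.pop())
        truth.biased_gene_ids[sex] = chosen


def simulate_genome(config: SimConfig) -> tuple[Assembly, pd.DataFrame, SimTruth]:
    """Random assembly, gene annotation, and ground truth.

    Under XY the last two scaffolds are the X (copies M=1/F=2) and the Y
    (M=1/F=0); under ZW the Z (M=2/F=1) and the W (M=0/F=1); under NONE
    only the ``n_autosomes`` diploid scaffolds exist.

    Returns
    -------
    assembly, annotation, truth
        ``annotation`` is a DataFrame with columns
        ``gene_id, scaffold, start, end, strand`` (0-based, half-open).
    """
    rng = config.rng(_STREAM_GENOME)
    names = [f"scaffold{i + 1:04d}" for i in range(config.n_autosomes)]
    lengths = {n: config.scaffold_length_bp for n in names}
    copy_number = {n: {"M": 2, "F": 2} for n in names}
    truth = SimTruth(architecture=config.architecture)

    if config.architecture != "NONE":
        hemi = f"scaffold{config.n_autosomes + 1:04d}"  # X or Z
        spec = f"scaffold{config.n_autosomes + 2:04d}"  # Y or W
        lengths[hemi] = config.sex_scaffold_length_bp
        lengths[spec] = config.sex_scaffold_length_bp
        if config.architecture == "XY":
            copy_number[hemi] = {"M": 1, "F": 2}
            copy_number[spec] = {"M": 1, "F": 0}
        else:
            copy_number[hemi] = {"M": 2, "F": 1}
            copy_number[spec] = {"M": 0, "F": 1}
        truth.hemizygous_scaffolds = {hemi}
        truth.sex_specific_scaffolds = {spec}
        names += [hemi, spec]
    truth.copy_number = copy_number

    sequences = {n: _random_sequence(rng, lengths[n]) for n in names}
    genes: list[dict] = []
    for i, n in enumerate(names):
        genes.extend(
            _place_genes(rng, n, lengths[n], config.n_genes_per_scaffold,
                         start_index=i * config.n_genes_per_scaffold)
        )
    annotation = pd.DataFrame(genes, columns=["gene_id", "scaffold", "start", "end", "strand"])
    _assign_biased(rng, annotation, truth, config)
    return Assembly(sequences), annotation, truth


def simulate_expression(
    annotation: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> ExpressionMatrix:
    """Negative-binomial RNA-Seq counts with sex-biased effects.

    Per-gene baseline means are log-normal; a biased gene's favored sex
    gets the baseline times ``bias_fold`` and the other sex the baseline
    times ``biased_opposite_scale`` (1.0 by default, so the mean count
    ratio is exactly ``bias_fold``; small values emulate sex-limited
    genes that are essentially off in the other sex). Genes on scaffolds
    absent from a sex have mean zero there. Counts are NB with the
    configured dispersion (Poisson in the dispersion -> 0 limit).
    """
    rng = config.rng(_STREAM_EXPRESSION)
    gene_ids = annotation["gene_id"].to_numpy()
    n_genes = gene_ids.size
    baseline = rng.lognormal(mean=np.log(100.0), sigma=1.2, size=n_genes)

    samples = [f"M{i + 1}" for i in range(config.n_male_samples)] + [
        f"F{i + 1}" for i in range(config.n_female_samples)
    ]
    sex = pd.Series(
        ["M"] * config.n_male_samples + ["F"] * config.n_female_samples,
        index=samples, name="sex",
    )

    mult = {"M": np.ones(n_genes), "F": np.ones(n_genes)}
    male_biased = annotation["gene_id"].isin(truth.biased_gene_ids["M"]).to_numpy()
    female_biased = annotation["gene_id"].isin(truth.biased_gene_ids["F"]).to_numpy()
    mult["M"][male_biased] = config.bias_fold
    mult["F"][male_biased] = config.biased_opposite_scale
    mult["F"][female_biased] = config.bias_fold
    mult["M"][female_biased] = config.biased_opposite_scale
    for s, cn in truth.copy_number.items():
        on_scaffold = (annotation["scaffold"] == s).to_numpy()
        for sx in ("M", "F"):
            if cn[sx] == 0:
                mult[sx][on_scaffold] = 0.0

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, smp in enumerate(samples):
        mu = baseline * mult[sex[smp]]
        if config.nb_dispersion <= 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            nonzero = mu > 0
            p = r / (r + mu[nonzero])
            counts[nonzero, j] = rng.negative_binomial(r, p)
    eff_length = pd.Series(
        (annotation["end"] - annotation["start"]).to_numpy(dtype=float),
        index=gene_ids, name="eff_length_bp",
    )
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        eff_length=eff_length,
        sex=sex,
    )


def simulate_coverage(
    assembly: Assembly, truth: SimTruth, config: SimConfig, bin_bp: int = 10_000
):
    """Per-bin sequencing depth per sample, Poisson around copy number.

    Raw depth of a bin of width w in a sample of sex s is
    Poisson(mean_depth * copies(s)/2 * w) / w; a diploid scaffold sits at
    ``mean_depth``, a hemizygous one at half, an absent one at zero.
    Returns a median-normalized :class:`sexscan.coverage.CoverageMatrix`.
    """
    if bin_bp < 1000:
        raise ValueError("bin_bp must be >= 1000")
    rng = config.rng(_STREAM_COVERAGE)
    rows = []
    for name, seq in assembly:
        for start in range(0, len(seq), bin_bp):
            rows.append((name, start, min(start + bin_bp, len(seq))))
    bins = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    widths = (bins["end"] - bins["start"]).to_numpy()

    samples = [f"gM{i + 1}" for i in range(config.n_male_samples)] + [
        f"gF{i + 1}" for i in range(config.n_female_samples)
    ]
    sex = pd.Series(
        ["M"] * config.n_male_samples + ["F"] * config.n_female_samples,
        index=samples, name="sex",
    )
    cn = np.array(
        [[truth.copy_number[s][sx] for sx in sex] for s in bins["scaffold"]], dtype=float
    )
    lam = config.mean_depth * cn / 2.0 * widths[:, None]
    raw = rng.poisson(lam) / widths[:, None]
    raw_df = pd.DataFrame(raw, columns=samples)
    return _coverage.normalize_coverage(bins, raw_df, sex)


def simulate_read_kmers(
    assembly: Assembly, truth: SimTruth, config: SimConfig
) -> dict[str, KmerCountTable]:
    """Per-sex canonical k-mer tables emulating pooled read counting.

    Each sex's table holds every canonical k-mer of the scaffolds that
    sex carries, with count ~ Poisson(mean_depth * copies / 2) truncated
    at 1, plus a ``kmer_error_rate`` fraction of the total k-mer mass as
    novel singleton error k-mers.
    """
    rng = config.rng(_STREAM_KMERS)
    k = config.kmer_k
    per_scaffold = {name: encode_kmers(seq, k) for name, seq in assembly}
    tables: dict[str, KmerCountTable] = {}
    for sx in ("M", "F"):
        parts, weights = [], []
        for name, codes in per_scaffold.items():
            copies = truth.copy_number[name][sx]
            if copies > 0 and codes.size:
                parts.append(codes)
                weights.append(np.full(codes.size, float(copies)))
        if not parts:
            tables[sx] = KmerCountTable(k=k, codes=np.empty(0, np.uint64),
                                        counts=np.empty(0, np.int64), source=f"reads_{sx}")
            continue
        codes = np.concatenate(parts)
        uniq, inverse = np.unique(codes, return_inverse=True)
        copy_mass = np.bincount(inverse, weights=np.concatenate(weights))
        lam = config.mean_depth * copy_mass / 2.0
        counts = np.maximum(1, rng.poisson(lam))

        n_err = int(round(config.kmer_error_rate * counts.sum()))
        if n_err > 0:
            err = canonicalize(
                rng.integers(0, 4**k, size=n_err, dtype=np.uint64), k
            )
            err = np.setdiff1d(err, uniq)  # novel only
            uniq = np.concatenate([uniq, err])
            counts = np.concatenate([counts, np.ones(err.size, dtype=np.int64)])
            order = np.argsort(uniq, kind="stable")
            uniq, counts = uniq[order], counts[order]
        tables[sx] = KmerCountTable(k=k, codes=uniq, counts=counts, source=f"reads_{sx}")
    return tables
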
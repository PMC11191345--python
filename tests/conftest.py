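"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exact enumeration, quadratic
scans, string-based set arithmetic) and never share code with the
implementation paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

import sexscan as sx


# ---------------------------------------------------------------- oracles

def hypergeom_tail_oracle(n_hit: int, n_drawn: int, n_marked: int, n_total: int) -> float:
    """Exact P(X >= n_hit), X ~ Hypergeom(N, K, n), by rational enumeration."""
    total = Fraction(0)
    denom = math.comb(n_total, n_drawn)
    for i in range(n_hit, min(n_marked, n_drawn) + 1):
        if n_drawn - i > n_total - n_marked:
            continue
        total += Fraction(
            math.comb(n_marked, i) * math.comb(n_total - n_marked, n_drawn - i), denom
        )
    return float(min(total, Fraction(1)))


def bh_stepup_oracle(pvalues) -> np.ndarray:
    """Brute-force q_i = min_{j>=i} min(1, p_(j) * m / j) over sorted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        q_sorted[rank_i] = min(
            min(1.0, p[order[rank_j]] * m / (rank_j + 1)) for rank_j in range(rank_i, m)
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_str(kmer: str) -> str:
    return min(kmer, revcomp_str(kmer))


def string_kmer_counts(seq: str, k: int) -> dict:
    """Naive canonical k-mer counting over one sequence (skips non-ACGT windows)."""
    out: dict = {}
    for i in range(len(seq) - k + 1):
        win = seq[i : i + k]
        if any(c not in "ACGT" for c in win):
            continue
        c = canonical_str(win)
        out[c] = out.get(c, 0) + 1
    return out


def ygs_oracle(assembly: sx.Assembly, k: int, carrier: set, opposite: set) -> dict:
    """Naive per-contig SC/VSC/VSC_UK via string sets.

    ``carrier`` and ``opposite`` are sets of canonical k-mer strings
    (already trusted-filtered). Returns contig -> (n_sc, n_vsc, n_vsc_uk).
    """
    global_counts: dict = {}
    per_contig: dict = {}
    for name, seq in assembly:
        counts = string_kmer_counts(seq, k)
        per_contig[name] = set(counts)
        for kmer, c in counts.items():
            global_counts[kmer] = global_counts.get(kmer, 0) + c
    singles = {kmer for kmer, c in global_counts.items() if c == 1}
    out = {}
    for name, kmers in per_contig.items():
        sc = kmers & singles
        vsc = sc & carrier
        uk = vsc - opposite
        out[name] = (len(sc), len(vsc), len(uk))
    return out


def table_to_string_set(table, min_count: int = 1) -> set:
    """Decode a KmerCountTable into canonical k-mer strings for the oracle."""
    codes = table.filter_min_count(min_count)
    return set(sx.kmers.decode_many(codes, table.k))


# --------------------------------------------------------------- fixtures

XY_SEED = 11


@pytest.fixture(scope="session")
def xy_config() -> sx.SimConfig:
    return sx.SimConfig(seed=XY_SEED, architecture="XY")


@pytest.fixture(scope="session")
def xy_sim(xy_config):
    return sx.simulate.simulate_genome(xy_config)


@pytest.fixture(scope="session")
def xy_result(xy_config) -> sx.pipeline.PipelineResult:
    """One full XY pipeline run shared across tests."""
    return sx.run_all(xy_config)


@pytest.fixture(scope="session")
def none_result() -> sx.pipeline.PipelineResult:
    """A no-sex-chromosome run with unclustered biased genes."""
    return sx.run_all(sx.SimConfig(seed=5, architecture="NONE"))


@pytest.fixture(scope="session")
def toy_assembly() -> sx.Assembly:
    """Three short contigs (< 100 kb total) for exact-oracle comparisons."""
    rng = np.random.default_rng(404)
    def seq(n):
        return "".join(rng.choice(list("ACGT"), size=n))
    return sx.Assembly(
        {"tigA": seq(30_000), "tigB": seq(20_000), "tigC": seq(10_000)}
    )
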
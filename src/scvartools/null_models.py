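"""Non-randomness statistics.

Four families: a per-gene combinatorial probability (1 / C(N, K)), a
genome-as-continuum Monte Carlo randomization with pluggable clustering
statistics, Friedman + Nemenyi cross-condition rank tests, and two-sample
t tests for sample metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .genome_model import AnnotatedGenome, cumulative_offsets

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# combinatorial per-gene probability
# ---------------------------------------------------------------------------

def pascal_probability(gene_length_bp: int, shared_variants: int) -> float:
    """Probability 1 / C(N, K) that K positions drawn uniformly without
    replacement from a gene of length N coincide with K fixed positions.

    Computed in log space (log-gamma) so large N do not overflow.
    """
    n, k = gene_length_bp, shared_variants
    if k < 0 or n < 0:
        raise ValueError("N and K must be non-negative")
    if k > n:
        raise ValueError(f"K={k} exceeds N={n}")
    if k == 0:
        return 1.0
    kk = min(k, n - k)
    if kk <= 100_000:
        # summed logs: accurate to a few ulps, unlike gammaln (~1e-11)
        log_binom = math.fsum(
            math.log(n - i) - math.log(i + 1) for i in range(kk)
        )
    else:
        log_binom = float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    return float(math.exp(-log_binom))


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


# ---------------------------------------------------------------------------
# continuum Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class NullTestResult:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    iterations: int
    seed: int
    p_empirical: float
    p_combined: Optional[float] = None
    per_condition_hit_prob: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "iterations": self.iterations,
            "seed": self.seed,
            "p_empirical": self.p_empirical,
            "p_combined": self.p_combined,
            "per_condition_hit_prob": self.per_condition_hit_prob,
        }


Statistic = Callable[[Mapping[str, np.ndarray]], np.ndarray]


def shared_gene_count(counts_by_condition: Mapping[str, np.ndarray]) -> np.ndarray:
    """Number of genes hit by >=1 variant in every condition simultaneously."""
    shared = None
    for m in counts_by_condition.values():
        b = m > 0
        shared = b if shared is None else (shared & b)
    return shared.sum(axis=1)


def max_per_gene_hits(counts_by_condition: Mapping[str, np.ndarray]) -> np.ndarray:
    """Maximum pooled per-gene hit count across all conditions."""
    total = sum(counts_by_condition.values())
    return total.max(axis=1)


def genes_with_min_hits(m: int) -> Statistic:
    """Statistic factory: number of genes with >= m pooled hits."""

    def _stat(counts_by_condition: Mapping[str, np.ndarray]) -> np.ndarray:
        total = sum(counts_by_condition.values())
        return (total >= m).sum(axis=1)

    return _stat


def weighted_gene_hit_score(weights: np.ndarray) -> Statistic:
    """Statistic factory: sum of per-gene weights over genes hit by >=1
    variant in any condition.

    With distinct irrational-ish weights the statistic is effectively
    continuous, which makes empirical p-values exactly uniform under the
    null — the right tool for calibration checks, where coarse integer
    statistics are super-uniform by construction.
    """
    w = np.asarray(weights, dtype=float)

    def _stat(counts_by_condition: Mapping[str, np.ndarray]) -> np.ndarray:
        total = sum(counts_by_condition.values())
        return (total > 0) @ w

    return _stat


STATISTICS: dict[str, Statistic] = {
    "shared-genes": shared_gene_count,
    "max-gene-hits": max_per_gene_hits,
}


def global_positions(genome: AnnotatedGenome, variants) -> list[int]:
    """Map (contig, pos) variant keys to the concatenated genome coordinate."""
    offsets = cumulative_offsets(genome)
    out = []
    for item in variants:
        if hasattr(item, "key"):
            contig, pos = item.key[0], item.key[1]
        else:
            contig, pos = item[0], item[1]
        out.append(offsets[contig] + pos)
    return out


class _GeneIndex:
    """Maps continuum positions to gene indices via sorted interval arrays."""

    def __init__(self, genome: AnnotatedGenome):
        offsets = cumulative_offsets(genome)
        ivals = sorted(
            (offsets[g.contig] + g.start, offsets[g.contig] + g.end) for g in genome.genes
        )
        self.starts = np.array([s for s, _ in ivals], dtype=np.int64)
        self.ends = np.array([e for _, e in ivals], dtype=np.int64)
        self.n_genes = len(ivals)
        if self.n_genes > 1 and np.any(self.ends[:-1] > self.starts[1:]):
            raise ValueError(
                "continuum randomization requires non-overlapping gene intervals"
            )
        self.total_length = genome.total_length

    def hit_counts(self, positions: np.ndarray) -> np.ndarray:
        """(n_rows, n_genes) int32 hit counts for an (n_rows, n_pos) array."""
        positions = np.atleast_2d(positions)
        n_rows = positions.shape[0]
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions < self.ends[np.clip(idx, 0, self.n_genes - 1)])
        counts = np.zeros((n_rows, self.n_genes + 1), dtype=np.int32)
        rows = np.broadcast_to(np.arange(n_rows)[:, None], positions.shape)
        cols = np.where(valid, idx, self.n_genes)
        np.add.at(counts, (rows, cols), 1)
        return counts[:, : self.n_genes]


def continuum_randomization(
    genome: AnnotatedGenome,
    observed_by_condition: Mapping[str, Sequence[int]],
    statistic: str | Statistic = "shared-genes",
    iterations: int = 1_000_000,
    seed: int = 0,
    chunk_size: int = 2000,
) -> NullTestResult:
    """Monte Carlo null: re-place each condition's observed number of
    variants uniformly along the concatenated genome and recompute the
    clustering statistic each iteration.

    ``observed_by_condition`` maps condition -> continuum positions (see
    :func:`global_positions`). p_empirical = (1 + #{null >= observed}) /
    (iterations + 1). p_combined multiplies, across conditions, the
    empirical probability that one uniform draw hits every gene of that
    condition's observed gene set (independence assumption; reported
    separately, never substituted for p_empirical).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    stat_name = statistic if isinstance(statistic, str) else getattr(
        statistic, "__name__", "custom"
    )
    stat_fn = STATISTICS[statistic] if isinstance(statistic, str) else statistic

    index = _GeneIndex(genome)
    rng = np.random.default_rng(seed)

    conditions = list(observed_by_condition)
    n_by_cond = {c: len(observed_by_condition[c]) for c in conditions}
    for c, n in n_by_cond.items():
        if n == 0:
            logger.warning("condition %r has zero observed variants", c)

    obs_counts = {
        c: index.hit_counts(np.asarray(observed_by_condition[c], dtype=np.int64))
        if n_by_cond[c]
        else np.zeros((1, index.n_genes), dtype=np.int32)
        for c in conditions
    }
    observed_stat = float(stat_fn(obs_counts)[0])
    obs_gene_sets = {c: np.flatnonzero(obs_counts[c][0] > 0) for c in conditions}

    n_ge = 0
    null_sum = 0.0
    null_sumsq = 0.0
    hit_all = {c: 0 for c in conditions}
    done = 0
    while done < iterations:
        chunk = min(chunk_size, iterations - done)
        counts = {}
        for c in conditions:
            if n_by_cond[c] == 0:
                counts[c] = np.zeros((chunk, index.n_genes), dtype=np.int32)
                continue
            pos = rng.integers(0, index.total_length, size=(chunk, n_by_cond[c]))
            counts[c] = index.hit_counts(pos)
        vals = np.asarray(stat_fn(counts), dtype=float)
        n_ge += int((vals >= observed_stat).sum())
        null_sum += float(vals.sum())
        null_sumsq += float((vals**2).sum())
        for c in conditions:
            g = obs_gene_sets[c]
            if g.size:
                hit_all[c] += int((counts[c][:, g] > 0).all(axis=1).sum())
            else:
                hit_all[c] += chunk
        done += chunk

    null_mean = null_sum / iterations
    null_var = max(null_sumsq / iterations - null_mean**2, 0.0)
    p_emp = (1 + n_ge) / (iterations + 1)
    per_cond = {c: (1 + hit_all[c]) / (iterations + 1) for c in conditions}
    p_combined = float(np.prod(list(per_cond.values()))) if conditions else None

    return NullTestResult(
        statistic_name=stat_name,
        observed=observed_stat,
        null_mean=null_mean,
        null_sd=math.sqrt(null_var),
        iterations=iterations,
        seed=seed,
        p_empirical=p_emp,
        p_combined=p_combined,
        per_condition_hit_prob=per_cond,
    )


# ---------------------------------------------------------------------------
# Friedman / Nemenyi
# ---------------------------------------------------------------------------

def _block_ranks(matrix: np.ndarray) -> np.ndarray:
    return np.vstack([stats.rankdata(row) for row in matrix])


def _friedman_chi2(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for an (n_blocks, k) value matrix."""
    n, k = matrix.shape
    ranks = _block_ranks(matrix)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: average-rank ties shrink the denominator
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0:  # every block constant
        return 0.0
    return chi2 / correction


def friedman_test(
    matrix: Sequence[Sequence[float]], method: str = "chi2"
) -> tuple[float, int, float]:
    """Friedman rank test over an (n_blocks x k_conditions) matrix.

    Returns (chi2_F, df, p). ``method='exact'`` replaces the chi-square
    approximation with the exact within-block permutation p-value
    (feasible for small n, k).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (blocks x conditions)")
    n, k = m.shape
    if k < 2 or n < 2:
        raise ValueError("need >=2 conditions and >=2 blocks")
    chi2 = _friedman_chi2(m)
    df = k - 1
    if method == "exact":
        p = _friedman_exact_p(m)
    elif method == "chi2":
        p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return chi2, df, p


def _friedman_exact_p(matrix: np.ndarray) -> float:
    """Exact permutation p-value: enumerate all within-block orderings."""
    n, k = matrix.shape
    total = math.factorial(k) ** n
    if total > 5_000_000:
        raise ValueError(f"exact enumeration infeasible: {total} permutations")
    observed = _friedman_chi2(matrix)
    base_ranks = _block_ranks(matrix)
    perms = list(permutations(range(k)))
    count = 0
    for combo in product(perms, repeat=n):
        permuted = np.vstack([base_ranks[i, list(p)] for i, p in enumerate(combo)])
        if _chi2_from_ranks(permuted, matrix) >= observed - 1e-12:
            count += 1
    return count / total


def _chi2_from_ranks(ranks: np.ndarray, matrix: np.ndarray) -> float:
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0:
        return 0.0
    return chi2 / correction


#: Critical values q_{0.05,k} of the Nemenyi test (studentized range upper
#: 5% quantile at infinite df divided by sqrt(2)), k = 2..10.
NEMENYI_Q_05: dict[int, float] = {
    2: 1.960, 3: 2.344, 4: 2.569, 5: 2.728, 6: 2.850,
    7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164,
}


@dataclass
class NemenyiPair:
    a: int
    b: int
    mean_rank_diff: float
    p_value: float
    significant: bool


def nemenyi_posthoc(
    matrix: Sequence[Sequence[float]], alpha: float = 0.05
) -> tuple[Optional[float], list[NemenyiPair]]:
    """Nemenyi post-hoc pairwise comparison after a Friedman test.

    Returns (critical_difference, pairs). Pairs whose absolute mean-rank
    difference exceeds CD = q_{alpha,k} * sqrt(k(k+1)/(6n)) are flagged.
    Returns (None, []) when k < 3 (not applicable).
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if k < 3:
        logger.warning("Nemenyi post-hoc requires k >= 3 conditions; got %d", k)
        return None, []
    if alpha != 0.05 or k > 10:
        q = float(stats.studentized_range.ppf(1 - alpha, k, np.inf)) / math.sqrt(2)
    else:
        q = NEMENYI_Q_05[k]
    cd = q * math.sqrt(k * (k + 1) / (6.0 * n))
    mean_ranks = _block_ranks(m).mean(axis=0)
    se = math.sqrt(k * (k + 1) / (12.0 * n))
    pairs: list[NemenyiPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            p = float(stats.studentized_range.sf(diff / se, k, np.inf))
            pairs.append(NemenyiPair(i, j, diff, min(p, 1.0), diff > cd))
    return cd, pairs


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------

def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_variance: bool = True,
) -> tuple[float, float, float]:
    """Student's (pooled-variance) two-sample t test; Welch by flag.

    Returns (t, df, p two-sided). Degenerate zero-variance equal-mean
    input yields (0, df, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_variance:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1 / na + 1 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        if se == 0:
            df = na + nb - 2
        else:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
    if se == 0:
        return (0.0, float(df), 1.0) if a.mean() == b.mean() else (math.inf, float(df), 0.0)
    t = (a.mean() - b.mean()) / se
    p = 2 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p
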
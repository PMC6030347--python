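"""Exact tests for Hardy-Weinberg proportions and genotypic linkage
disequilibrium.

The HWE test conditions on the observed allele counts: under the null every
genotype array with those counts has the Levene conditional probability

    P(array) = n! 2^h prod_a m_a! / ( (2n)! prod_{i<=j} n_ij! )

and the p-value is the total probability of arrays no more probable than
the observed one (conditional-probability ordering, ties in the tail).
Small problems are enumerated exhaustively; larger ones are sampled in
the style of Guo and Thompson, either by independent Monte Carlo over
gamete arrangements (the default: conditional on allele counts, every
arrangement is equally likely) or by the Markov switch chain.

The LD test is genotypic: it permutes single-locus genotypes among
individuals, so no haplotype phase is assumed, and measures association by
the G statistic of the genotype-by-genotype contingency table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .model import (
    AlleleLabel,
    Genotype,
    GenotypeCountTable,
    GenotypeTable,
    binomial_pairs,
    sort_alleles,
    stable_seed,
)

__all__ = [
    "ExactTestResult",
    "levene_probability",
    "log_levene_probability",
    "enumerate_genotype_arrays",
    "count_genotype_arrays",
    "hwe_exact_test",
    "ld_g_statistic",
    "ld_permutation_test",
    "ld_test_matrix",
    "LDTestMatrix",
    "bonferroni_threshold",
    "format_two_sig",
]

#: log-probability tie tolerance when accumulating the tail
_TIE_EPS = 1e-9


@dataclass
class ExactTestResult:
    """Outcome of an exact or Monte-Carlo test."""

    p_value: float
    method: str                  # "enumeration" | "monte_carlo" | "permutation"
    statistic: float | None = None   # log conditional probability or G
    reps: int | None = None
    se: float | None = None      # Monte-Carlo standard error

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Levene conditional probability


def _array_to_matrix(gct: GenotypeCountTable,
                     alleles: list[AlleleLabel] | None = None,
                     ) -> tuple[np.ndarray, list[AlleleLabel]]:
    """Symmetric genotype-count matrix (upper triangle populated)."""
    if alleles is None:
        alleles = sort_alleles(gct.allele_counts)
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    m = np.zeros((k, k), dtype=np.int64)
    for g, c in gct.counts.items():
        i, j = idx[g.a1], idx[g.a2]
        m[min(i, j), max(i, j)] += c
    return m, alleles


def log_levene_probability(mat: np.ndarray) -> float:
    """Log Levene probability of a genotype array given its allele counts.

    ``mat`` is an upper-triangular genotype count matrix.
    """
    k = mat.shape[0]
    n = int(np.triu(mat).sum())
    het = int(np.triu(mat, 1).sum())
    allele_counts = np.zeros(k, dtype=np.int64)
    for i in range(k):
        allele_counts[i] = 2 * mat[i, i] + mat[:i, i].sum() + mat[i, i + 1:].sum()
    two_n = int(allele_counts.sum())
    if two_n != 2 * n:
        raise ValueError("inconsistent genotype/allele counts")
    logp = (gammaln(n + 1) + het * math.log(2.0)
            + float(np.sum(gammaln(allele_counts + 1)))
            - gammaln(two_n + 1))
    iu = np.triu_indices(k)
    logp -= float(np.sum(gammaln(mat[iu] + 1)))
    return logp


def levene_probability(gct: GenotypeCountTable) -> float:
    """Conditional probability of the observed genotype array."""
    gct.validate()
    mat, _ = _array_to_matrix(gct)
    return math.exp(log_levene_probability(mat))


# ---------------------------------------------------------------------------
# exhaustive enumeration


def enumerate_genotype_arrays(allele_counts: Sequence[int],
                              limit: int | None = None,
                              ) -> Iterable[np.ndarray]:
    """Yield every genotype-count matrix consistent with ``allele_counts``.

    Cells are filled in row-major upper-triangular order with a capacity
    prune (remaining allele-i copies must fit in the row's remaining
    cells), so every visited branch leads to at least one array.  With
    ``limit`` set, an ``OverflowError`` aborts once more than ``limit``
    arrays have been yielded.
    """
    m = list(allele_counts)
    k = len(m)
    mat = np.zeros((k, k), dtype=np.int64)
    yielded = 0

    def fill(i: int, j: int, rem: list[int]):
        nonlocal yielded
        if i == k:
            yielded += 1
            if limit is not None and yielded > limit:
                raise OverflowError("array space larger than limit")
            yield mat.copy()
            return
        if j == k:
            if rem[i] != 0:
                return
            yield from fill(i + 1, i + 1, rem)
            return
        if i == j:
            top = rem[i] // 2
        else:
            top = min(rem[i], rem[j])
        # capacity of the cells after (i, j) in row i
        tail_cap = sum(rem[t] for t in range(j + 1, k))
        for c in range(top, -1, -1):
            left = rem[i] - (2 * c if i == j else c)
            if left > tail_cap:
                break    # smaller c leaves even more unplaceable copies
            mat[i, j] = c
            rem[i] = left
            if i != j:
                rem[j] -= c
            yield from fill(i, j + 1, rem)
            rem[i] += 2 * c if i == j else c
            if i != j:
                rem[j] += c
        mat[i, j] = 0

    yield from fill(0, 0, m)


def _enumerate_log_probs(allele_counts: Sequence[int]) -> "np.ndarray":
    """Log Levene probabilities of every conditional array, computed
    incrementally during the enumeration (no per-array matrix work)."""
    m = list(allele_counts)
    k = len(m)
    n = sum(m) // 2
    const = (gammaln(n + 1) + float(np.sum(gammaln(np.array(m) + 1)))
             - gammaln(2 * n + 1))
    lg = gammaln(np.arange(n + 2) + 1.0)
    ln2 = math.log(2.0)
    out: list[float] = []

    def fill(i: int, j: int, rem: list[int], acc: float):
        if i == k:
            out.append(const + acc)
            return
        if j == k:
            if rem[i] == 0:
                fill(i + 1, i + 1, rem, acc)
            return
        if i == j:
            top = rem[i] // 2
        else:
            top = min(rem[i], rem[j])
        tail_cap = sum(rem[t] for t in range(j + 1, k))
        off = ln2 if i != j else 0.0
        for c in range(top, -1, -1):
            left = rem[i] - (2 * c if i == j else c)
            if left > tail_cap:
                break
            rem[i] = left
            if i != j:
                rem[j] -= c
            fill(i, j + 1, rem, acc + c * off - lg[c])
            rem[i] += 2 * c if i == j else c
            if i != j:
                rem[j] += c

    fill(0, 0, m, 0.0)
    return np.array(out)


def count_genotype_arrays(allele_counts: Sequence[int],
                          limit: int = 10 ** 6) -> int | None:
    """Count arrays with the given allele counts; None if above ``limit``."""
    c = 0
    try:
        for _ in enumerate_genotype_arrays(allele_counts, limit=limit):
            c += 1
    except OverflowError:
        return None
    return c


# ---------------------------------------------------------------------------
# Guo-Thompson Markov chain


def _gt_chain(mat: np.ndarray, log_obs: float, reps: int, burnin: int,
              rng: np.random.Generator) -> tuple[float, float]:
    """Run the switch chain; return (p_hat, se) with add-one correction.

    The chain state is the ordered arrangement of the 2n allele copies
    into n gamete pairs.  Conditional on allele counts, every arrangement
    is equally likely (each genotype array has n!/prod(n_ij!) labelled
    assignments times 2^het orderings, exactly its Levene weight), so a
    random transposition of two allele tokens is a symmetric proposal on a
    uniform target: every move is accepted and no acceptance ratio is
    needed.  The log Levene probability of the induced genotype array is
    maintained incrementally for the tail indicator and refreshed
    periodically to cancel float drift.
    """
    k = mat.shape[0]
    cur = mat.astype(np.int64).copy()
    log_cur = log_levene_probability(cur)

    tokens: list[int] = []
    iu = np.triu_indices(k)
    for i, j in zip(*iu):
        tokens.extend([int(i), int(j)] * int(cur[i, j]))
    two_n = len(tokens)
    n = two_n // 2
    if n < 2:
        return 1.0, 0.0

    lgamma_cache = gammaln(np.arange(int(cur.max()) + n + 2) + 1.0)

    kept = 0
    indicators: list[int] = []
    pos_draw = rng.integers(0, two_n, size=2 * (burnin + reps))
    for step in range(burnin + reps):
        p1 = int(pos_draw[2 * step])
        p2 = int(pos_draw[2 * step + 1])
        u, v = p1 >> 1, p2 >> 1
        if u != v and tokens[p1] != tokens[p2]:
            a1, a2 = tokens[2 * u], tokens[2 * u + 1]
            b1, b2 = tokens[2 * v], tokens[2 * v + 1]
            old_u = (a1, a2) if a1 <= a2 else (a2, a1)
            old_v = (b1, b2) if b1 <= b2 else (b2, b1)
            tokens[p1], tokens[p2] = tokens[p2], tokens[p1]
            a1, a2 = tokens[2 * u], tokens[2 * u + 1]
            b1, b2 = tokens[2 * v], tokens[2 * v + 1]
            new_u = (a1, a2) if a1 <= a2 else (a2, a1)
            new_v = (b1, b2) if b1 <= b2 else (b2, b1)
            delta = 0.0
            for cell, inc in ((old_u, -1), (old_v, -1),
                              (new_u, 1), (new_v, 1)):
                c0 = int(cur[cell])
                delta += lgamma_cache[c0] - lgamma_cache[c0 + inc]
                if cell[0] != cell[1]:
                    delta += inc * 0.6931471805599453   # ln 2
                cur[cell] = c0 + inc
            log_cur += delta
        if step >= burnin:
            indicators.append(1 if log_cur <= log_obs + _TIE_EPS else 0)
            kept += 1
            if kept % 50_000 == 0:
                log_cur = log_levene_probability(cur)
    hits = sum(indicators)
    p_hat = (1 + hits) / (1 + kept)
    # batch-means standard error: honest under chain autocorrelation
    nb = 50
    if kept >= 2 * nb:
        bs = kept // nb
        arr = np.array(indicators[:nb * bs], dtype=float).reshape(nb, bs)
        means = arr.mean(axis=1)
        se = float(means.std(ddof=1) / math.sqrt(nb))
    else:
        se = math.sqrt(max(p_hat * (1 - p_hat), 0.0) / max(kept, 1))
    return p_hat, se


def _mc_shuffle(mat: np.ndarray, log_obs: float, reps: int,
                rng: np.random.Generator) -> tuple[float, float]:
    """Independent Monte Carlo over gamete arrangements.

    Conditional on allele counts every ordered arrangement of the 2n
    allele copies is equally likely, so a full shuffle per replicate draws
    an independent genotype array from the Levene distribution; the
    binomial standard error is exact.
    """
    k = mat.shape[0]
    tokens = []
    iu = np.triu_indices(k)
    for i, j in zip(*iu):
        tokens.extend([int(i), int(j)] * int(mat[i, j]))
    tokens = np.array(tokens, dtype=np.int64)
    two_n = tokens.size
    n = two_n // 2
    allele_counts = np.bincount(tokens, minlength=k)
    const = (gammaln(n + 1) + float(np.sum(gammaln(allele_counts + 1)))
             - gammaln(two_n + 1))
    lgamma_cache = gammaln(np.arange(n + 2) + 1.0)
    ln2 = math.log(2.0)
    diag_codes = np.arange(k) * k + np.arange(k)
    hits = 0
    for _ in range(reps):
        arr = rng.permutation(tokens).reshape(n, 2)
        lo = arr.min(axis=1)
        hi = arr.max(axis=1)
        codes = lo * k + hi
        counts = np.bincount(codes, minlength=k * k)
        het = n - int(counts[diag_codes].sum())
        logp = const + het * ln2 - float(lgamma_cache[counts].sum())
        if logp <= log_obs + _TIE_EPS:
            hits += 1
    p_hat = (1 + hits) / (1 + reps)
    se = math.sqrt(max(p_hat * (1 - p_hat), 0.0) / reps)
    return p_hat, se


# ---------------------------------------------------------------------------
# public HWE test


def hwe_exact_test(gct: GenotypeCountTable, method: str = "auto",
                   reps: int = 100_000, burnin: int = 10_000,
                   seed: int | None = None,
                   enumeration_limit: int = 10 ** 6) -> ExactTestResult:
    """Exact test of Hardy-Weinberg proportions at one locus.

    ``auto`` enumerates when the conditional array space has at most
    ``enumeration_limit`` arrays and otherwise samples ``reps``
    independent arrangements (``mc``).  ``mcmc`` runs the switch chain
    instead; both randomized methods need ``seed`` for reproducibility.
    """
    gct.validate()
    mat, alleles = _array_to_matrix(gct)
    if len(alleles) <= 1:
        return ExactTestResult(p_value=1.0, method="enumeration",
                               statistic=0.0)
    allele_counts = [int(2 * mat[i, i] + mat[:i, i].sum()
                         + mat[i, i + 1:].sum())
                     for i in range(len(alleles))]
    log_obs = log_levene_probability(mat)

    if method == "auto":
        n_arrays = count_genotype_arrays(allele_counts,
                                         limit=enumeration_limit)
        method = "enumerate" if n_arrays is not None else "mc"

    if method == "enumerate":
        logs = _enumerate_log_probs(allele_counts)
        # normalize in log space for numerical safety
        mx = logs.max()
        probs = np.exp(logs - mx)
        total = probs.sum()
        tail = probs[logs <= log_obs + _TIE_EPS].sum()
        return ExactTestResult(p_value=float(tail / total),
                               method="enumeration", statistic=log_obs)
    if method in ("mc", "mcmc"):
        if reps < 1000:
            import warnings

            warnings.warn("fewer than 1000 Monte-Carlo reps gives a "
                          "coarse p-value")
        rng = np.random.default_rng(seed)
        if method == "mc":
            p_hat, se = _mc_shuffle(mat, log_obs, reps=reps, rng=rng)
        else:
            p_hat, se = _gt_chain(mat, log_obs, reps=reps, burnin=burnin,
                                  rng=rng)
        return ExactTestResult(p_value=p_hat, method="monte_carlo",
                               statistic=log_obs, reps=reps, se=se)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# genotypic LD


def ld_g_statistic(table: np.ndarray) -> float:
    """G = 2 sum o ln(o/e) over non-empty cells of a genotype contingency
    table; 0 for degenerate (single row/column) tables."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    e = row @ col / t.sum()
    mask = t > 0
    return float(2.0 * np.sum(t[mask] * np.log(t[mask] / e[mask])))


def _pair_contingency(ga: Sequence[int], gb: Sequence[int],
                      ka: int, kb: int) -> np.ndarray:
    tab = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(tab, (np.asarray(ga), np.asarray(gb)), 1)
    return tab


def ld_permutation_test(table: GenotypeTable, locus_a: str, locus_b: str,
                        reps: int = 10_000,
                        seed: int | None = None) -> ExactTestResult:
    """Permutation test of genotypic association between two loci.

    Locus-B genotypes are shuffled among the individuals typed at both
    loci; p = (1 + #{G* >= G_obs}) / (1 + reps).
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    ca, cb = table.calls[locus_a], table.calls[locus_b]
    pairs = [(a, b) for a, b in zip(ca, cb) if a is not None and b is not None]
    if len(pairs) < 2:
        raise ValueError(
            f"need >= 2 individuals typed at both {locus_a} and {locus_b}")
    ga_raw = [p[0] for p in pairs]
    gb_raw = [p[1] for p in pairs]
    types_a = {g: i for i, g in enumerate(dict.fromkeys(ga_raw))}
    types_b = {g: i for i, g in enumerate(dict.fromkeys(gb_raw))}
    ga = np.array([types_a[g] for g in ga_raw])
    gb = np.array([types_b[g] for g in gb_raw])
    g_obs = ld_g_statistic(
        _pair_contingency(ga, gb, len(types_a), len(types_b)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(gb)
        g_star = ld_g_statistic(
            _pair_contingency(ga, perm, len(types_a), len(types_b)))
        if g_star >= g_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + reps)
    se = math.sqrt(max(p * (1 - p), 0.0) / reps)
    return ExactTestResult(p_value=p, method="permutation", statistic=g_obs,
                           reps=reps, se=se)


@dataclass
class LDTestMatrix:
    """All pairwise LD results for a locus panel plus the Bonferroni
    verdict."""

    results: dict[tuple[str, str], ExactTestResult]
    alpha: float
    bonferroni_alpha: float

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return sorted(p for p, r in self.results.items()
                      if r.p_value < self.bonferroni_alpha)

    @property
    def n_pairs(self) -> int:
        return len(self.results)


def ld_test_matrix(table: GenotypeTable, reps: int = 10_000,
                   alpha: float = 0.05,
                   seed: int | None = None) -> LDTestMatrix:
    """Run the genotypic LD permutation test for every locus pair.

    Each pair draws from an independent seed stream derived from the master
    seed and the pair name, so results do not depend on evaluation order.
    """
    loci = table.loci
    m = binomial_pairs(len(loci))
    results: dict[tuple[str, str], ExactTestResult] = {}
    for i, la in enumerate(loci):
        for lb in loci[i + 1:]:
            pair_seed = None
            if seed is not None:
                pair_seed = np.random.SeedSequence(
                    [seed, stable_seed(la, lb)]).generate_state(1)[0]
            results[(la, lb)] = ld_permutation_test(
                table, la, lb, reps=reps, seed=pair_seed)
    return LDTestMatrix(results=results, alpha=alpha,
                        bonferroni_alpha=bonferroni_threshold(alpha, m))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha out of (0, 1): {alpha}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_two_sig(x: float) -> str:
    """Display a threshold at two significant figures (e.g. 0.00024)."""
    if x == 0:
        return "0"
    from decimal import Decimal

    d = Decimal(f"{x:.1e}")
    return format(d.normalize(), "f")
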
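"""Interpopulation differentiation: Weir-Cockerham theta with permutation
p-values, Nei's DA distance, and frequency-only Fst surrogates.

``wc_theta`` implements the Weir & Cockerham (1984) variance-components
estimator: for each allele at each locus the among-population (a),
among-individual (b) and within-individual (c) components are computed
from sample sizes, allele frequencies and heterozygote proportions, and
theta is the ratio sum(a) / sum(a + b + c) over alleles (and loci, for the
multilocus estimate).  Negative estimates are legitimate sampling outcomes
and are preserved.

When only published allele-frequency tables are available (no genotypes),
``frequency_fst`` offers Nei's G_st and the Reynolds coancestry estimator;
these are frequency-level approximations, not the genotype-based theta.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AlleleFrequencySpectrum,
    AlleleLabel,
    DistanceMatrix,
    GenotypeTable,
    sort_alleles,
)

__all__ = [
    "FstResult",
    "PopulationPair",
    "nei_da",
    "wc_theta",
    "wc_components",
    "fst_permutation_pvalue",
    "frequency_fst",
    "distance_table",
]

SpectrumSet = Mapping[str, AlleleFrequencySpectrum]


@dataclass
class FstResult:
    """Theta estimate with its variance components."""

    locus: str                      # locus name or "multilocus"
    theta: float
    components: tuple[float, float, float]   # (sum a, sum b, sum c)
    p_value: float | None = None
    degenerate: bool = False        # all components zero (monomorphic)


@dataclass
class PopulationPair:
    """Two populations restricted to their shared loci."""

    pop_a: GenotypeTable | SpectrumSet
    pop_b: GenotypeTable | SpectrumSet
    shared_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.shared_loci:
            la = set(self._loci(self.pop_a))
            lb = set(self._loci(self.pop_b))
            # preserve pop_a order
            self.shared_loci = [l for l in self._loci(self.pop_a)
                                if l in la & lb]
        if not self.shared_loci:
            raise ValueError("populations share no loci")

    @staticmethod
    def _loci(pop) -> list[str]:
        if isinstance(pop, GenotypeTable):
            return list(pop.loci)
        return list(pop.keys())

    def spectra(self, which: str) -> SpectrumSet:
        pop = self.pop_a if which == "a" else self.pop_b
        if isinstance(pop, GenotypeTable):
            return {l: pop.allele_spectrum(l) for l in self.shared_loci}
        return {l: pop[l] for l in self.shared_loci}


# ---------------------------------------------------------------------------
# Nei's DA


def nei_da(spectra_a: SpectrumSet, spectra_b: SpectrumSet,
           loci: Sequence[str] | None = None) -> float:
    """Nei's DA distance: 1 - mean over loci of sum_a sqrt(x_a * y_a).

    Alleles private to one population contribute zero to the locus term;
    the allele space is the union per locus.
    """
    if loci is None:
        loci = [l for l in spectra_a if l in spectra_b]
    if not loci:
        raise ValueError("no shared loci")
    acc = 0.0
    for locus in loci:
        xa = spectra_a[locus].freqs
        yb = spectra_b[locus].freqs
        shared = set(xa) & set(yb)
        acc += sum(math.sqrt(xa[a] * yb[a]) for a in shared)
    return 1.0 - acc / len(loci)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _code_locus(tables: Sequence[GenotypeTable], locus: str,
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Integer-code genotypes per table: (codes (n_typed x 2), het flags).

    Allele coding is shared across tables (union allele space).
    """
    alleles = sort_alleles(
        {a for t in tables for g in t.calls[locus] if g is not None
         for a in g.alleles()})
    idx = {a: i for i, a in enumerate(alleles)}
    out = []
    for t in tables:
        calls = [g for g in t.calls[locus] if g is not None]
        if calls:
            codes = np.array([[idx[g.a1], idx[g.a2]] for g in calls],
                             dtype=np.int64)
            het = codes[:, 0] != codes[:, 1]
        else:
            codes = np.zeros((0, 2), dtype=np.int64)
            het = np.zeros(0, dtype=bool)
        out.append((codes, het))
    out.append((np.zeros((0, 2)), len(alleles)))  # sentinel with k
    return out


def _pop_stats(codes: np.ndarray, het: np.ndarray, k: int,
               ) -> tuple[int, np.ndarray, np.ndarray]:
    """(n, allele frequencies, per-allele heterozygote proportions)."""
    n = codes.shape[0]
    if n == 0:
        return 0, np.zeros(k), np.zeros(k)
    cnt = np.bincount(codes.ravel(), minlength=k).astype(float)
    hvec = np.bincount(codes[het].ravel(), minlength=k).astype(float)
    return n, cnt / (2 * n), hvec / n


def _wc_abc(stats: Sequence[tuple[int, np.ndarray, np.ndarray]],
            ) -> tuple[float, float, float]:
    """Summed Weir-Cockerham (a, b, c) over alleles from per-pop stats."""
    stats = [(n, p, h) for n, p, h in stats if n > 0]
    r = len(stats)
    if r < 2:
        raise ValueError("need >= 2 populations with data")
    ns = np.array([s[0] for s in stats], dtype=float)
    if (ns < 2).any():
        raise ValueError("every population needs >= 2 individuals")
    P = np.stack([s[1] for s in stats])          # r x k frequencies
    H = np.stack([s[2] for s in stats])          # r x k het proportions
    n_bar = ns.mean()
    r_nbar = r * n_bar
    n_c = (r_nbar - (ns ** 2).sum() / r_nbar) / (r - 1)
    p_bar = (ns[:, None] * P).sum(axis=0) / r_nbar
    s2 = (ns[:, None] * (P - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (ns[:, None] * H).sum(axis=0) / r_nbar
    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_components(tables: Sequence[GenotypeTable], locus: str,
                  ) -> tuple[float, float, float]:
    """Summed (a, b, c) variance components over alleles at one locus."""
    coded = _code_locus(tables, locus)
    k = coded[-1][1]
    stats = [_pop_stats(codes, het, k) for codes, het in coded[:-1]]
    return _wc_abc(stats)


def wc_theta(tables: Sequence[GenotypeTable],
             loci: Sequence[str] | None = None,
             per_locus: bool = False,
             ) -> FstResult | list[FstResult]:
    """Weir-Cockerham theta across >= 2 populations.

    With ``per_locus`` a list of per-locus results is returned; otherwise
    the multilocus estimate sum_l a / sum_l (a + b + c).  Monomorphic loci
    yield all-zero components and are reported as theta 0 with the
    ``degenerate`` flag.
    """
    if loci is None:
        shared = set(tables[0].loci)
        for t in tables[1:]:
            shared &= set(t.loci)
        loci = [l for l in tables[0].loci if l in shared]
    if not loci:
        raise ValueError("no shared loci")

    per: list[FstResult] = []
    tot_a = tot_b = tot_c = 0.0
    for locus in loci:
        a, b, c = wc_components(tables, locus)
        tot_a += a
        tot_b += b
        tot_c += c
        denom = a + b + c
        if abs(denom) < 1e-300:
            per.append(FstResult(locus=locus, theta=0.0,
                                 components=(a, b, c), degenerate=True))
        else:
            per.append(FstResult(locus=locus, theta=a / denom,
                                 components=(a, b, c)))
    if per_locus:
        return per
    denom = tot_a + tot_b + tot_c
    if abs(denom) < 1e-300:
        return FstResult(locus="multilocus", theta=0.0,
                         components=(tot_a, tot_b, tot_c), degenerate=True)
    return FstResult(locus="multilocus", theta=tot_a / denom,
                     components=(tot_a, tot_b, tot_c))


def fst_permutation_pvalue(pop_a: GenotypeTable, pop_b: GenotypeTable,
                           loci: Sequence[str] | None = None,
                           reps: int = 1000,
                           seed: int | None = None) -> FstResult:
    """Permutation p-value for theta > 0 between two populations.

    Individuals are shuffled between the populations (sizes preserved);
    p = (1 + #{theta* >= theta_obs}) / (1 + reps).  Only individuals typed
    at a locus carry it into the permuted tables, mirroring the observed
    estimate.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if loci is None:
        loci = [l for l in pop_a.loci if l in set(pop_b.loci)]
    obs = wc_theta([pop_a, pop_b], loci)
    assert isinstance(obs, FstResult)

    # integer-coded pooled genotypes per locus, aligned on pooled
    # individuals so one permutation per replicate moves whole individuals
    n_pool = pop_a.n + pop_b.n
    na = pop_a.n
    pooled = []
    for locus in loci:
        alleles = sort_alleles(
            {a for t in (pop_a, pop_b) for g in t.calls[locus]
             if g is not None for a in g.alleles()})
        idx = {a: i for i, a in enumerate(alleles)}
        codes = np.zeros((n_pool, 2), dtype=np.int64)
        valid = np.zeros(n_pool, dtype=bool)
        for off, t in ((0, pop_a), (pop_a.n, pop_b)):
            for i, g in enumerate(t.calls[locus]):
                if g is not None:
                    codes[off + i] = (idx[g.a1], idx[g.a2])
                    valid[off + i] = True
        het = codes[:, 0] != codes[:, 1]
        pooled.append((codes, het, valid, len(alleles)))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(n_pool)
        ia, ib = perm[:na], perm[na:]
        num = den = 0.0
        for codes, het, valid, k in pooled:
            sa = ia[valid[ia]]
            sb = ib[valid[ib]]
            stats = [_pop_stats(codes[sa], het[sa], k),
                     _pop_stats(codes[sb], het[sb], k)]
            a, b, c = _wc_abc(stats)
            num += a
            den += a + b + c
        theta_star = num / den if abs(den) > 1e-300 else 0.0
        if theta_star >= obs.theta - 1e-12:
            hits += 1
    return FstResult(locus=obs.locus, theta=obs.theta,
                     components=obs.components,
                     p_value=(1 + hits) / (1 + reps))


# ---------------------------------------------------------------------------
# frequency-only Fst


def frequency_fst(spectra_a: SpectrumSet, spectra_b: SpectrumSet,
                  estimator: str = "nei_gst",
                  loci: Sequence[str] | None = None) -> float:
    """Differentiation from allele-frequency tables alone.

    ``nei_gst``: (H_T - H_S) / H_T with H_S the mean within-population
    expected heterozygosity and H_T from the mean frequencies.
    ``reynolds``: coancestry estimator sum (x-y)^2 / (2 sum (1 - sum xy)).
    Both are approximations used when reference populations publish only
    frequency tables; neither is the genotype-based Weir-Cockerham theta.
    """
    if loci is None:
        loci = [l for l in spectra_a if l in spectra_b]
    if not loci:
        raise ValueError("no shared loci")
    if estimator == "nei_gst":
        hs_sum = 0.0
        ht_sum = 0.0
        for locus in loci:
            xa, yb = spectra_a[locus].freqs, spectra_b[locus].freqs
            alleles = set(xa) | set(yb)
            x = np.array([xa.get(a, 0.0) for a in alleles])
            y = np.array([yb.get(a, 0.0) for a in alleles])
            hs_sum += 1.0 - 0.5 * (float(x @ x) + float(y @ y))
            mean = 0.5 * (x + y)
            ht_sum += 1.0 - float(mean @ mean)
        if ht_sum <= 0.0:
            return 0.0      # both populations fixed: undefined, flagged 0
        return (ht_sum - hs_sum) / ht_sum
    if estimator == "reynolds":
        num = 0.0
        den = 0.0
        for locus in loci:
            xa, yb = spectra_a[locus].freqs, spectra_b[locus].freqs
            alleles = set(xa) | set(yb)
            x = np.array([xa.get(a, 0.0) for a in alleles])
            y = np.array([yb.get(a, 0.0) for a in alleles])
            num += 0.5 * float(((x - y) ** 2).sum())
            den += 1.0 - float(x @ y)
        return num / den if den > 0 else 0.0
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# pairwise distance tables


def distance_table(populations: Sequence[tuple[str, object]],
                   metric: str = "da",
                   floor_negative: bool = True,
                   fst_estimator: str = "auto") -> DistanceMatrix:
    """Full pairwise distance matrix over populations.

    ``populations`` is a list of (name, data) where data is a
    ``GenotypeTable`` or a mapping locus -> ``AlleleFrequencySpectrum``.
    ``metric`` is ``da`` or ``fst``.  For ``fst``, genotype inputs use
    Weir-Cockerham theta and frequency inputs fall back to Nei G_st
    (``fst_estimator`` overrides).  Negative Fst estimates are floored at
    zero inside the exported matrix (NJ and MDS need dissimilarities);
    raw values are available through :func:`wc_theta`.
    """
    if len(populations) < 2:
        raise ValueError("need >= 2 populations")
    names = [name for name, _ in populations]

    def spectra_of(data):
        if isinstance(data, GenotypeTable):
            return {l: data.allele_spectrum(l) for l in data.loci}
        return data

    k = len(populations)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            name_i, data_i = populations[i]
            name_j, data_j = populations[j]
            if metric == "da":
                val = nei_da(spectra_of(data_i), spectra_of(data_j))
            elif metric == "fst":
                both_genotypes = (isinstance(data_i, GenotypeTable)
                                  and isinstance(data_j, GenotypeTable))
                if both_genotypes and fst_estimator in ("auto", "wc"):
                    val = wc_theta([data_i, data_j]).theta
                else:
                    est = ("nei_gst" if fst_estimator in ("auto", "wc")
                           else fst_estimator)
                    val = frequency_fst(spectra_of(data_i),
                                        spectra_of(data_j), estimator=est)
                if floor_negative and val < 0:
                    val = 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = val
    return DistanceMatrix(names, d)
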
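"""Core domain types for co-dominant STR data.

Allele labels follow forensic repeat nomenclature: an integer repeat count
with an optional partial-repeat suffix (``"13"``, ``"13.2"``).  Labels are
kept as structured text, never floats, so ``13.2`` stays exact and distinct
from any decimal reading.  Genotypes are unordered allele pairs stored
canonically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlleleLabel",
    "Genotype",
    "GenotypeTable",
    "AlleleFrequencySpectrum",
    "GenotypeCountTable",
    "DistanceMatrix",
    "sort_alleles",
    "MISSING_SENTINELS",
]

#: cell values that encode a missing genotype call in delimited input
MISSING_SENTINELS = {"", "0", "NA", "na", "-", "."}


@dataclass(frozen=True, order=False)
class AlleleLabel:
    """A repeat-number allele label such as ``13`` or ``13.2``.

    Parameters
    ----------
    repeats : int
        Full repeat count (non-negative).
    partial : int
        Partial-repeat bases, 0 (none) to 3.
    """

    repeats: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValueError(f"negative repeat count: {self.repeats}")
        if not 0 <= self.partial <= 3:
            raise ValueError(
                f"partial repeat must be 0..3, got {self.partial}")

    @classmethod
    def parse(cls, text: str | AlleleLabel) -> "AlleleLabel":
        if isinstance(text, AlleleLabel):
            return text
        s = str(text).strip()
        if "." in s:
            whole, _, frac = s.partition(".")
            if frac == "0":
                frac = ""
            if not whole.isdigit() or (frac and not frac.isdigit()):
                raise ValueError(f"unparseable allele label: {text!r}")
            partial = int(frac) if frac else 0
        else:
            whole, partial = s, 0
            if not whole.isdigit():
                raise ValueError(f"unparseable allele label: {text!r}")
        return cls(int(whole), partial)

    @property
    def key(self) -> tuple[int, int]:
        return (self.repeats, self.partial)

    def __lt__(self, other: "AlleleLabel") -> bool:
        return self.key < other.key

    def __le__(self, other: "AlleleLabel") -> bool:
        return self.key <= other.key

    def __str__(self) -> str:
        if self.partial:
            return f"{self.repeats}.{self.partial}"
        return str(self.repeats)

    def __repr__(self) -> str:
        return f"AlleleLabel({self})"


def sort_alleles(labels: Iterable[AlleleLabel | str]) -> list[AlleleLabel]:
    """Sort allele labels ascending by (repeat count, partial repeat)."""
    return sorted((AlleleLabel.parse(x) for x in labels), key=lambda a: a.key)


@dataclass(frozen=True)
class Genotype:
    """Unordered co-dominant genotype, stored with ``a1 <= a2``."""

    a1: AlleleLabel
    a2: AlleleLabel

    def __post_init__(self) -> None:
        if self.a2 < self.a1:
            object.__setattr__(self, "a1", self.a2)
            object.__setattr__(self, "a2", self.a1)

    @classmethod
    def of(cls, a1: str | AlleleLabel, a2: str | AlleleLabel) -> "Genotype":
        x, y = AlleleLabel.parse(a1), AlleleLabel.parse(a2)
        if y < x:
            x, y = y, x
        return cls(x, y)

    @property
    def heterozygous(self) -> bool:
        return self.a1 != self.a2

    def alleles(self) -> tuple[AlleleLabel, AlleleLabel]:
        return (self.a1, self.a2)

    def __str__(self) -> str:
        return f"{self.a1}/{self.a2}"


class GenotypeTable:
    """Individuals x loci table of STR genotype calls for one population.

    ``calls[locus]`` is a list aligned with ``individual_ids``; ``None``
    marks a missing call.  Per-locus statistics use the per-locus typed
    count, so missing data never contaminate other loci.
    """

    def __init__(
        self,
        population_id: str,
        individual_ids: Sequence[str],
        loci: Sequence[str],
        calls: Mapping[str, Sequence[Genotype | None]],
    ) -> None:
        if len(set(individual_ids)) != len(individual_ids):
            dupes = {i for i in individual_ids
                     if list(individual_ids).count(i) > 1}
            raise ValueError(f"duplicate individual ids: {sorted(dupes)}")
        if len(individual_ids) < 1:
            raise ValueError("a population needs at least one individual")
        self.population_id = str(population_id)
        self.individual_ids = list(individual_ids)
        self.loci = list(loci)
        self.calls: dict[str, list[Genotype | None]] = {}
        for locus in self.loci:
            col = list(calls[locus])
            if len(col) != len(self.individual_ids):
                raise ValueError(
                    f"locus {locus}: {len(col)} calls for "
                    f"{len(self.individual_ids)} individuals")
            self.calls[locus] = col

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def typed_count(self, locus: str) -> int:
        return sum(g is not None for g in self.calls[locus])

    def genotype_counts(self, locus: str) -> "GenotypeCountTable":
        counts: dict[Genotype, int] = {}
        for g in self.calls[locus]:
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        return GenotypeCountTable(locus=locus, counts=counts)

    def allele_spectrum(self, locus: str) -> "AlleleFrequencySpectrum":
        return self.genotype_counts(locus).to_spectrum()

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        missing = [l for l in loci if l not in self.calls]
        if missing:
            raise KeyError(f"loci not in table: {missing}")
        return GenotypeTable(self.population_id, self.individual_ids, loci,
                             {l: self.calls[l] for l in loci})

    def __repr__(self) -> str:
        return (f"GenotypeTable({self.population_id!r}, n={self.n}, "
                f"loci={len(self.loci)})")


@dataclass
class GenotypeCountTable:
    """Genotype counts at one locus, with derived allele counts."""

    locus: str
    counts: dict[Genotype, int]

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {g}")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def het_count(self) -> int:
        return sum(c for g, c in self.counts.items() if g.heterozygous)

    @property
    def allele_counts(self) -> dict[AlleleLabel, int]:
        out: dict[AlleleLabel, int] = {}
        for g, c in self.counts.items():
            out[g.a1] = out.get(g.a1, 0) + c
            out[g.a2] = out.get(g.a2, 0) + c
        return out

    def to_spectrum(self) -> "AlleleFrequencySpectrum":
        ac = self.allele_counts
        n = self.n
        return AlleleFrequencySpectrum(
            locus=self.locus, n=n,
            counts={a: ac[a] for a in sort_alleles(ac)})

    def validate(self) -> None:
        if sum(self.allele_counts.values()) != 2 * self.n:
            raise ValueError("allele counts do not sum to 2n")


@dataclass
class AlleleFrequencySpectrum:
    """Allele counts and frequencies at one locus.

    Exactly one of ``counts`` / ``freqs`` may be authoritative.  When built
    from genotypes, integer ``counts`` are exact and frequencies derive from
    them.  When loaded from a rounded published table, ``freqs`` are the
    source and counts are reconstructed as ``round(freq * 2n)`` —
    approximate by construction.
    """

    locus: str
    n: int
    counts: dict[AlleleLabel, int] = field(default_factory=dict)
    freqs: dict[AlleleLabel, float] = field(default_factory=dict)

    #: tolerated deviation of a published column sum from 1
    SUM_TOL = 5e-3

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.locus}: sample size must be >= 1")
        if self.counts and not self.freqs:
            tot = sum(self.counts.values())
            if tot != 2 * self.n:
                raise ValueError(
                    f"{self.locus}: allele counts sum to {tot}, "
                    f"expected 2n = {2 * self.n}")
            self.freqs = {a: c / tot for a, c in self.counts.items()}
        elif self.freqs and not self.counts:
            s = sum(self.freqs.values())
            if abs(s - 1.0) > self.SUM_TOL:
                raise ValueError(
                    f"{self.locus}: frequencies sum to {s:.4f}, not 1")
            self.counts = {a: round(f * 2 * self.n)
                           for a, f in self.freqs.items()}
        elif not self.counts and not self.freqs:
            raise ValueError(f"{self.locus}: empty spectrum")
        if any(f <= 0 for f in self.freqs.values()):
            raise ValueError(f"{self.locus}: non-positive frequency present")

    @property
    def alleles(self) -> list[AlleleLabel]:
        return sort_alleles(self.freqs)

    @property
    def k(self) -> int:
        return len(self.freqs)

    def frequency_array(self) -> np.ndarray:
        return np.array([self.freqs[a] for a in self.alleles], dtype=float)

    def sum_p2(self) -> float:
        return float(np.sum(self.frequency_array() ** 2))

    def __repr__(self) -> str:
        return (f"AlleleFrequencySpectrum({self.locus!r}, n={self.n}, "
                f"k={self.k})")


class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix between populations."""

    def __init__(self, labels: Sequence[str], d: np.ndarray) -> None:
        d = np.asarray(d, dtype=float)
        if d.shape != (len(labels), len(labels)):
            raise ValueError(
                f"matrix shape {d.shape} does not match {len(labels)} labels")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        self.labels = list(labels)
        self.d = 0.5 * (d + d.T)
        np.fill_diagonal(self.d, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    @property
    def size(self) -> int:
        return len(self.labels)

    def floored(self) -> "DistanceMatrix":
        """Copy with negative entries clamped to 0 (for NJ / MDS input)."""
        return DistanceMatrix(self.labels, np.maximum(self.d, 0.0))

    def has_negative(self) -> bool:
        return bool((self.d < 0).any())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.size, 1)
        return self.d[iu]

    def __repr__(self) -> str:
        return f"DistanceMatrix({self.labels})"


def binomial_pairs(k: int) -> int:
    """Number of unordered locus pairs C(k, 2)."""
    return math.comb(k, 2)


def stable_seed(*parts: object) -> int:
    """Deterministic 31-bit seed token from arbitrary parts.

    Python's builtin ``hash`` is salted per process, so derived random
    streams would differ between runs; this uses crc32 instead.
    """
    import zlib

    text = "\x1f".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF
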
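"""Forensic efficiency parameters for STR loci.

The per-locus panel computed here is the standard "Powerstat" set used in
forensic population surveys: observed and expected heterozygosity (HO, HE),
polymorphism information content (PIC), matching probability (MP) and its
complement the power of discrimination (PD), probability of excluding a
random non-parent (PE), and the typical paternity index (TPI).  Cumulative
panel statistics (CPD, CPE) combine loci multiplicatively under linkage
equilibrium.

Formulas
--------
HO = h / n                          (h heterozygotes among n individuals)
HE_biased = 1 - sum p_i^2
HE_unbiased = 2n/(2n-1) * HE_biased
PIC = 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4      (Botstein)
MP_observed = sum_g (n_g / n)^2     (observed genotype frequencies)
MP_hwe = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
PD = 1 - MP
PE = HO^2 (1 - 2 HO (1 - HO)^2)     (Brenner convention)
TPI = 1 / (2 (1 - HO))
CPD = 1 - prod MP_l ;  CPE = 1 - prod (1 - PE_l)
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

from .model import AlleleFrequencySpectrum, GenotypeCountTable, GenotypeTable

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "match_probability",
    "power_of_discrimination",
    "power_of_exclusion",
    "typical_paternity_index",
    "LocusForensicStats",
    "PanelSummary",
    "locus_summary",
    "cumulative_panel",
    "round_half_up",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. n = 0)."""


def round_half_up(x: float, places: int = 4) -> float:
    """Round half away from zero at ``places`` decimals (display convention
    of forensic reports, unlike banker's rounding)."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def observed_heterozygosity(gct: GenotypeCountTable) -> float:
    """HO = heterozygote count / typed individuals."""
    n = gct.n
    if n == 0:
        raise UndefinedStatisticError(
            f"{gct.locus}: no typed individuals")
    return gct.het_count / n


def expected_heterozygosity(spec: AlleleFrequencySpectrum,
                            mode: str = "unbiased") -> float:
    """Expected heterozygosity under random mating.

    ``biased`` is the plug-in 1 - sum p^2; ``unbiased`` applies the
    small-sample factor 2n/(2n-1).
    """
    sp2 = spec.sum_p2()
    he = 1.0 - sp2
    if mode == "biased":
        return he
    if mode == "unbiased":
        if spec.n < 1:
            raise UndefinedStatisticError(
                f"{spec.locus}: n must be >= 1 for unbiased HE")
        return he * (2 * spec.n) / (2 * spec.n - 1)
    raise ValueError(f"unknown HE mode {mode!r}")


def pic(spec: AlleleFrequencySpectrum) -> float:
    """Polymorphism information content (Botstein form)."""
    p = spec.frequency_array()
    sp2 = float(np.sum(p ** 2))
    sp4 = float(np.sum(p ** 4))
    return 1.0 - sp2 - sp2 * sp2 + sp4


def match_probability(source: GenotypeCountTable | AlleleFrequencySpectrum,
                      mode: str = "observed") -> float:
    """Probability that two random individuals share a genotype.

    ``observed`` sums squared observed genotype frequencies and requires
    genotype counts.  ``hwe_expected`` sums squared Hardy-Weinberg genotype
    frequencies from the allele spectrum.
    """
    if mode == "observed":
        if not isinstance(source, GenotypeCountTable):
            raise TypeError(
                "observed-mode MP needs genotype counts, not a spectrum")
        n = source.n
        if n == 0:
            raise UndefinedStatisticError(
                f"{source.locus}: no typed individuals")
        return float(sum((c / n) ** 2 for c in source.counts.values()))
    if mode == "hwe_expected":
        spec = (source.to_spectrum()
                if isinstance(source, GenotypeCountTable) else source)
        p = spec.frequency_array()
        sp2 = float(np.sum(p ** 2))
        sp4 = float(np.sum(p ** 4))
        # sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
        #   = sp4 + 2 * (sp2^2 - sp4) = 2 sp2^2 - sp4
        return 2.0 * sp2 * sp2 - sp4
    raise ValueError(f"unknown MP mode {mode!r}")


def power_of_discrimination(mp: float) -> float:
    return 1.0 - mp


def power_of_exclusion(ho: float) -> float:
    """PE from observed heterozygosity (Brenner/Powerstat convention)."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"HO out of [0, 1]: {ho}")
    return ho * ho * (1.0 - 2.0 * ho * (1.0 - ho) ** 2)


def typical_paternity_index(ho: float) -> float:
    """TPI = 1 / (2 (1 - HO)); +inf when every individual is heterozygous."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"HO out of [0, 1]: {ho}")
    if ho == 1.0:
        return math.inf
    return 1.0 / (2.0 * (1.0 - ho))


@dataclass
class LocusForensicStats:
    """One row of a forensic parameter report."""

    locus: str
    n: int
    HO: float
    HE: float
    PIC: float
    MP: float
    PD: float
    PE: float
    TPI: float
    hwe_p: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, places: int = 4) -> dict:
        out = self.as_dict()
        for k in ("HO", "HE", "PIC", "MP", "PD", "PE", "TPI", "hwe_p"):
            if out[k] is not None and math.isfinite(out[k]):
                out[k] = round_half_up(out[k], places)
        return out


@dataclass
class PanelSummary:
    """Cumulative discrimination / exclusion power of a locus panel."""

    loci_used: list[str]
    CPD: float
    CPE: float
    #: product of per-locus MP: the CPD complement, reported in scientific
    #: notation because CPD itself collapses to 0.999... in fixed point
    cmp_product: float
    cpe_complement: float

    def as_dict(self) -> dict:
        return asdict(self)


def locus_summary(table: GenotypeTable, locus: str,
                  he_mode: str = "unbiased",
                  mp_mode: str = "observed") -> LocusForensicStats:
    """Assemble the full per-locus panel from one pass over genotypes."""
    gct = table.genotype_counts(locus)
    if gct.n == 0:
        raise UndefinedStatisticError(f"{locus}: no typed individuals")
    spec = gct.to_spectrum()
    ho = observed_heterozygosity(gct)
    mp = match_probability(gct if mp_mode == "observed" else spec,
                           mode=mp_mode)
    return LocusForensicStats(
        locus=locus,
        n=gct.n,
        HO=ho,
        HE=expected_heterozygosity(spec, mode=he_mode),
        PIC=pic(spec),
        MP=mp,
        PD=power_of_discrimination(mp),
        PE=power_of_exclusion(ho),
        TPI=typical_paternity_index(ho),
    )


def cumulative_panel(stats: Sequence[LocusForensicStats] | Iterable,
                     ) -> PanelSummary:
    """Combine per-locus MP and PE into panel-level CPD / CPE.

    Products are accumulated in log space: a 21-locus CPD differs from 1 by
    ~1e-20, far below what naive subtraction in fixed point can show, so the
    complement ``prod MP_l`` is reported alongside.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("empty locus list")
    loci = [s.locus for s in stats]
    if len(set(loci)) != len(loci):
        dupes = {l for l in loci if loci.count(l) > 1}
        raise ValueError(f"duplicate loci in panel: {sorted(dupes)}")
    log_mp = 0.0
    log_one_minus_pe = 0.0
    for s in stats:
        if s.MP <= 0.0:
            log_mp = -math.inf
        else:
            log_mp += math.log(s.MP)
        if s.PE >= 1.0:
            log_one_minus_pe = -math.inf
        else:
            log_one_minus_pe += math.log1p(-s.PE)
    mp_prod = math.exp(log_mp)
    pe_comp = math.exp(log_one_minus_pe)
    return PanelSummary(
        loci_used=loci,
        CPD=1.0 - mp_prod,
        CPE=1.0 - pe_comp,
        cmp_product=mp_prod,
        cpe_complement=pe_comp,
    )
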
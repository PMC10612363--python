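"""Haplotype-level and per-locus forensic parameters.

Haplotype-level quantities (diversity, match probability, discrimination
capacity, unique-haplotype fraction) all derive from the multiplicity
spectrum — the histogram of how many distinct haplotypes occur exactly
``m`` times.  Per-locus statistics follow the conventions of the STRAF
program: Botstein's PIC, Brenner-style power of exclusion, and typical
paternity index 1/(2H) with H = sum of squared allele frequencies used as
the haploid homozygosity analogue.  These per-locus formulas are
convention-dependent and are documented as such.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

from .panels import (
    Allele,
    LocusPanel,
    PanelError,
    PopulationSample,
    haplotype_key,
)

__all__ = [
    "MultiplicitySpectrum",
    "ForensicSummary",
    "LocusStats",
    "DualCopyStats",
    "multiplicity_spectrum",
    "haplotype_diversity",
    "match_probability",
    "discrimination_capacity",
    "unique_haplotype_fraction",
    "forensic_summary",
    "allele_frequencies",
    "locus_forensic_params",
    "locus_stats",
    "dualcopy_haplotype_stats",
    "categorical_diversity",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimal places (display rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# multiplicity spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiplicitySpectrum:
    """Histogram ``multiplicity -> number of distinct haplotypes seen that
    many times``; the sufficient statistic for all haplotype-level
    parameters."""

    n: int
    counts: tuple[tuple[int, int], ...]  # sorted (multiplicity, n_haplotypes)

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "MultiplicitySpectrum":
        items = tuple(sorted((int(m), int(c)) for m, c in counts.items() if c))
        if any(m < 1 or c < 0 for m, c in items):
            raise ValueError(f"invalid multiplicity counts {counts!r}")
        n = sum(m * c for m, c in items)
        if n == 0:
            raise ValueError("empty spectrum")
        return cls(n, items)

    @classmethod
    def from_items(cls, items: Iterable[Hashable]) -> "MultiplicitySpectrum":
        tally = Counter(items)
        if not tally:
            raise ValueError("empty sample")
        return cls.from_counts(Counter(tally.values()))

    @property
    def distinct(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def singletons(self) -> int:
        return dict(self.counts).get(1, 0)

    def sum_p_squared(self) -> Fraction:
        """Exact sum of squared observed haplotype frequencies."""
        return Fraction(sum(c * m * m for m, c in self.counts), self.n * self.n)


def multiplicity_spectrum(
    sample: PopulationSample, panel_subset: LocusPanel | None = None
) -> MultiplicitySpectrum:
    """Spectrum of full haplotype strings compared on a marker subset
    (defaults to the sample's own panel)."""
    panel = panel_subset or sample.panel
    return MultiplicitySpectrum.from_items(
        haplotype_key(rec, panel) for rec in sample.records
    )


# ---------------------------------------------------------------------------
# haplotype-level parameters
# ---------------------------------------------------------------------------

def haplotype_diversity(spectrum: MultiplicitySpectrum) -> float:
    """HD = n(1 - sum p_i^2)/(n - 1); computed in exact rationals."""
    n = spectrum.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    hd = Fraction(n, n - 1) * (1 - spectrum.sum_p_squared())
    return float(hd)


def match_probability(spectrum: MultiplicitySpectrum) -> float:
    """HMP = sum of squared observed haplotype frequencies."""
    return float(spectrum.sum_p_squared())


def discrimination_capacity(spectrum: MultiplicitySpectrum) -> float:
    """DC = distinct haplotypes / sample size."""
    return spectrum.distinct / spectrum.n


def unique_haplotype_fraction(spectrum: MultiplicitySpectrum) -> float:
    return spectrum.singletons / spectrum.n


@dataclass(frozen=True)
class ForensicSummary:
    n: int
    distinct: int
    unique_fraction: float
    dc: float
    hmp: float
    hd: float

    def display(self) -> dict[str, float | int]:
        """Printed-precision view: percentages at 2 d.p., diversities at 4."""
        return {
            "n": self.n,
            "distinct": self.distinct,
            "unique_fraction_pct": round_half_up(100 * self.unique_fraction, 2),
            "dc_pct": round_half_up(100 * self.dc, 2),
            "hmp": round_half_up(self.hmp, 4),
            "hd": round_half_up(self.hd, 4),
        }


def forensic_summary(spectrum: MultiplicitySpectrum) -> ForensicSummary:
    return ForensicSummary(
        n=spectrum.n,
        distinct=spectrum.distinct,
        unique_fraction=unique_haplotype_fraction(spectrum),
        dc=discrimination_capacity(spectrum),
        hmp=match_probability(spectrum),
        hd=haplotype_diversity(spectrum) if spectrum.n >= 2 else 0.0,
    )


def categorical_diversity(labels: Sequence[Hashable]) -> float:
    """HD formula applied to arbitrary category labels (e.g. haplogroups)."""
    if len(labels) < 2:
        raise ValueError("categorical diversity requires n >= 2")
    return haplotype_diversity(MultiplicitySpectrum.from_items(labels))


# ---------------------------------------------------------------------------
# per-locus parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusStats:
    locus: str
    allele_frequencies: tuple[tuple[float, float], ...]  # (allele, frequency)
    n_eff: int
    excluded: tuple[str, ...] = ()
    gd: float | None = None
    pic: float | None = None
    pm: float | None = None
    pd: float | None = None
    pe: float | None = None
    tpi: float | None = None

    @property
    def distinct_alleles(self) -> int:
        return len(self.allele_frequencies)

    def frequencies(self) -> dict[float, float]:
        return dict(self.allele_frequencies)


def allele_frequencies(sample: PopulationSample, locus: str) -> LocusStats:
    """Allele frequency table at a single-copy locus.

    Records with a null or duplicated allele at the locus are excluded from
    the denominator (and logged); microvariants are distinct alleles.
    """
    definition = sample.panel.locus(locus)
    if definition.copy_number != 1:
        raise PanelError(f"{locus} is dual-copy; use dualcopy_haplotype_stats")
    tally: Counter[float] = Counter()
    excluded: list[str] = []
    for rec in sample.records:
        a = rec.alleles[locus]
        if a.is_null or a.is_duplicated:
            excluded.append(rec.sample_id)
            continue
        tally[a.values[0]] += 1
    n_eff = sum(tally.values())
    freqs = tuple(
        (allele, count / n_eff) for allele, count in sorted(tally.items())
    )
    return LocusStats(locus, freqs, n_eff, tuple(excluded))


def _gd(sum_p2: float, n: int) -> float:
    return (n / (n - 1)) * (1.0 - sum_p2)


def locus_forensic_params(
    freqs: Mapping[float, float] | Sequence[tuple[float, float]],
    n_eff: int,
    locus: str = "",
) -> LocusStats:
    """Fill GD, PIC, PM, PD, PE, TPI from an allele frequency table.

    GD = (n/(n-1))(1 - sum p^2); PM = sum p^2; PD = 1 - PM;
    PIC = 1 - sum p^2 - [(sum p^2)^2 - sum p^4];
    with H = sum p^2 and h = 1 - H: PE = h^2 (1 - 2 h H); TPI = 1/(2H).
    """
    table = dict(freqs) if isinstance(freqs, Mapping) else dict(freqs)
    total = sum(table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {total}, expected 1")
    if n_eff < 2:
        raise ValueError("locus statistics require n_eff >= 2")
    p = list(table.values())
    s2 = sum(q * q for q in p)
    s4 = sum(q ** 4 for q in p)
    pic = 1.0 - s2 - (s2 * s2 - s4)
    h = 1.0 - s2
    pe = h * h * (1.0 - 2.0 * h * s2)
    tpi = 1.0 / (2.0 * s2)
    return LocusStats(
        locus=locus,
        allele_frequencies=tuple(sorted(table.items())),
        n_eff=n_eff,
        gd=_gd(s2, n_eff),
        pic=pic,
        pm=s2,
        pd=1.0 - s2,
        pe=pe,
        tpi=tpi,
    )


def locus_stats(sample: PopulationSample, locus: str) -> LocusStats:
    """Frequencies plus all forensic parameters for one single-copy locus."""
    base = allele_frequencies(sample, locus)
    full = locus_forensic_params(base.frequencies(), base.n_eff, locus)
    return LocusStats(
        locus=locus,
        allele_frequencies=full.allele_frequencies,
        n_eff=base.n_eff,
        excluded=base.excluded,
        gd=full.gd,
        pic=full.pic,
        pm=full.pm,
        pd=full.pd,
        pe=full.pe,
        tpi=full.tpi,
    )


@dataclass(frozen=True)
class DualCopyStats:
    locus: str
    pair_frequencies: tuple[tuple[tuple[float, float], float], ...]
    n_eff: int
    excluded: tuple[str, ...]

    @property
    def distinct_pairs(self) -> int:
        return len(self.pair_frequencies)

    @property
    def distinct_alleles(self) -> int:
        return len({a for pair, _ in self.pair_frequencies for a in pair})

    @property
    def gd(self) -> float:
        s2 = sum(f * f for _, f in self.pair_frequencies)
        return _gd(s2, self.n_eff)


def dualcopy_haplotype_stats(sample: PopulationSample, locus: str) -> DualCopyStats:
    """Unordered allele-pair frequency table and GD at a dual-copy locus."""
    definition = sample.panel.locus(locus)
    if definition.copy_number != 2:
        raise PanelError(f"{locus} is not a dual-copy locus")
    tally: Counter[tuple[float, float]] = Counter()
    excluded: list[str] = []
    for rec in sample.records:
        a = rec.alleles[locus]
        if a.is_null or len(a.values) != 2:
            excluded.append(rec.sample_id)
            continue
        tally[(a.values[0], a.values[1])] += 1
    n_eff = sum(tally.values())
    if n_eff == 0:
        raise ValueError(f"no typed records at {locus}")
    freqs = tuple((pair, c / n_eff) for pair, c in sorted(tally.items()))
    return DualCopyStats(locus, freqs, n_eff, tuple(excluded))
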
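"""Founder-expansion stepwise-mutation simulator for Y-STR samples.

Each simulated male descends from one of K founders: the founder vector is
copied and every allele copy receives a net step displacement summed over
M ~ Poisson(mu_l * G) single-step (+1/-1, equiprobable) mutations.
Subpopulation structure is created by first drifting a per-subpopulation
copy of each founder for ``divergence_generations`` before the within-
population expansion, so divergence 0 gives exchangeable subpopulations.
Low-rate anomalies (microvariant, duplication, null) can be injected and
are recorded in the truth log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .forensic import MultiplicitySpectrum
from .panels import (
    Allele,
    Anomaly,
    HaplotypeRecord,
    LocusPanel,
    PopulationSample,
    build_panel,
    derive_anomalies,
)

__all__ = [
    "FounderSpec",
    "SubpopulationSpec",
    "AnomalyRates",
    "SimulationConfig",
    "SimulationResult",
    "TruthRecord",
    "simulate_sample",
    "make_fixture_spectrum",
    "DEFAULT_RATE_STANDARD",
    "DEFAULT_RATE_RAPID",
]

DEFAULT_RATE_STANDARD = 2e-3
DEFAULT_RATE_RAPID = 1e-2


@dataclass(frozen=True)
class FounderSpec:
    label: str
    vector: tuple[tuple[int, ...], ...] | None = None  # per-locus value tuples


@dataclass(frozen=True)
class SubpopulationSpec:
    name: str
    size: int
    founder_weights: tuple[float, ...]


@dataclass(frozen=True)
class AnomalyRates:
    microvariant: float = 0.0
    duplication: float = 0.0
    null: float = 0.0

    def __post_init__(self) -> None:
        for name, rate in (
            ("microvariant", self.microvariant),
            ("duplication", self.duplication),
            ("null", self.null),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"anomaly rate {name} must be in [0, 1], got {rate}")


@dataclass(frozen=True)
class SimulationConfig:
    panel: LocusPanel
    founders: tuple[FounderSpec, ...]
    subpopulations: tuple[SubpopulationSpec, ...]
    generations: int = 30
    divergence_generations: int = 0
    mutation_rates: Mapping[str, float] | None = None  # per locus, per generation
    anomaly_rates: AnomalyRates = AnomalyRates()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.founders:
            raise ValueError("at least one founder required")
        if not self.subpopulations:
            raise ValueError("at least one subpopulation required")
        for sp in self.subpopulations:
            if sp.size < 1:
                raise ValueError(f"subpopulation {sp.name!r}: size must be >= 1")
            if len(sp.founder_weights) != len(self.founders):
                raise ValueError(
                    f"subpopulation {sp.name!r}: founder weights must match founder count"
                )
            if abs(sum(sp.founder_weights) - 1.0) > 1e-9:
                raise ValueError(f"subpopulation {sp.name!r}: weights must sum to 1")
        if self.generations < 0 or self.divergence_generations < 0:
            raise ValueError("generation counts must be nonnegative")

    def rate(self, locus_name: str) -> float:
        if self.mutation_rates is not None and locus_name in self.mutation_rates:
            return float(self.mutation_rates[locus_name])
        definition = self.panel.locus(locus_name)
        return (
            DEFAULT_RATE_RAPID
            if definition.mutation_class == "rapidly_mutating"
            else DEFAULT_RATE_STANDARD
        )


class TruthRecord(NamedTuple):
    sample_id: str
    subpopulation: str
    founder: str
    n_mutations: int
    anomalies: tuple[Anomaly, ...]


@dataclass(frozen=True)
class SimulationResult:
    samples: tuple[PopulationSample, ...]
    truth: tuple[TruthRecord, ...]

    def merged(self, name: str = "combined") -> PopulationSample:
        records = tuple(r for s in self.samples for r in s.records)
        return PopulationSample(name, self.samples[0].panel, records)


def _net_steps(rng: np.random.Generator, expected: float) -> tuple[int, int]:
    """Net displacement and raw mutation count for one allele copy."""
    m = int(rng.poisson(expected))
    if m == 0:
        return 0, 0
    steps = rng.integers(0, 2, size=m) * 2 - 1
    return int(steps.sum()), m


def _founder_vector(
    spec: FounderSpec, panel: LocusPanel, rng: np.random.Generator
) -> tuple[tuple[int, ...], ...]:
    if spec.vector is not None:
        vec = tuple(tuple(int(v) for v in copies) for copies in spec.vector)
        if len(vec) != len(panel):
            raise ValueError(f"founder {spec.label!r}: vector length != panel size")
        return vec
    out = []
    for locus in panel:
        mid = int((locus.allele_range.lo + locus.allele_range.hi) / 2)
        out.append(tuple(mid for _ in range(locus.copy_number)))
    return tuple(out)


def simulate_sample(config: SimulationConfig) -> SimulationResult:
    """Draw one sample per subpopulation plus a truth log; reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    base = {f.label: _founder_vector(f, panel, rng) for f in config.founders}

    # per-subpopulation drifted founder copies (divergence offset)
    drifted: dict[tuple[str, str], tuple[tuple[int, ...], ...]] = {}
    for sp in config.subpopulations:
        for founder in config.founders:
            vec = []
            for locus, copies in zip(panel, base[founder.label]):
                expected = config.rate(locus.name) * config.divergence_generations
                vec.append(
                    tuple(v + _net_steps(rng, expected)[0] for v in copies)
                )
            drifted[(sp.name, founder.label)] = tuple(vec)

    samples: list[PopulationSample] = []
    truth: list[TruthRecord] = []
    counter = 0
    labels = [f.label for f in config.founders]
    for sp in config.subpopulations:
        records: list[HaplotypeRecord] = []
        for _ in range(sp.size):
            counter += 1
            sid = f"S{counter:05d}"
            founder = labels[rng.choice(len(labels), p=np.asarray(sp.founder_weights))]
            origin = drifted[(sp.name, founder)]
            alleles: dict[str, Allele] = {}
            n_mut = 0
            for locus, copies in zip(panel, origin):
                expected = config.rate(locus.name) * config.generations
                values = []
                for v in copies:
                    step, m = _net_steps(rng, expected)
                    n_mut += m
                    values.append(float(v + step))
                if locus.copy_number == 2:
                    alleles[locus.name] = Allele.pair(values[0], values[1])
                else:
                    alleles[locus.name] = Allele.present(values[0])

            alleles = _inject_anomalies(alleles, panel, config.anomaly_rates, rng)
            anomalies = derive_anomalies(alleles, panel)
            records.append(
                HaplotypeRecord(
                    sample_id=sid,
                    population=sp.name,
                    region=sp.name,
                    haplogroup=founder,
                    alleles=alleles,
                    anomalies=anomalies,
                )
            )
            truth.append(TruthRecord(sid, sp.name, founder, n_mut, anomalies))
        samples.append(PopulationSample(sp.name, panel, tuple(records)))
    return SimulationResult(tuple(samples), tuple(truth))


def _inject_anomalies(
    alleles: dict[str, Allele],
    panel: LocusPanel,
    rates: AnomalyRates,
    rng: np.random.Generator,
) -> dict[str, Allele]:
    single = [l.name for l in panel if l.copy_number == 1]
    if not single:
        return alleles
    wanted = [
        kind
        for kind, rate in (
            ("microvariant", rates.microvariant),
            ("duplication", rates.duplication),
            ("null", rates.null),
        )
        if rate > 0.0 and rng.random() < rate
    ]
    if not wanted:
        return alleles
    chosen = rng.choice(len(single), size=min(len(wanted), len(single)), replace=False)
    out = dict(alleles)
    for kind, idx in zip(wanted, np.atleast_1d(chosen)):
        locus = single[int(idx)]
        value = out[locus].values[0]
        if kind == "microvariant":
            out[locus] = Allele.present(value + 0.2)
        elif kind == "duplication":
            out[locus] = Allele.duplicated(value, value + 1)
        else:
            out[locus] = Allele.null()
    return out


# ---------------------------------------------------------------------------
# spectrum-shaped fixtures
# ---------------------------------------------------------------------------

def make_fixture_spectrum(
    shape: Mapping[int, int],
    panel: LocusPanel | None = None,
    name: str = "fixture",
    population: str = "SIM",
    seed: int = 0,
) -> PopulationSample:
    """Construct a sample whose multiplicity spectrum equals ``shape``
    exactly: for each (multiplicity m -> count c), c distinct random
    haplotypes each repeated m times."""
    spectrum = MultiplicitySpectrum.from_counts(shape)  # validates
    panel = panel or build_panel("yfiler_plus_27")
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    vectors: list[dict[str, Allele]] = []
    while len(vectors) < spectrum.distinct:
        alleles: dict[str, Allele] = {}
        key = []
        for locus in panel:
            lo = int(math.ceil(locus.allele_range.lo))
            hi = int(math.floor(locus.allele_range.hi))
            values = sorted(
                int(rng.integers(lo, hi + 1)) for _ in range(locus.copy_number)
            )
            key.extend(values)
            if locus.copy_number == 2:
                alleles[locus.name] = Allele.pair(*values)
            else:
                alleles[locus.name] = Allele.present(values[0])
        tkey = tuple(key)
        if tkey in seen:
            continue
        seen.add(tkey)
        vectors.append(alleles)

    records: list[HaplotypeRecord] = []
    i = 0
    sid = 0
    for mult, count in sorted(dict(shape).items(), reverse=True):
        for _ in range(count):
            alleles = vectors[i]
            i += 1
            for _ in range(mult):
                sid += 1
                records.append(
                    HaplotypeRecord(
                        sample_id=f"F{sid:05d}",
                        population=population,
                        alleles=alleles,
                        anomalies=derive_anomalies(alleles, panel),
                    )
                )
    return PopulationSample(name, panel, tuple(records))
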
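"""Seeded generators for genotypes, pedigrees, genotyping noise and egg logs.

Everything the analysis consumes can be simulated here: Hardy-Weinberg
parental genotypes, Mendelian sexual offspring, terminal-fusion automictic
parthenotes (homozygous at every locus for one maternal allele), per-locus
genotyping failure / allele dropout, and oviposition schedules where eggs
arrive in pairs every few days and the chance an egg is fertilized decays
geometrically with time since insemination (a stand-in for sperm-storage
depletion).  All generators are reproducible given (seed, parameters).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import UsageError, ValidationError
from .genotypes_io import LocusGenotype, MultilocusGenotype, Panel
from .repro_metrics import EggEvent, Fate
from .util import as_rng

#: locus names of the default nine-locus panel
DEFAULT_LOCUS_NAMES = (
    "Cp1",
    "Cpl80",
    "Cpl150",
    "Cpl471",
    "Cpl930",
    "Cpl1163",
    "Cpl962",
    "Cpl1161",
    "Cpl1141",
)


@dataclass(frozen=True)
class LocusModel:
    """Allele lengths and frequencies for one simulated locus."""

    name: str
    allele_lengths: tuple[int, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        lengths = tuple(int(a) for a in self.allele_lengths)
        freqs = tuple(float(f) for f in self.frequencies)
        if len(lengths) != len(freqs):
            raise ValidationError(f"{self.name}: lengths and frequencies differ in size")
        if len(set(lengths)) != len(lengths):
            raise ValidationError(f"{self.name}: allele lengths must be distinct")
        if any(f < 0 for f in freqs):
            raise ValidationError(f"{self.name}: frequencies must be non-negative")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValidationError(f"{self.name}: frequencies must sum to 1")
        object.__setattr__(self, "allele_lengths", lengths)
        object.__setattr__(self, "frequencies", freqs)

    @classmethod
    def equifrequent(cls, name: str, lengths: Sequence[int]) -> "LocusModel":
        k = len(lengths)
        return cls(name, tuple(lengths), tuple(1.0 / k for _ in range(k)))


def default_locus_models(n_alleles: int = 6) -> list[LocusModel]:
    """Nine equifrequent loci; diverse enough that a Mendelian offspring is
    essentially never homozygous at every locus (< 1e-5 at 6 alleles)."""
    models = []
    for i, name in enumerate(DEFAULT_LOCUS_NAMES):
        base = 100 + 20 * i
        models.append(
            LocusModel.equifrequent(name, [base + 4 * k for k in range(n_alleles)])
        )
    return models


def panel_of(models: Sequence[LocusModel]) -> Panel:
    return Panel(tuple(m.name for m in models))


def simulate_population(
    n_dams: int,
    n_sires: int,
    loci: Sequence[LocusModel],
    seed=None,
) -> list[MultilocusGenotype]:
    """Draw Hardy-Weinberg genotypes: two independent alleles per locus."""
    if not loci:
        raise UsageError("simulate_population requires at least one locus model")
    if n_dams < 0 or n_sires < 0:
        raise UsageError("population sizes must be non-negative")
    rng = as_rng(seed)
    out = []
    specs = [("dam", "D", n_dams), ("sire", "S", n_sires)]
    for role, prefix, count in specs:
        for i in range(count):
            genotypes = {}
            for model in loci:
                pair = rng.choice(model.allele_lengths, size=2, p=model.frequencies)
                genotypes[model.name] = LocusGenotype(int(pair[0]), int(pair[1]))
            out.append(MultilocusGenotype(f"{prefix}{i + 1:03d}", genotypes, role))
    return out


def _require_full(ind: MultilocusGenotype, who: str) -> None:
    if any(not g.is_full for g in ind.genotypes.values()):
        raise UsageError(f"{who} genotype must be full at every locus")


def simulate_offspring(
    dam: MultilocusGenotype,
    sire: MultilocusGenotype,
    seed=None,
    offspring_id: str = "offspring",
) -> MultilocusGenotype:
    """Mendelian offspring: one allele uniformly from each parent per locus."""
    if set(dam.genotypes) != set(sire.genotypes):
        raise UsageError("dam and sire are genotyped on different panels")
    _require_full(dam, "dam")
    _require_full(sire, "sire")
    rng = as_rng(seed)
    genotypes = {}
    for locus, dg in dam.genotypes.items():
        sg = sire.genotypes[locus]
        a = dg.a1 if rng.random() < 0.5 else dg.a2
        b = sg.a1 if rng.random() < 0.5 else sg.a2
        genotypes[locus] = LocusGenotype(a, b)
    return MultilocusGenotype(offspring_id, genotypes, "offspring")


def simulate_parthenote(
    dam: MultilocusGenotype,
    seed=None,
    offspring_id: str = "parthenote",
) -> MultilocusGenotype:
    """Terminal-fusion automixis: duplicate one maternal allele per locus.

    The product is homozygous at every locus for an allele the dam carries.
    (Central fusion, which would retain maternal heterozygosity, is out of
    scope.)
    """
    _require_full(dam, "dam")
    rng = as_rng(seed)
    genotypes = {}
    for locus, dg in dam.genotypes.items():
        a = dg.a1 if rng.random() < 0.5 else dg.a2
        genotypes[locus] = LocusGenotype(a, a)
    return MultilocusGenotype(offspring_id, genotypes, "offspring")


def apply_genotyping_noise(
    g: MultilocusGenotype,
    locus_failure_rate: float = 0.0,
    allele_dropout_rate: float = 0.0,
    seed=None,
) -> MultilocusGenotype:
    """Knock out whole loci and single allele slots at the given rates."""
    for rate in (locus_failure_rate, allele_dropout_rate):
        if not 0.0 <= rate <= 1.0:
            raise UsageError("noise rates must be probabilities in [0, 1]")
    rng = as_rng(seed)
    genotypes = {}
    for locus, lg in g.genotypes.items():
        if rng.random() < locus_failure_rate:
            genotypes[locus] = LocusGenotype()
            continue
        slots = []
        for a in (lg.a1, lg.a2):
            if a is not None and rng.random() < allele_dropout_rate:
                a = None
            slots.append(a)
        genotypes[locus] = LocusGenotype(*slots)
    return MultilocusGenotype(g.individual_id, genotypes, g.role)


# ---------------------------------------------------------------------------
# oviposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OvipositionModel:
    """Stochastic model of a female's laying season.

    Egg pairs are laid every ``pair_interval_days`` (inclusive integer
    range, default 6-7 days) for ``season_length_days``.  Each egg is a
    wind case with ``wind_rate``; otherwise it is a parthenote with
    ``parthenote_rate``, else fertilized with probability
    ``initial_fertility * fertilization_decay ** days_since_insemination``
    (zero before insemination).  Developed eggs hatch with
    ``hatch_given_fertile``.
    """

    pair_interval_days: tuple[int, int] = (6, 7)
    season_length_days: int = 105
    wind_rate: float = 0.05
    initial_fertility: float = 0.6
    fertilization_decay: float = 0.985
    parthenote_rate: float = 0.011
    hatch_given_fertile: float = 0.8

    def __post_init__(self) -> None:
        lo, hi = (int(x) for x in self.pair_interval_days)
        if lo <= 0 or hi < lo:
            raise ValidationError("pair_interval_days must be a positive (lo, hi) range")
        object.__setattr__(self, "pair_interval_days", (lo, hi))
        if self.season_length_days <= 0:
            raise ValidationError("season_length_days must be positive")
        for name in (
            "wind_rate",
            "initial_fertility",
            "fertilization_decay",
            "parthenote_rate",
            "hatch_given_fertile",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1]")

    @classmethod
    def from_dict(cls, doc: dict) -> "OvipositionModel":
        doc = dict(doc)
        if "pair_interval_days" in doc:
            doc["pair_interval_days"] = tuple(doc["pair_interval_days"])
        return cls(**doc)


def simulate_oviposition(
    female_id: str,
    model: OvipositionModel,
    insemination_day: Optional[int] = None,
    seed=None,
) -> list[EggEvent]:
    """Simulate one female's egg-case log as :class:`EggEvent` records."""
    rng = as_rng(seed)
    lo, hi = model.pair_interval_days
    events: list[EggEvent] = []
    day = 0
    pair_idx = 0
    while day <= model.season_length_days:
        pair_idx += 1
        pair_id = f"{female_id}-pair{pair_idx:03d}"
        for side in ("a", "b"):
            egg_id = f"{female_id}-{pair_idx:03d}{side}"
            if rng.random() < model.wind_rate:
                events.append(EggEvent(female_id, day, Fate.WIND, pair_id))
                continue
            if rng.random() < model.parthenote_rate:
                fate = (
                    Fate.HATCHED
                    if rng.random() < model.hatch_given_fertile
                    else Fate.EMBRYO_DEATH
                )
                events.append(
                    EggEvent(female_id, day, fate, pair_id, egg_id, parthenote=True)
                )
                continue
            if insemination_day is not None and day >= insemination_day:
                p = model.initial_fertility * model.fertilization_decay ** (
                    day - insemination_day
                )
            else:
                p = 0.0
            if rng.random() < p:
                fate = (
                    Fate.HATCHED
                    if rng.random() < model.hatch_given_fertile
                    else Fate.EMBRYO_DEATH
                )
                events.append(
                    EggEvent(female_id, day, fate, pair_id, egg_id, parthenote=False)
                )
            else:
                events.append(EggEvent(female_id, day, Fate.INFERTILE, pair_id))
        day += int(rng.integers(lo, hi + 1))
    return events


def load_locus_models(path) -> list[LocusModel]:
    """Read locus models from a YAML config: a list of LocusModel mappings."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    items = doc["loci"] if isinstance(doc, dict) else doc
    return [
        LocusModel(m["name"], tuple(m["allele_lengths"]), tuple(m["frequencies"]))
        for m in items
    ]
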
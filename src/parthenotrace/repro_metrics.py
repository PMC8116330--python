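"""Per-female and cohort reproductive statistics from oviposition logs.

Egg cases laid without an ovum ("wind" cases) are excluded from every
fertility denominator.  Fertility is the percentage of non-wind egg cases
that developed an embryo and hatchability the percentage that hatched;
both are adjusted by default to count only eggs attributable to
insemination, i.e. parthenote-flagged eggs are excluded from the
numerators.  Fertility duration is the day offset between a female's first
and last inseminated-fertile egg.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, UsageError, ValidationError
from .util import round_half_away

DayLike = Union[int, _dt.date]


class Fate(str, Enum):
    WIND = "wind"
    INFERTILE = "infertile"
    EMBRYO_DEATH = "embryo_death"
    HATCHED = "hatched"


#: fates that mean an embryo developed
FERTILE_FATES = frozenset({Fate.EMBRYO_DEATH, Fate.HATCHED})


@dataclass(frozen=True)
class EggEvent:
    """One egg-case record: who laid it, when, and what became of it."""

    female_id: str
    lay_day: DayLike
    fate: Fate
    pair_id: Optional[str] = None
    offspring_id: Optional[str] = None
    parthenote: Optional[bool] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fate", Fate(self.fate))
        if self.fate is Fate.WIND and (self.offspring_id or self.parthenote):
            raise ValidationError("wind cases carry no offspring id or parthenote flag")
        if self.parthenote and self.fate not in FERTILE_FATES:
            raise ValidationError(
                "parthenote flag allowed only for eggs that developed an embryo"
            )

    @property
    def is_fertile(self) -> bool:
        return self.fate in FERTILE_FATES


def _day_offset(day: DayLike, origin: DayLike) -> int:
    if isinstance(day, _dt.date) and isinstance(origin, _dt.date):
        return (day - origin).days
    if isinstance(day, _dt.date) != isinstance(origin, _dt.date):
        raise ValidationError("lay dates and insemination day must share a type")
    return int(day) - int(origin)


@dataclass(frozen=True)
class FemaleSummary:
    """Aggregate metrics for one female; percentages are unrounded."""

    female_id: str
    n_laid: int
    n_eggs: int
    n_fertile_ai: int
    n_parthenote: int
    n_hatched_ai: int
    fertility_pct: Optional[float]
    hatchability_pct: Optional[float]
    first_fertile_day: Optional[int]
    last_fertile_day: Optional[int]
    fertility_duration_days: Optional[int]

    def rounded(self, ndigits: int = 1) -> "FemaleSummary":
        def r(x):
            return None if x is None else round_half_away(x, ndigits)

        return FemaleSummary(
            self.female_id,
            self.n_laid,
            self.n_eggs,
            self.n_fertile_ai,
            self.n_parthenote,
            self.n_hatched_ai,
            r(self.fertility_pct),
            r(self.hatchability_pct),
            self.first_fertile_day,
            self.last_fertile_day,
            self.fertility_duration_days,
        )


def summarize_female(
    events: Iterable[EggEvent],
    insemination_day: DayLike = 0,
    *,
    include_parthenotes: bool = False,
) -> FemaleSummary:
    """Summarize one female's oviposition record after insemination.

    Eggs laid before ``insemination_day`` are excluded.  With the default
    adjusted mode, parthenote-flagged eggs count toward the denominator but
    not toward fertility or hatchability numerators nor the fertile-day
    span; ``include_parthenotes=True`` gives the raw convention.
    """
    events = list(events)
    if not events:
        raise UsageError("summarize_female requires at least one event")
    females = {e.female_id for e in events}
    if len(females) != 1:
        raise ValidationError(f"events mix female ids: {sorted(females)}")
    (female_id,) = females

    offsets = [( _day_offset(e.lay_day, insemination_day), e) for e in events]
    offsets = [(d, e) for d, e in offsets if d >= 0]

    n_laid = len(offsets)
    non_wind = [(d, e) for d, e in offsets if e.fate is not Fate.WIND]
    n_eggs = len(non_wind)
    n_parthenote = sum(1 for _, e in non_wind if e.parthenote)

    def counts_for_ai(e: EggEvent) -> bool:
        return include_parthenotes or not e.parthenote

    fertile = [(d, e) for d, e in non_wind if e.is_fertile and counts_for_ai(e)]
    n_fertile_ai = len(fertile)
    n_hatched_ai = sum(1 for _, e in fertile if e.fate is Fate.HATCHED)

    if n_eggs:
        fertility_pct = 100.0 * n_fertile_ai / n_eggs
        hatchability_pct = 100.0 * n_hatched_ai / n_eggs
    else:
        fertility_pct = hatchability_pct = None

    if fertile:
        first = min(d for d, _ in fertile)
        last = max(d for d, _ in fertile)
        duration = last - first
    else:
        first = last = duration = None

    return FemaleSummary(
        female_id,
        n_laid,
        n_eggs,
        n_fertile_ai,
        n_parthenote,
        n_hatched_ai,
        fertility_pct,
        hatchability_pct,
        first,
        last,
        duration,
    )


@dataclass(frozen=True)
class CohortTotals:
    label: str
    n_females: int
    n_eggs: int
    n_fertile_ai: int
    n_hatchlings_ai: int
    pooled_fertility_pct: Optional[float]


def cohort_totals(
    summaries: Iterable[FemaleSummary],
    group_labels: Mapping[str, str],
) -> dict[str, CohortTotals]:
    """Pool per-female summaries into per-label totals.

    Pooled fertility is the ratio of summed fertile eggs to summed non-wind
    eggs within a label (not a mean of per-female percentages).
    """
    summaries = list(summaries)
    missing = [s.female_id for s in summaries if s.female_id not in group_labels]
    if missing:
        raise ValidationError(f"group_labels does not cover females: {missing}")
    out: dict[str, CohortTotals] = {}
    for label in dict.fromkeys(group_labels.values()):
        group = [s for s in summaries if group_labels[s.female_id] == label]
        n_eggs = sum(s.n_eggs for s in group)
        n_fertile = sum(s.n_fertile_ai for s in group)
        n_hatch = sum(s.n_hatched_ai for s in group)
        pooled = 100.0 * n_fertile / n_eggs if n_eggs else None
        out[label] = CohortTotals(label, len(group), n_eggs, n_fertile, n_hatch, pooled)
    return out


@dataclass(frozen=True)
class IncidenceResult:
    observed_pct: float
    max_pct: float
    pct_of_fertile: float


def incidence(
    confirmed_parthenotes: int,
    consistent_unconfirmed: int,
    ungenotyped_fertile: int,
    total_eggs: int,
    total_fertile: int,
    *,
    include_unconfirmed: bool = True,
) -> IncidenceResult:
    """Parthenogenesis incidence over an egg-laying cohort.

    ``observed_pct`` is the (optionally unconfirmed-inclusive) parthenote
    count over all non-wind eggs; ``max_pct`` additionally counts every
    ungenotyped fertile egg as a parthenote; ``pct_of_fertile`` uses the
    fertile-egg denominator.  Values are unrounded percentages.
    """
    counts = (
        confirmed_parthenotes,
        consistent_unconfirmed,
        ungenotyped_fertile,
        total_eggs,
        total_fertile,
    )
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be non-negative")
    if total_eggs == 0:
        raise UndefinedMetricError("incidence undefined for zero eggs")
    numerator = confirmed_parthenotes + (
        consistent_unconfirmed if include_unconfirmed else 0
    )
    if numerator + ungenotyped_fertile > total_fertile or total_fertile > total_eggs:
        raise ValidationError(
            "expected parthenotes + ungenotyped <= total_fertile <= total_eggs"
        )
    observed = 100.0 * numerator / total_eggs
    maximum = 100.0 * (numerator + ungenotyped_fertile) / total_eggs
    of_fertile = 100.0 * numerator / total_fertile if total_fertile else 0.0
    return IncidenceResult(observed, maximum, of_fertile)


# ---------------------------------------------------------------------------
# sperm morphometrics
# ---------------------------------------------------------------------------

MORPHO_COMPONENTS = ("head", "midpiece", "flagellum", "acrosome")
#: components whose per-cell sum defines the total length
TOTAL_COMPONENTS = ("head", "midpiece", "flagellum")


def morphometrics_summary(measurements) -> pd.DataFrame:
    """Mean and standard error per sperm component plus the per-cell total.

    ``measurements`` is a DataFrame (or records coercible to one) with one
    row per cell and the columns head, midpiece, flagellum and acrosome.
    The total is computed per cell as head + midpiece + flagellum and then
    summarized, so mean(total) equals the sum of the component means
    exactly.  SE is sample sd / sqrt(n) over all cells.
    """
    df = pd.DataFrame(measurements)
    missing = [c for c in MORPHO_COMPONENTS if c not in df.columns]
    if missing:
        raise ValidationError(f"measurements lack components: {missing}")
    if df[list(MORPHO_COMPONENTS)].isna().any().any():
        raise ValidationError("measurements contain missing component values")
    n = len(df)
    if n < 2:
        raise UsageError("morphometrics_summary requires at least two cells")
    work = df[list(MORPHO_COMPONENTS)].astype(float).copy()
    work["total"] = sum(work[c] for c in TOTAL_COMPONENTS)
    rows = []
    for comp in ("total", *MORPHO_COMPONENTS):
        x = work[comp].to_numpy()
        rows.append(
            {
                "component": comp,
                "n": n,
                "mean": float(np.mean(x)),
                "se": float(np.std(x, ddof=1) / np.sqrt(n)),
            }
        )
    return pd.DataFrame(rows).set_index("component")


# ---------------------------------------------------------------------------
# event-log IO
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("female_id", "lay_date", "pair_id", "fate", "offspring_id", "parthenote")


def _parse_day(token) -> DayLike:
    s = str(token).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return _dt.date.fromisoformat(s)
    except ValueError:
        raise ValidationError(
            f"lay_date {token!r} is neither an integer day nor an ISO-8601 date"
        ) from None


def read_event_log(path) -> list[EggEvent]:
    """Read a delimited oviposition log (ISO dates or integer day indexes)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = {"female_id", "lay_date", "fate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"event log must have columns {sorted(required)}, got {list(df.columns)}"
        )
    events = []
    for rec in df.to_dict("records"):
        flag = str(rec.get("parthenote", "")).strip().lower()
        events.append(
            EggEvent(
                female_id=str(rec["female_id"]).strip(),
                lay_day=_parse_day(rec["lay_date"]),
                fate=Fate(str(rec["fate"]).strip().lower()),
                pair_id=str(rec.get("pair_id", "")).strip() or None,
                offspring_id=str(rec.get("offspring_id", "")).strip() or None,
                parthenote={"true": True, "1": True, "false": False, "0": False}.get(
                    flag, None
                ),
            )
        )
    return events


def write_event_log(events: Sequence[EggEvent], path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "female_id": e.female_id,
                "lay_date": e.lay_day.isoformat()
                if isinstance(e.lay_day, _dt.date)
                else e.lay_day,
                "pair_id": e.pair_id or "",
                "fate": e.fate.value,
                "offspring_id": e.offspring_id or "",
                "parthenote": "" if e.parthenote is None else str(e.parthenote).lower(),
            }
        )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(Path(path), index=False)
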
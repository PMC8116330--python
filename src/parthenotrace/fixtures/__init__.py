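"""Loaders for the packaged golden fixtures (see ``fixtures/PROVENANCE.md``).

The fixtures ship the study's printed tables as plain text: the nine-locus
panel, 15 parthenote offspring genotypes, two known dam genotypes, the four
published maternal reconstructions, per-female insemination-trial outcomes,
sperm morphometric means, and the 48-female habitat egg-survey counts.
``build_trial_events`` expands the per-female trial counts into a concrete
event log whose summary statistics reproduce the printed percentages.
"""
from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ..genotypes_io import MultilocusGenotype, Panel, read_genotype_table
from ..repro_metrics import EggEvent, Fate

_PKG = "parthenotrace.fixtures"


def fixture_path(name: str) -> Path:
    return Path(str(resources.files(_PKG).joinpath(name)))


def load_panel() -> Panel:
    return Panel.from_yaml(fixture_path("panel.yaml"))


def load_parthenote_offspring() -> list[MultilocusGenotype]:
    """The 15 genotyped parthenote offspring (P1-P12, AI-P1-AI-P3)."""
    return read_genotype_table(
        fixture_path("table4_offspring.csv"), load_panel(), role="offspring"
    )


def load_habitat_parthenotes() -> list[MultilocusGenotype]:
    """The 12 parthenotes from the 48-female habitat (P1-P12)."""
    return [g for g in load_parthenote_offspring() if not g.individual_id.startswith("AI-")]


def load_known_dams() -> dict[str, MultilocusGenotype]:
    dams = read_genotype_table(fixture_path("table4_dams.csv"), load_panel(), role="dam")
    return {d.individual_id: d for d in dams}


def load_published_reconstructions() -> dict[str, MultilocusGenotype]:
    """The published 'Female 1'-'Female 4' reconstructed dam rows."""
    rows = read_genotype_table(
        fixture_path("table4_reconstructed.csv"), load_panel(), role="dam"
    )
    return {r.individual_id: r for r in rows}


#: published block membership of the habitat parthenotes
PUBLISHED_BLOCKS = {
    "Female 1": ("P1", "P2", "P3", "P4"),
    "Female 2": ("P5", "P6", "P7", "P8"),
    "Female 3": ("P10", "P11", "P9"),
    "Female 4": ("P12",),
}

#: dam of each parthenote laid after artificial insemination
AI_PARTHENOTE_DAMS = {"AI-P1": "854", "AI-P2": "307", "AI-P3": "307"}


def load_trials() -> pd.DataFrame:
    df = pd.read_csv(fixture_path("table3_trials.csv"), dtype={"female_id": str})
    return df.set_index("female_id", drop=False)


def trial_groups(trials: Optional[pd.DataFrame] = None) -> dict[str, str]:
    trials = load_trials() if trials is None else trials
    return dict(zip(trials["female_id"], trials["group"]))


def load_habitat_survey() -> dict:
    with open(fixture_path("habitat_survey.yaml")) as fh:
        return yaml.safe_load(fh)


def load_sperm_morphometrics() -> pd.DataFrame:
    return pd.read_csv(fixture_path("table2_sperm.csv")).set_index("component")


def _spread_days(first: int, last: int, n: int) -> list[int]:
    if n == 1:
        return [first]
    return [first + round(i * (last - first) / (n - 1)) for i in range(n)]


def build_trial_events(trials: Optional[pd.DataFrame] = None) -> dict[str, list[EggEvent]]:
    """Expand the per-female trial counts into per-female event logs.

    Lay days for eggs whose exact date was not printed are assigned
    deterministically; the fertile-day endpoints, all counts, and therefore
    every summary metric match the fixture row.  Day 0 is insemination.
    """
    trials = load_trials() if trials is None else trials
    logs: dict[str, list[EggEvent]] = {}
    for rec in trials.to_dict("records"):
        fid = rec["female_id"]
        events: list[EggEvent] = []
        n_fertile = int(rec["n_fertile_ai"])
        n_hatched = int(rec["n_hatched_ai"])
        if n_fertile:
            first = int(rec["first_fertile_day"])
            last = int(rec["last_fertile_day"])
            for i, day in enumerate(_spread_days(first, last, n_fertile)):
                fate = Fate.HATCHED if i < n_hatched else Fate.EMBRYO_DEATH
                events.append(
                    EggEvent(fid, day, fate, offspring_id=f"{fid}-F{i + 1}", parthenote=False)
                )
        p_days = str(rec["parthenote_days"]) if not _isna(rec["parthenote_days"]) else ""
        p_ids = str(rec["parthenote_ids"]) if not _isna(rec["parthenote_ids"]) else ""
        if p_days:
            for day, oid in zip(p_days.split(";"), p_ids.split(";")):
                events.append(
                    EggEvent(fid, int(day), Fate.HATCHED, offspring_id=oid, parthenote=True)
                )
        n_infertile = int(rec["n_eggs"]) - n_fertile - int(rec["n_parthenote"])
        for i in range(n_infertile):
            events.append(EggEvent(fid, 1 + i, Fate.INFERTILE))
        n_wind = int(rec["eggs_laid"]) - int(rec["n_eggs"])
        for i in range(n_wind):
            events.append(EggEvent(fid, 2 + i, Fate.WIND))
        logs[fid] = sorted(events, key=lambda e: (e.lay_day, e.fate.value))
    return logs


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or str(x) == "nan"


def synthetic_sperm_cells(
    n_cells: int = 50,
    means: Optional[dict[str, float]] = None,
    jitter: float = 0.5,
    seed=0,
) -> pd.DataFrame:
    """Per-cell measurement table whose component means are exact.

    Zero-sum jitter is added around each target mean so that sample means
    equal the targets to floating-point precision, letting additivity
    checks run against the published component means.
    """
    if means is None:
        fixture = load_sperm_morphometrics()
        means = {
            c: float(fixture.loc[c, "mean_um"])
            for c in ("head", "midpiece", "flagellum", "acrosome")
        }
    rng = np.random.default_rng(seed)
    data = {}
    for comp, mu in means.items():
        noise = rng.normal(0.0, jitter, size=n_cells)
        noise -= noise.mean()  # exact zero-sum
        data[comp] = mu + noise
    return pd.DataFrame(data)
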
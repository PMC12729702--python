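"""Seedling-emergence metrics from daily count series.

Three per-replicate quantities summarize an emergence test in which
``seeds_sown`` propagules are sown and newly emerged seedlings are counted
daily over an observation window (90 days in the umbu trials):

* emergence percentage  SE = 100 * sum_i n_i / seeds_sown,
* Maguire's emergence speed index  ESI = sum_i n_i / t_i,
* Edmond–Drapalla mean emergence time  MET = sum_i n_i t_i / sum_i n_i,

with n_i the count newly emerged on day t_i after sowing.  MET is undefined
for replicates with zero emergence; such replicates contribute SE = 0 and
ESI = 0 to genotype means but are excluded from the MET mean (the exclusion
is recorded on the result).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmergenceCounts",
    "read_emergence_counts",
    "emergence_percent",
    "maguire_esi",
    "mean_emergence_time",
    "replicate_metrics",
    "genotype_emergence_traits",
]

REQUIRED_COLUMNS = ("genotype", "replicate", "day", "emerged", "sown")


@dataclasses.dataclass(frozen=True)
class EmergenceCounts:
    """Daily newly-emerged counts for one replicate."""

    genotype: str
    replicate: int
    days: tuple[int, ...]
    emerged: tuple[int, ...]
    seeds_sown: int
    window: int = 90

    def __post_init__(self) -> None:
        days = np.asarray(self.days)
        counts = np.asarray(self.emerged)
        if self.seeds_sown <= 0:
            raise ValueError("seeds_sown must be positive")
        if days.size != counts.size:
            raise ValueError("days and emerged must have equal length")
        if days.size and (np.any(np.diff(days) <= 0) or days[0] < 1):
            raise ValueError("days must be strictly increasing integers >= 1")
        if days.size and days[-1] > self.window:
            raise ValueError(f"day {int(days[-1])} beyond the "
                             f"{self.window}-day window")
        if np.any(counts < 0):
            raise ValueError("emerged counts must be non-negative")
        if counts.sum() > self.seeds_sown:
            raise ValueError("total emerged exceeds seeds sown")


def emergence_percent(counts: EmergenceCounts) -> float:
    """SE: final emergence as a percentage of seeds sown."""
    return 100.0 * sum(counts.emerged) / counts.seeds_sown


def maguire_esi(counts: EmergenceCounts) -> float:
    """Maguire's emergence speed index: sum of n_i / t_i."""
    return float(sum(n / t for n, t in zip(counts.emerged, counts.days)))


def mean_emergence_time(counts: EmergenceCounts) -> float:
    """Edmond–Drapalla MET: count-weighted mean emergence day.

    Returns NaN when nothing emerged.
    """
    total = sum(counts.emerged)
    if total == 0:
        return float("nan")
    return float(sum(n * t for n, t in zip(counts.emerged, counts.days)) / total)


def read_emergence_counts(path: str | Path, cumulative: bool = False,
                          window: int = 90) -> list[EmergenceCounts]:
    """Read a daily-count CSV (genotype, replicate, day, emerged, sown).

    ``cumulative=True`` interprets the counts as running totals and
    differences them to daily new emergences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"emergence file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path.name}")
    out: list[EmergenceCounts] = []
    for (gen, rep), grp in df.groupby(["genotype", "replicate"], sort=False):
        grp = grp.sort_values("day")
        counts = grp["emerged"].to_numpy(dtype=int)
        if cumulative:
            counts = np.diff(counts, prepend=0)
        sown = grp["sown"].to_numpy()
        if len(set(sown)) != 1:
            raise ValueError(f"inconsistent seeds_sown for ({gen}, {rep})")
        out.append(EmergenceCounts(
            genotype=str(gen), replicate=int(rep),
            days=tuple(int(d) for d in grp["day"]),
            emerged=tuple(int(c) for c in counts),
            seeds_sown=int(sown[0]), window=window,
        ))
    return out


def replicate_metrics(records: Sequence[EmergenceCounts]) -> pd.DataFrame:
    """Per-replicate SE / ESI / MET table."""
    rows = [
        {
            "genotype": rec.genotype,
            "replicate": rec.replicate,
            "SE": emergence_percent(rec),
            "ESI": maguire_esi(rec),
            "MET": mean_emergence_time(rec),
        }
        for rec in records
    ]
    return pd.DataFrame(rows)


def genotype_emergence_traits(records: Sequence[EmergenceCounts]) -> pd.DataFrame:
    """Genotype-mean SE / ESI / MET, excluding undefined MET replicates.

    The returned frame carries an ``n_met`` column with the number of
    replicates that contributed to each MET mean, so exclusions are visible.
    """
    per_rep = replicate_metrics(records)
    grouped = per_rep.groupby("genotype", sort=False)
    out = grouped[["SE", "ESI"]].mean()
    out["MET"] = grouped["MET"].mean()  # pandas mean skips NaN
    out["n_met"] = grouped["MET"].count()
    return out.reset_index()
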
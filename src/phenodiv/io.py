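"""Data model and file I/O for replicate-level phenotype tables.

The central container is :class:`PhenotypeTable`, a validated wrapper around a
tidy :class:`pandas.DataFrame` holding one row per (genotype, replicate) in a
balanced completely randomized design (CRD).  Every downstream computation —
ANOVA, genetic parameters, distances, clustering — consumes either this table
or the genotype-mean matrix derived from it by :func:`genotype_means`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TRAITS",
    "PhenotypeTable",
    "MeansMatrix",
    "PhenotypeFormatError",
    "BalanceError",
    "read_phenotype_table",
    "write_phenotype_table",
    "genotype_means",
    "write_means_matrix",
]

#: Default trait set for umbu (Spondias tuberosa) diaspore characterization:
#: fruit length/diameter/fresh mass (mm, mm, g), endocarp length/width/
#: thickness/mass (mm, mm, mm, g), seedling emergence (%), emergence speed
#: index, and mean emergence time (days).
DEFAULT_TRAITS: tuple[str, ...] = (
    "FL", "FD", "FFM", "EL", "EW", "ET", "EM", "SE", "ESI", "MET",
)

#: Significant digits used when writing tables; wide enough that a
#: write-then-read round trip preserves float64 values.
_FLOAT_FMT = "%.12g"


class PhenotypeFormatError(ValueError):
    """Malformed phenotype file: missing columns or non-numeric cells."""


class BalanceError(ValueError):
    """Design is not balanced: genotypes differ in replicate count."""


@dataclasses.dataclass(frozen=True)
class PhenotypeTable:
    """Replicate-level measurements in a balanced CRD.

    Parameters
    ----------
    data:
        Tidy frame with columns ``genotype``, ``replicate``, optionally
        ``population``, and one numeric column per trait.
    traits:
        Ordered trait column names.
    """

    data: pd.DataFrame
    traits: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.data
        for col in ("genotype", "replicate"):
            if col not in df.columns:
                raise PhenotypeFormatError(f"missing required column {col!r}")
        for trait in self.traits:
            if trait not in df.columns:
                raise PhenotypeFormatError(f"missing trait column {trait!r}")
            values = df[trait].to_numpy()
            if not np.issubdtype(values.dtype, np.number):
                bad = df.index[pd.to_numeric(df[trait], errors="coerce").isna()]
                row = int(bad[0]) if len(bad) else -1
                raise PhenotypeFormatError(
                    f"non-numeric value in trait {trait!r} at row {row}"
                )
            if not np.all(np.isfinite(values.astype(float))):
                raise PhenotypeFormatError(
                    f"non-finite value in trait {trait!r}"
                )
        dup = df.duplicated(subset=["genotype", "replicate"])
        if dup.any():
            pairs = df.loc[dup, ["genotype", "replicate"]].to_records(index=False)
            raise PhenotypeFormatError(
                f"duplicated (genotype, replicate) pairs: {list(pairs)[:5]}"
            )
        counts = df.groupby("genotype", sort=False).size()
        if counts.nunique() != 1:
            k_mode = int(counts.mode().iloc[0])
            offenders = sorted(counts.index[counts != k_mode].astype(str))
            raise BalanceError(
                "unbalanced design: genotypes with replicate count != "
                f"{k_mode}: {offenders}"
            )
        if int(counts.iloc[0]) < 2:
            raise BalanceError("need at least k=2 replicates per genotype")

    @property
    def genotypes(self) -> list[str]:
        """Genotype labels in first-appearance order."""
        return list(dict.fromkeys(self.data["genotype"].astype(str)))

    @property
    def g(self) -> int:
        return self.data["genotype"].nunique()

    @property
    def k(self) -> int:
        return int(self.data.groupby("genotype").size().iloc[0])

    def trait_matrix(self) -> pd.DataFrame:
        """Replicate-level (g*k) x p trait value frame."""
        return self.data[list(self.traits)].astype(float)


@dataclasses.dataclass(frozen=True)
class MeansMatrix:
    """Genotype x trait matrix of replicate means, carrying the replicate
    count ``k`` used to form them (needed by the genetic-parameter and
    distance formulas)."""

    means: pd.DataFrame  # index: genotype, columns: traits
    k: int

    @property
    def genotypes(self) -> list[str]:
        return list(self.means.index.astype(str))

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.means.columns)

    def values(self) -> np.ndarray:
        return self.means.to_numpy(dtype=float)


def read_phenotype_table(
    path: str | Path,
    trait_names: Sequence[str] | None = None,
    decimal: str = ".",
) -> PhenotypeTable:
    """Read a replicate-level phenotype CSV.

    The file must carry ``genotype`` and ``replicate`` columns plus one
    column per trait; ``population`` is optional.  ``decimal`` selects the
    decimal separator (``","`` for Brazilian-format files); it is never
    guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, decimal=decimal)
    df.columns = [str(c).strip() for c in df.columns]
    if trait_names is None:
        reserved = {"genotype", "replicate", "population"}
        trait_names = [c for c in df.columns if c not in reserved]
    missing = [c for c in ("genotype", "replicate", *trait_names)
               if c not in df.columns]
    if missing:
        raise PhenotypeFormatError(
            f"missing column(s) {missing} in {path.name}"
        )
    for trait in trait_names:
        coerced = pd.to_numeric(df[trait], errors="coerce")
        bad = coerced.isna() & df[trait].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            raise PhenotypeFormatError(
                f"non-numeric value {df.loc[bad, trait].iloc[0]!r} in trait "
                f"{trait!r} at file line {int(bad.idxmax()) + 2}"
            )
        df[trait] = coerced
    df["genotype"] = df["genotype"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    return PhenotypeTable(data=df, traits=tuple(trait_names))


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    """Write a phenotype table as CSV at full round-trip precision."""
    cols = ["genotype", "replicate"]
    if "population" in table.data.columns:
        cols.append("population")
    cols += list(table.traits)
    table.data[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def genotype_means(table: PhenotypeTable) -> MeansMatrix:
    """Average the k replicates of each genotype for every trait.

    Row order follows first appearance in the table; the result is invariant
    to any permutation of the input rows.
    """
    means = (
        table.data.groupby("genotype", sort=False)[list(table.traits)]
        .mean()
        .loc[table.genotypes]
    )
    return MeansMatrix(means=means, k=table.k)


def write_means_matrix(means: MeansMatrix, path: str | Path) -> None:
    out = means.means.copy()
    out.insert(0, "k", means.k)
    out.to_csv(path, index_label="genotype", float_format=_FLOAT_FMT)
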
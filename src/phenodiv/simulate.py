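"""Synthetic phenotype and emergence data with known ground truth.

The generator runs the one-way CRD model ``Y_ij = mu + G_i + e_ij`` forward:
genotype effect vectors G_i are drawn from a zero-mean multivariate normal
whose covariance combines per-trait genetic variances with a genetic
correlation matrix, and residuals e_ij likewise from the environmental
covariance.  Genetic variances are set from target broad-sense
heritabilities by inverting the expected-mean-squares algebra,

    sigma_g^2 = h2 * sigma_e^2 / (k * (1 - h2)),

so that the ANOVA estimator ``h2_hat = (QMg - QMr)/QMg`` is centered on the
target.  Defaults emulate a balanced umbu diaspore trial: 38 genotypes from
three populations (13 + 8 + 17), 4 replicates, the ten standard traits with
grand means, residual variances and heritabilities in the ranges reported
for such trials (h2 from 63% to 98.5%), and the reported phenotypic
correlation structure as the default genetic correlation matrix.

Emergence counts are simulated per replicate as binomial(seeds sown,
genotype emergence probability); emergence days follow a lognormal timing
distribution (median 40 days by default) truncated at the 90-day window and
binned to integer days.

Randomness is organized in deterministically derived sub-streams keyed by
(seed, role, genotype[, replicate]); standard-normal draws are made
trait-by-trait and mixed through the Cholesky factor, so appending a trait
never perturbs the values generated for existing ones.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DEFAULT_TRAITS, PhenotypeTable
from .emergence import EmergenceCounts

__all__ = [
    "TraitSpec",
    "EmergenceSpec",
    "SimulationConfig",
    "sigma_g_for_h2",
    "simulate_phenotypes",
    "simulate_emergence",
]


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """Per-trait ground truth: grand mean, target h2, residual variance."""

    mean: float
    h2: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")


@dataclasses.dataclass(frozen=True)
class EmergenceSpec:
    """Emergence-test kinetics: per-genotype final-emergence probability
    range, lognormal timing (median in days, log-sd), window and sowing."""

    p_range: tuple[float, float] = (0.05, 0.75)
    timing_median_days: float = 40.0
    timing_log_sd: float = 0.35
    window_days: int = 90
    seeds_sown: int = 25


def _default_traits() -> dict[str, TraitSpec]:
    # grand means near the reported population medians; residual variances
    # and heritabilities matching the reported per-trait ANOVA summaries
    return {
        "FL": TraitSpec(34.0, 0.9851, 0.55),
        "FD": TraitSpec(31.0, 0.9770, 0.65),
        "FFM": TraitSpec(20.0, 0.9757, 1.81),
        "EL": TraitSpec(20.0, 0.9560, 0.41),
        "EW": TraitSpec(14.0, 0.9496, 0.27),
        "ET": TraitSpec(11.0, 0.9232, 0.24),
        "EM": TraitSpec(1.15, 0.9600, 0.01),
        "SE": TraitSpec(23.4, 0.9063, 99.40),
        "ESI": TraitSpec(0.21, 0.9179, 0.01),
        "MET": TraitSpec(44.8, 0.6310, 265.81),
    }


# Reported phenotypic correlations among the ten diaspore traits, used as
# the default genetic correlation matrix (positive definite as given;
# smallest eigenvalue ~0.016).
_DEFAULT_CORR = {
    ("FL", "FD"): 0.911, ("FL", "FFM"): 0.902, ("FL", "EL"): 0.766,
    ("FL", "EW"): 0.252, ("FL", "ET"): 0.161, ("FL", "EM"): 0.408,
    ("FL", "SE"): 0.414, ("FL", "ESI"): 0.397, ("FL", "MET"): 0.059,
    ("FD", "FFM"): 0.951, ("FD", "EL"): 0.720, ("FD", "EW"): 0.492,
    ("FD", "ET"): 0.368, ("FD", "EM"): 0.514, ("FD", "SE"): 0.279,
    ("FD", "ESI"): 0.255, ("FD", "MET"): 0.110,
    ("FFM", "EL"): 0.720, ("FFM", "EW"): 0.432, ("FFM", "ET"): 0.329,
    ("FFM", "EM"): 0.468, ("FFM", "SE"): 0.267, ("FFM", "ESI"): 0.254,
    ("FFM", "MET"): 0.107,
    ("EL", "EW"): 0.585, ("EL", "ET"): 0.608, ("EL", "EM"): 0.680,
    ("EL", "SE"): 0.412, ("EL", "ESI"): 0.419, ("EL", "MET"): -0.071,
    ("EW", "ET"): 0.882, ("EW", "EM"): 0.697, ("EW", "SE"): 0.176,
    ("EW", "ESI"): 0.134, ("EW", "MET"): 0.115,
    ("ET", "EM"): 0.692, ("ET", "SE"): 0.116, ("ET", "ESI"): 0.143,
    ("ET", "MET"): -0.090,
    ("EM", "SE"): 0.329, ("EM", "ESI"): 0.326, ("EM", "MET"): -0.056,
    ("SE", "ESI"): 0.920, ("SE", "MET"): -0.030,
    ("ESI", "MET"): -0.332,
}


def default_genetic_correlations(traits: Sequence[str] = DEFAULT_TRAITS) -> pd.DataFrame:
    r = np.eye(len(traits))
    index = {t: i for i, t in enumerate(traits)}
    for (a, b), v in _DEFAULT_CORR.items():
        if a in index and b in index:
            r[index[a], index[b]] = r[index[b], index[a]] = v
    return pd.DataFrame(r, index=list(traits), columns=list(traits))


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of a simulated balanced CRD trial."""

    g: int = 38
    k: int = 4
    populations: tuple[tuple[str, int], ...] = (
        ("SJ_Mata", 13), ("AJ", 8), ("BV", 17),
    )
    traits: Mapping[str, TraitSpec] = dataclasses.field(
        default_factory=_default_traits)
    genetic_correlations: pd.DataFrame | None = None
    env_correlations: pd.DataFrame | None = None
    population_shift: Mapping[str, Mapping[str, float]] | None = None
    emergence: EmergenceSpec = dataclasses.field(default_factory=EmergenceSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 2 or self.k < 2:
            raise ValueError("need g >= 2 and k >= 2")
        if sum(n for _, n in self.populations) != self.g:
            raise ValueError("population sizes must sum to g")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.traits)

    def population_of(self, genotype_index: int) -> str:
        i = genotype_index
        for name, n in self.populations:
            if i < n:
                return name
            i -= n
        raise IndexError(genotype_index)


def sigma_g_for_h2(h2: float, sigma2_e: float, k: int) -> float:
    """Genetic variance giving an expected ANOVA h2 equal to the target.

    Inverts h2 = k*sigma_g^2 / (k*sigma_g^2 + sigma_e^2).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    return h2 * sigma2_e / (k * (1.0 - h2))


def _covariance(sds: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return corr * np.outer(sds, sds)


def _cholesky_pd(matrix: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{what} matrix is not positive definite") from exc


def _corr_array(corr: pd.DataFrame | None, traits: Sequence[str]) -> np.ndarray:
    if corr is None:
        return np.eye(len(traits))
    arr = corr.loc[list(traits), list(traits)].to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("correlation matrix must be symmetric")
    return arr


def simulate_phenotypes(config: SimulationConfig) -> PhenotypeTable:
    """Draw a replicate-level phenotype table from the configured model.

    Fully reproducible from ``config.seed``; genotype effects and residuals
    come from sub-streams keyed (seed, role, genotype[, replicate]).
    """
    traits = list(config.trait_names)
    p = len(traits)
    specs = [config.traits[t] for t in traits]
    mu = np.array([s.mean for s in specs])
    sg = np.sqrt([sigma_g_for_h2(s.h2, s.sigma2_e, config.k) for s in specs])
    se = np.sqrt([s.sigma2_e for s in specs])
    rg = _corr_array(config.genetic_correlations, traits)
    re_ = _corr_array(config.env_correlations, traits)
    lg = _cholesky_pd(_covariance(sg, rg), "genetic correlation") \
        if np.any(sg > 0) else np.zeros((p, p))
    le = _cholesky_pd(_covariance(se, re_), "environmental correlation")
    rows = []
    for i in range(config.g):
        pop = config.population_of(i)
        zg = np.random.default_rng([config.seed, 0, i]).standard_normal(p)
        effect = lg @ zg
        shift = np.zeros(p)
        if config.population_shift and pop in config.population_shift:
            for t, delta in config.population_shift[pop].items():
                shift[traits.index(t)] = delta
        for j in range(config.k):
            ze = np.random.default_rng(
                [config.seed, 1, i, j]).standard_normal(p)
            y = mu + shift + effect + le @ ze
            rows.append({
                "genotype": str(i + 1), "replicate": j + 1,
                "population": pop,
                **{t: y[ti] for ti, t in enumerate(traits)},
            })
    return PhenotypeTable(data=pd.DataFrame(rows), traits=tuple(traits))


def simulate_emergence(config: SimulationConfig) -> list[EmergenceCounts]:
    """Draw daily emergence counts for every genotype x replicate."""
    spec = config.emergence
    lo, hi = spec.p_range
    mu_log = np.log(spec.timing_median_days)
    records = []
    for i in range(config.g):
        p_i = float(np.random.default_rng(
            [config.seed, 2, i]).uniform(lo, hi))
        for j in range(config.k):
            rng = np.random.default_rng([config.seed, 3, i, j])
            emerged = int(rng.binomial(spec.seeds_sown, p_i))
            day_counts: dict[int, int] = {}
            for _ in range(emerged):
                # rejection-sample the truncated lognormal
                for _attempt in range(1000):
                    t = float(rng.lognormal(mu_log, spec.timing_log_sd))
                    if t <= spec.window_days:
                        break
                day = max(1, min(spec.window_days, int(np.ceil(t))))
                day_counts[day] = day_counts.get(day, 0) + 1
            days = tuple(sorted(day_counts))
            records.append(EmergenceCounts(
                genotype=str(i + 1), replicate=j + 1, days=days,
                emerged=tuple(day_counts[d] for d in days),
                seeds_sown=spec.seeds_sown, window=spec.window_days,
            ))
    return records


def emergence_to_frame(records: Sequence[EmergenceCounts]) -> pd.DataFrame:
    """Long-format daily-count frame (the on-disk CSV layout)."""
    rows = [
        {"genotype": r.genotype, "replicate": r.replicate, "day": d,
         "emerged": n, "sown": r.seeds_sown}
        for r in records
        for d, n in zip(r.days, r.emerged)
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "replicate", "day", "emerged", "sown"])
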
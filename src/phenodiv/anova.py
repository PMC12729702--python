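"""One-way CRD ANOVA, genetic-parameter estimators, and Pearson correlations.

For a balanced completely randomized design with g genotypes and k replicates
under the model ``Y_ij = mu + G_i + e_ij``, the genotype and residual mean
squares (QMg, QMr) carry expectations ``E[QMg] = k*sigma_g^2 + sigma_e^2`` and
``E[QMr] = sigma_e^2``.  The moment estimators implemented here follow the
standard quantitative-genetics decomposition:

    sigma_f^2 = QMg / k          (phenotypic variance of a genotype mean)
    sigma_e^2 = QMr / k          (environmental variance of a genotype mean)
    sigma_g^2 = (QMg - QMr) / k  (genetic variance)
    h^2       = sigma_g^2 / sigma_f^2 = (QMg - QMr) / QMg   (broad sense)
    CVg       = 100 * sqrt(sigma_g^2) / m
    CVe = CV  = 100 * sqrt(QMr) / m   (experimental coefficient of variation)
    CVg/CVe   = sqrt((QMg - QMr) / (k * QMr))

Note the CVe convention: the environmental coefficient of variation uses the
replicate-level residual standard deviation sqrt(QMr), not sqrt(QMr/k); this
is the convention under which the ratio CVg/CVe equals
sqrt((QMg-QMr)/(k*QMr)) and coincides with the experiment-wide CV.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import MeansMatrix, PhenotypeTable

__all__ = [
    "TraitAnova",
    "GeneticParams",
    "CorrelationMatrix",
    "anova_crd",
    "genetic_parameters",
    "genetic_parameters_from_ms",
    "pearson_matrix",
    "significance_code",
]


def significance_code(p: float, alpha: float = 0.05, alpha_strong: float = 0.01) -> str:
    """Star convention: '**' below 1%, '*' below 5%, 'ns' otherwise."""
    if p < alpha_strong:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


@dataclasses.dataclass(frozen=True)
class TraitAnova:
    """One-way ANOVA decomposition for a single trait."""

    trait: str
    ss_genotype: float
    ss_residual: float
    ss_total: float
    df_genotype: int
    df_residual: int
    qm_g: float
    qm_r: float
    f_value: float
    p_value: float
    significance: str
    grand_mean: float
    k: int
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class GeneticParams:
    """Variance components and derived genetic parameters for one trait.

    ``sigma2_g`` is reported as computed even when negative (QMg < QMr);
    ``h2_percent`` is then floored at 0 and ``negative_variance_flag`` set,
    so estimator bias remains observable in simulation studies.
    """

    trait: str
    sigma2_f: float
    sigma2_e: float
    sigma2_g: float
    h2_percent: float
    cvg_percent: float
    cve_percent: float
    cv_percent: float
    cvg_over_cve: float
    grand_mean: float
    negative_variance_flag: bool


@dataclasses.dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations among traits with per-pair significance."""

    r: pd.DataFrame
    p: pd.DataFrame
    codes: pd.DataFrame
    n: int
    undefined_traits: tuple[str, ...] = ()


def anova_crd(table: PhenotypeTable, trait: str) -> TraitAnova:
    """One-way completely-randomized ANOVA for ``trait``.

    p-values come from the F distribution with (g-1, g(k-1)) degrees of
    freedom.  A zero residual mean square yields F = +inf with p = 0 and a
    degenerate-input warning.
    """
    if trait not in table.traits:
        raise KeyError(f"unknown trait {trait!r}")
    y = table.data[trait].astype(float)
    groups = table.data["genotype"]
    g, k = table.g, table.k
    if g < 2:
        raise ValueError("ANOVA requires at least 2 genotypes")
    grand = float(y.mean())
    means = y.groupby(groups).transform("mean")
    ss_g = float(((means - grand) ** 2).sum())
    ss_e = float(((y - means) ** 2).sum())
    ss_t = float(((y - grand) ** 2).sum())
    df_g, df_e = g - 1, g * (k - 1)
    qm_g, qm_r = ss_g / df_g, ss_e / df_e
    degenerate = False
    if qm_r > 0:
        f = qm_g / qm_r
        p = float(stats.f.sf(f, df_g, df_e))
    else:
        degenerate = True
        if qm_g > 0:
            f, p = math.inf, 0.0
        else:  # all values identical
            f, p = float("nan"), 1.0
        warnings.warn(
            f"degenerate ANOVA input for trait {trait!r}: zero residual "
            "mean square",
            stacklevel=2,
        )
    return TraitAnova(
        trait=trait, ss_genotype=ss_g, ss_residual=ss_e, ss_total=ss_t,
        df_genotype=df_g, df_residual=df_e, qm_g=qm_g, qm_r=qm_r,
        f_value=f, p_value=p, significance=significance_code(p),
        grand_mean=grand, k=k, degenerate=degenerate,
    )


def genetic_parameters_from_ms(
    qm_g: float,
    qm_r: float,
    k: int,
    m: float | None = None,
    trait: str = "",
) -> GeneticParams:
    """Genetic parameters straight from mean squares.

    Accepts printed ANOVA summaries (QMg, QMr, k) so published tables can be
    re-derived without replicate-level data.  The grand mean ``m`` is only
    needed for the CV quantities; when omitted they are reported as NaN.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if qm_g < 0 or qm_r < 0:
        raise ValueError("mean squares must be non-negative")
    sigma2_f = qm_g / k
    sigma2_e = qm_r / k
    sigma2_g = (qm_g - qm_r) / k
    negative = sigma2_g < 0
    h2 = 0.0 if negative or qm_g == 0 else 100.0 * (qm_g - qm_r) / qm_g
    if qm_r > 0:
        ratio = 0.0 if negative else math.sqrt((qm_g - qm_r) / (k * qm_r))
    else:
        ratio = math.inf if qm_g > 0 else 0.0
    if m is None or m == 0:
        if m == 0:
            warnings.warn("zero grand mean: CV quantities undefined", stacklevel=2)
        cvg = cve = cv = float("nan")
        m_out = float("nan") if m is None else 0.0
    else:
        cvg = 100.0 * math.sqrt(max(sigma2_g, 0.0)) / abs(m)
        cve = cv = 100.0 * math.sqrt(qm_r) / abs(m)
        m_out = float(m)
    return GeneticParams(
        trait=trait, sigma2_f=sigma2_f, sigma2_e=sigma2_e, sigma2_g=sigma2_g,
        h2_percent=h2, cvg_percent=cvg, cve_percent=cve, cv_percent=cv,
        cvg_over_cve=ratio, grand_mean=m_out, negative_variance_flag=negative,
    )


def genetic_parameters(anova: TraitAnova, m: float | None = None,
                       k: int | None = None) -> GeneticParams:
    """Genetic parameters from a fitted :class:`TraitAnova`."""
    return genetic_parameters_from_ms(
        anova.qm_g, anova.qm_r,
        k if k is not None else anova.k,
        m if m is not None else anova.grand_mean,
        trait=anova.trait,
    )


def pearson_matrix(means: MeansMatrix) -> CorrelationMatrix:
    """Pearson correlation matrix across genotype means.

    r = cov(x, y) / (s_x s_y); two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2)
    on n-2 df, with n the number of genotypes.  Zero-variance traits yield
    undefined (NaN) rows/columns flagged in ``undefined_traits`` and marked
    'ns' nowhere (code left empty).
    """
    x = means.values()
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 genotypes for correlations")
    sd = x.std(axis=0, ddof=1)
    constant = [t for t, s in zip(means.traits, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * math.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    pval = 2.0 * stats.t.sf(np.abs(t), n - 2)
    pval = np.where(np.isclose(np.abs(r), 1.0), 0.0, pval)
    np.fill_diagonal(pval, 0.0)
    traits = list(means.traits)
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(pval, index=traits, columns=traits)
    codes = p_df.map(lambda q: "" if np.isnan(q) else significance_code(q))
    for tname in constant:
        r_df.loc[tname, :] = r_df.loc[:, tname] = np.nan
        r_df.loc[tname, tname] = 1.0
        p_df.loc[tname, :] = p_df.loc[:, tname] = np.nan
        codes.loc[tname, :] = codes.loc[:, tname] = ""
    return CorrelationMatrix(
        r=r_df, p=p_df, codes=codes, n=n, undefined_traits=tuple(constant)
    )
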
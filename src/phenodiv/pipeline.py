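"""End-to-end divergence pipeline with a structured report.

Stages: (optional) emergence metrics -> phenotype table -> per-trait ANOVA
and genetic parameters -> Scott-Knott letters -> pooled covariance and
distance matrices -> Tocher and UPGMA/Mojena clustering -> Singh importance
and canonical variates -> Pearson correlations.  Every stage's output is
written as CSV (plus Newick for the dendrogram) and collected into a single
JSON report with a provenance block (input hashes, config echo, seed,
package version).  Given identical inputs and seed the report is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .anova import anova_crd, genetic_parameters, pearson_matrix
from .divergence import (mahalanobis_matrix, pooled_residual_covariance,
                         standardized_euclidean_matrix)
from .emergence import read_emergence_counts, replicate_metrics
from .importance import canonical_variates, singh_contributions
from .io import (PhenotypeTable, genotype_means, read_phenotype_table,
                 write_means_matrix, write_phenotype_table)
from .scott_knott import scott_knott
from .simulate import (EmergenceSpec, SimulationConfig, TraitSpec,
                       default_genetic_correlations, emergence_to_frame,
                       simulate_emergence, simulate_phenotypes)
from .tocher import tocher_cluster
from .upgma import mojena_cut, to_newick, upgma_tree

__all__ = ["PipelineReport", "run_pipeline", "build_simulation_config"]

_FLOAT_FMT = "%.12g"


@dataclasses.dataclass(frozen=True)
class PipelineReport:
    sections: dict[str, Any]
    out_dir: Path

    def to_json(self) -> str:
        return json.dumps(self.sections, indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_simulation_config(block: Mapping[str, Any]) -> SimulationConfig:
    """SimulationConfig from a plain config mapping (YAML-friendly)."""
    kwargs: dict[str, Any] = {}
    for key in ("g", "k", "seed"):
        if key in block:
            kwargs[key] = int(block[key])
    if "populations" in block:
        kwargs["populations"] = tuple(
            (str(name), int(n)) for name, n in block["populations"])
    if "traits" in block:
        kwargs["traits"] = {
            str(name): TraitSpec(**{k: float(v) for k, v in spec.items()})
            for name, spec in block["traits"].items()
        }
    if block.get("genetic_correlations") == "default":
        names = tuple(kwargs.get("traits", _default_names(kwargs)))
        kwargs["genetic_correlations"] = default_genetic_correlations(names)
    elif "genetic_correlations" in block:
        kwargs["genetic_correlations"] = pd.DataFrame(
            block["genetic_correlations"])
    if "emergence" in block:
        e = dict(block["emergence"])
        if "p_range" in e:
            e["p_range"] = tuple(float(v) for v in e["p_range"])
        kwargs["emergence"] = EmergenceSpec(**e)
    return SimulationConfig(**kwargs)


def _default_names(kwargs):
    from .io import DEFAULT_TRAITS
    return kwargs["traits"].keys() if "traits" in kwargs else DEFAULT_TRAITS


def run_pipeline(config: Mapping[str, Any] | str | Path) -> PipelineReport:
    """Run the full analysis described by ``config``.

    ``config`` is a mapping (or path to a YAML file) with either a
    ``simulate`` block or an ``input`` phenotype CSV path, plus optional
    ``emergence`` counts path, ``traits`` list, ``alpha``, ``distance``
    (``mahalanobis`` or ``euclidean-std`` for Tocher), ``mojena_c``,
    ``decimal`` and ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        import yaml

        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    cfg = dict(config)
    out_dir = Path(cfg.get("out_dir", "phenodiv_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("alpha", 0.05))
    tocher_metric = str(cfg.get("distance", "mahalanobis"))
    mojena_c = float(cfg.get("mojena_c", 1.25))
    provenance: dict[str, Any] = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()
                   if k not in ("genetic_correlations",)},
        "input_hashes": {},
    }
    notes: list[str] = []

    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim = build_simulation_config(cfg["simulate"])
        provenance["seed"] = sim.seed
        table = simulate_phenotypes(sim)
        write_phenotype_table(table, out_dir / "phenotypes.csv")
        emergence_records = simulate_emergence(sim)
        emergence_to_frame(emergence_records).to_csv(
            out_dir / "emergence_counts.csv", index=False)
    elif "input" in cfg:
        in_path = Path(cfg["input"])
        if not in_path.exists():
            raise FileNotFoundError(f"input file not found: {in_path}")
        provenance["input_hashes"][str(in_path)] = _sha256(in_path)
        table = read_phenotype_table(
            in_path, cfg.get("traits"),
            decimal="," if cfg.get("decimal") == "comma" else ".")
        emergence_records = None
        if cfg.get("emergence"):
            e_path = Path(cfg["emergence"])
            provenance["input_hashes"][str(e_path)] = _sha256(e_path)
            emergence_records = read_emergence_counts(e_path)
    else:
        raise ValueError("config needs either a 'simulate' block or 'input'")

    sections: dict[str, Any] = {"provenance": provenance, "notes": notes}

    # --- emergence metrics ------------------------------------------------
    if emergence_records:
        per_rep = replicate_metrics(emergence_records)
        per_rep.to_csv(out_dir / "emergence_metrics.csv", index=False,
                       float_format=_FLOAT_FMT)
        table = _merge_emergence(table, per_rep, notes)
        sections["emergence"] = {
            "n_replicates": len(emergence_records),
            "mean_SE": float(per_rep["SE"].mean()),
            "mean_ESI": float(per_rep["ESI"].mean()),
            "mean_MET": float(per_rep["MET"].mean(skipna=True)),
        }

    means = genotype_means(table)
    write_means_matrix(means, out_dir / "genotype_means.csv")

    # --- ANOVA + genetic parameters + Scott-Knott -------------------------
    anova_rows, sk_rows = [], []
    anovas = {}
    for trait in table.traits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            av = anova_crd(table, trait)
        gp = genetic_parameters(av)
        anovas[trait] = av
        anova_rows.append({
            "trait": trait, "QMg": av.qm_g, "QMr": av.qm_r, "F": av.f_value,
            "p_value": av.p_value, "significance": av.significance,
            "h2_percent": gp.h2_percent, "CVg_percent": gp.cvg_percent,
            "CVg_over_CVe": gp.cvg_over_cve, "CV_percent": gp.cv_percent,
            "grand_mean": av.grand_mean,
        })
        sk = scott_knott(
            means.means[trait].to_numpy(), av.qm_r, table.k,
            av.df_residual, alpha=alpha, labels=means.genotypes, trait=trait)
        for geno in means.genotypes:
            sk_rows.append({
                "genotype": geno, "trait": trait,
                "mean": float(means.means.loc[geno, trait]),
                "group": sk.letters[geno],
            })
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(out_dir / "anova_genetic_parameters.csv", index=False,
                    float_format=_FLOAT_FMT)
    pd.DataFrame(sk_rows).to_csv(out_dir / "scott_knott.csv", index=False,
                                 float_format=_FLOAT_FMT)
    sections["anova"] = anova_df.to_dict(orient="records")
    sections["scott_knott_groups"] = {
        trait: int(pd.DataFrame(sk_rows).query("trait == @trait")["group"]
                   .nunique())
        for trait in table.traits
    }

    # --- distances + clustering -------------------------------------------
    pooled = pooled_residual_covariance(table)
    d_mahal = mahalanobis_matrix(means, pooled)
    d_eucl = standardized_euclidean_matrix(means)
    for dist, name in ((d_mahal, "mahalanobis_d2"),
                       (d_eucl, "euclidean_standardized")):
        dist.values.to_csv(out_dir / f"distance_{name}.csv",
                           float_format=_FLOAT_FMT)
        dist.to_long().to_csv(out_dir / f"distance_{name}_pairs.csv",
                              index=False, float_format=_FLOAT_FMT)

    d_tocher = d_mahal if tocher_metric == "mahalanobis" else d_eucl
    toch = tocher_cluster(d_tocher)
    with open(out_dir / "tocher_groups.txt", "w") as fh:
        for label, members in toch.clusters.items():
            fh.write(f"{label}\t{','.join(members)}\n")
    pd.DataFrame(
        [{"group": lab, "genotype": g} for lab, mem in toch.clusters.items()
         for g in mem]
    ).to_csv(out_dir / "tocher_groups.csv", index=False)
    sections["tocher"] = {
        "metric": d_tocher.metric, "theta": toch.theta,
        "n_groups": toch.n_clusters,
        "clusters": {lab: list(mem) for lab, mem in toch.clusters.items()},
    }

    tree = upgma_tree(d_eucl)
    cut = mojena_cut(tree, c=mojena_c)
    (out_dir / "dendrogram.nwk").write_text(to_newick(tree) + "\n")
    pd.DataFrame(tree.linkage,
                 columns=["node_a", "node_b", "height", "size"]).to_csv(
        out_dir / "upgma_merges.csv", index=False, float_format=_FLOAT_FMT)
    pd.Series(cut.membership, name="group").rename_axis("genotype").to_csv(
        out_dir / "upgma_groups.csv")
    sections["upgma"] = {
        "metric": d_eucl.metric, "mojena_c": cut.c, "cutoff": cut.cutoff,
        "mean_height": cut.mean_height, "sd_height": cut.sd_height,
        "n_groups": cut.n_groups, "membership": cut.membership,
    }

    # --- importance + CVA + correlations ----------------------------------
    singh = singh_contributions(means, pooled)
    singh.to_frame().to_csv(out_dir / "singh_importance.csv",
                            index_label="trait", float_format=_FLOAT_FMT)
    sections["singh"] = {
        "percent": singh.percent.to_dict(), "total_d2": singh.total_d2,
        "ranking": singh.ranking(),
    }

    cva = canonical_variates(table)
    cva.to_frame().to_csv(out_dir / "canonical_variates.csv", index=False,
                          float_format=_FLOAT_FMT)
    cva.scores.to_csv(out_dir / "canonical_scores.csv",
                      index_label="genotype", float_format=_FLOAT_FMT)
    sections["canonical_variates"] = {
        "eigenvalues": cva.eigenvalues.tolist(),
        "proportion": cva.proportion.tolist(),
        "cumulative": cva.cumulative.tolist(),
    }

    corr = pearson_matrix(means)
    corr.r.to_csv(out_dir / "correlations_r.csv", float_format=_FLOAT_FMT)
    corr.p.to_csv(out_dir / "correlations_p.csv", float_format=_FLOAT_FMT)
    corr.codes.to_csv(out_dir / "correlations_codes.csv")
    sections["correlations"] = {
        "n": corr.n,
        "r": {f"{a}:{b}": float(corr.r.loc[a, b])
              for i, a in enumerate(corr.r.index)
              for b in corr.r.columns[i + 1:]},
    }

    report = PipelineReport(sections=sections, out_dir=out_dir)
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    (out_dir / "report.txt").write_text(_text_report(sections))
    return report


def _merge_emergence(table: PhenotypeTable, per_rep: pd.DataFrame,
                     notes: list[str]) -> PhenotypeTable:
    """Attach SE/ESI/MET replicate metrics as traits where absent.

    MET is dropped (with a note) if any replicate left it undefined, since
    the balanced ANOVA requires complete replicate-level data.
    """
    new_traits = [t for t in ("SE", "ESI", "MET") if t not in table.traits]
    if not new_traits:
        return table
    per_rep = per_rep.copy()
    per_rep["genotype"] = per_rep["genotype"].astype(str)
    if "MET" in new_traits and per_rep["MET"].isna().any():
        n_bad = int(per_rep["MET"].isna().sum())
        notes.append(
            f"MET undefined for {n_bad} zero-emergence replicate(s); MET "
            "excluded from the replicate-level trait set")
        new_traits.remove("MET")
    if not new_traits:
        return table
    merged = table.data.merge(
        per_rep[["genotype", "replicate", *new_traits]],
        on=["genotype", "replicate"], how="left")
    if merged[new_traits].isna().any().any():
        raise ValueError(
            "emergence metrics missing for some (genotype, replicate) pairs")
    return PhenotypeTable(data=merged, traits=table.traits + tuple(new_traits))


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _text_report(sections: Mapping[str, Any]) -> str:
    lines = ["phenodiv pipeline report", "=" * 24, ""]
    for row in sections.get("anova", []):
        lines.append(
            f"{row['trait']:>6}: QMg={_fmt(row['QMg'])} QMr={_fmt(row['QMr'])} "
            f"F={_fmt(row['F'])}{row['significance']} "
            f"h2={_fmt(row['h2_percent'])}% "
            f"CVg/CVe={_fmt(row['CVg_over_CVe'])} CV={_fmt(row['CV_percent'])}%")
    if "tocher" in sections:
        t = sections["tocher"]
        lines += ["", f"Tocher ({t['metric']}): theta={_fmt(t['theta'])}, "
                      f"{t['n_groups']} groups"]
        for lab, mem in t["clusters"].items():
            lines.append(f"  {lab:>5}: {', '.join(mem)}")
    if "upgma" in sections:
        u = sections["upgma"]
        lines += ["", f"UPGMA/Mojena (c={_fmt(u['mojena_c'])}): "
                      f"cutoff={_fmt(u['cutoff'])}, {u['n_groups']} groups"]
    if "singh" in sections:
        lines += ["", "Singh trait importance (%):"]
        for tr in sections["singh"]["ranking"]:
            lines.append(f"  {tr:>6}: {_fmt(sections['singh']['percent'][tr])}")
    if "canonical_variates" in sections:
        cum = sections["canonical_variates"]["cumulative"]
        lines += ["", "Canonical variates cumulative proportion: "
                  + ", ".join(_fmt(c) for c in cum)]
    for note in sections.get("notes", []):
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
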
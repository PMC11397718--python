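"""Config-driven end-to-end run: inputs -> trait screen -> clustering
-> pedigree scores -> trend correlations -> report bundle.

Stages are pure functions of their inputs plus the options in
:class:`PipelineConfig`; one seed governs every stochastic stage, so a
rerun with the same config is bit-identical. Missing inputs degrade
explicitly: every skipped stage is named, with its reason, in the run
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import (
    DEFAULT_FEATURES,
    build_feature_matrix,
    cut_two_level,
    group_summaries,
    hierarchical_cluster,
    to_newick,
)
from .morphostats import CV_THRESHOLD, uniformity_distinctness_report
from .pedigree import (
    EmptyInputError,
    family_aggregation,
    hybridization_frequency,
    pd_progression,
)
from .simulate import SimConfig, generate_study
from .traits import (
    Pedigree,
    TraitTable,
    compute_derived_ratios,
    read_pedigree,
    read_taxonomy,
    read_trait_table,
    write_pedigree,
    write_taxonomy,
    write_trait_table,
)
from .trends import trend_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs. Exactly one of ``sim`` and
    ``trait_table_path`` must be set (generate-or-load)."""

    out_dir: str = "pollenstats_run"
    sim: SimConfig | None = None
    trait_table_path: str | None = None
    taxonomy_path: str | None = None
    pedigree_path: str | None = None
    dialect: str = "csv"
    linkage: str = "ward"
    k_top: int = 4
    k_sub: int = 3
    features: tuple[str, ...] = DEFAULT_FEATURES
    cv_threshold: float = CV_THRESHOLD
    alpha: float = 0.05
    freq_high: float = 0.20
    freq_medium: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.sim is not None and self.trait_table_path is not None:
            raise ValueError("sim and trait_table_path are mutually exclusive")
        if (self.sim is None and self.trait_table_path is None
                and self.pedigree_path is None):
            raise ValueError("provide sim, a trait table, or a pedigree")
        for name in ("cv_threshold", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write CSV outputs and a JSON manifest, and
    return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pollenstats",
        "version": __version__,
        "seed": config.seed,
        "options": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("sim",)
        },
        "inputs": {},
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, df) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    def stage(name: str, status: str, detail: str = "") -> None:
        manifest["stages"][name] = {"status": status, "detail": detail}
        if status == "skipped":
            logger.warning("stage %s skipped: %s", name, detail)

    # -- inputs --------------------------------------------------------
    table: TraitTable | None = None
    taxonomy = None
    pedigree: Pedigree | None = None
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        manifest["options"]["sim"] = dataclasses.asdict(sim)
        study = generate_study(sim)
        table, taxonomy, pedigree = study.table, study.taxonomy, study.pedigree
        write_trait_table(table, out / "trait_table.csv")
        write_taxonomy(taxonomy, out / "taxonomy.csv")
        write_pedigree(pedigree, out / "pedigree.csv")
        manifest["outputs"] += ["trait_table.csv", "taxonomy.csv", "pedigree.csv"]
        stage("generate", "ran", f"{len(taxonomy)} taxa")
    else:
        if config.trait_table_path:
            path = Path(config.trait_table_path)
            table = read_trait_table(path, config.dialect)
            manifest["inputs"][path.name] = _sha256(path)
        if config.taxonomy_path:
            taxonomy = read_taxonomy(config.taxonomy_path, config.dialect)
            manifest["inputs"][Path(config.taxonomy_path).name] = _sha256(
                Path(config.taxonomy_path))
        if config.pedigree_path:
            pedigree = read_pedigree(config.pedigree_path, config.dialect)
            manifest["inputs"][Path(config.pedigree_path).name] = _sha256(
                Path(config.pedigree_path))
        stage("generate", "skipped", "inputs loaded from files")

    # -- trait screen --------------------------------------------------
    if table is not None:
        screen = uniformity_distinctness_report(
            table, threshold=config.cv_threshold)
        emit("uniformity_distinctness.csv", screen)
        stage("stats", "ran", f"{len(screen)} traits screened")
    else:
        stage("stats", "skipped", "no trait table")

    # -- clustering ----------------------------------------------------
    result = None
    derived = None
    if table is not None:
        derived = compute_derived_ratios(table)
        try:
            features = build_feature_matrix(table, derived, config.features)
            dendro = hierarchical_cluster(features, linkage=config.linkage)
            result = cut_two_level(dendro, k_top=config.k_top,
                                   k_sub=config.k_sub)
            (out / "dendrogram.nwk").write_text(to_newick(dendro))
            manifest["outputs"].append("dendrogram.nwk")
            import pandas as pd

            parts = pd.DataFrame(
                [{"taxon_id": t, "group": g,
                  "subgroup": result.subgroup_of.get(t, "")}
                 for t, g in result.group_of.items()]
            )
            emit("clusters.csv", parts)
            emit("group_summaries.csv",
                 group_summaries(table, result, derived, alpha=config.alpha))
            stage("cluster", "ran",
                  f"{len(result.group_of)} taxa into "
                  f"{config.k_top}+{config.k_sub}")
        except ValueError as exc:
            stage("cluster", "skipped", str(exc))
    else:
        stage("cluster", "skipped", "no trait table")

    # -- pedigree scores -----------------------------------------------
    import pandas as pd

    if pedigree is not None and len(pedigree):
        rows = []
        if result is not None:
            for level in ("four_group", "six_group"):
                try:
                    rep = family_aggregation(result, pedigree, level=level)
                    rows.append({"statistic": f"family_aggregation_{level}",
                                 "percentage": rep.percentage,
                                 "n_evaluable": rep.n_evaluable})
                except EmptyInputError as exc:
                    stage(f"family_aggregation_{level}", "skipped", str(exc))
        else:
            stage("family_aggregation", "skipped", "no clustering available")
        pd_means = table.taxon_means().get("PD") if table is not None else None
        if pd_means is not None:
            for mode in ("assume_lower", "exclude_unknown"):
                try:
                    rep = pd_progression(pd_means.dropna().to_dict(),
                                         pedigree, mode=mode)
                    rows.append({"statistic": f"pd_progression_{mode}",
                                 "percentage": rep.percentage,
                                 "n_evaluable": rep.n_evaluable})
                except (EmptyInputError, ValueError) as exc:
                    stage(f"pd_progression_{mode}", "skipped", str(exc))
        hf = hybridization_frequency(pedigree, high=config.freq_high,
                                     medium=config.freq_medium)
        emit("hybridization_frequency.csv", pd.DataFrame(
            [{"species": s, "frequency": f,
              "class": hf.classification[s]}
             for s, f in hf.frequency.items()]))
        if rows:
            emit("pedigree_scores.csv", pd.DataFrame(rows))
        stage("pedigree", "ran", f"{len(pedigree)} routes")
    else:
        stage("pedigree", "skipped", "no pedigree provided")

    # -- trends --------------------------------------------------------
    if taxonomy is not None and table is not None:
        trends = trend_report(table, taxonomy)
        emit("trends.csv", trends)
        stage("trend", "ran", f"{len(trends)} correlations")
    else:
        stage("trend", "skipped", "no taxonomy provided")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
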
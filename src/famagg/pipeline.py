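"""End-to-end orchestration: simulate/load -> classify -> test -> report.

A :class:`PipelineConfig` names the inputs (or enables the simulate stage),
toggles the stages, and carries per-stage parameter blocks.  ``run_pipeline``
executes the enabled stages in a fixed order, writes each stage's artifacts
under the output directory, and returns the assembled study report (also
written as ``report.json``).  The seed is recorded in every emitted report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from famagg import io as fio
from famagg.aggregation import FamilialAggregation, FamilyTable
from famagg.brca_like import predict_brca_like
from famagg.cluster import ClusterConfig, hierarchical_cluster, standardize, top_variant_genes
from famagg.methylation import call_methylation, expression_association, sample_positive
from famagg.simulate import SyntheticConfig, generate_cohort, generate_methylation
from famagg.subtypes import calls_to_frame, classify_cohort, subtype_distribution

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "brca_like", "methylation", "aggregation", "cluster")


@dataclass
class PipelineConfig:
    out_dir: str = "famagg_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "classify", "aggregation")
    # inputs (unused when the simulate stage is enabled)
    expression: str | None = None
    annotation: str | None = None
    centroids: str | None = None
    families: str | None = None
    labels: str | None = None
    signature: str | None = None
    ratios: str | None = None
    methylation_gene: str | None = None
    # per-stage parameter blocks
    simulate_params: dict = field(default_factory=dict)
    classify_method: str = "spearman"
    aggregation_params: dict = field(default_factory=dict)
    cluster_params: dict = field(default_factory=dict)
    methylation_threshold: float = 0.2

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
        if "simulate" not in self.stages:
            for attr in ("expression",):
                needs_expr = {"classify", "cluster"} & set(self.stages)
                if needs_expr and self.expression is None:
                    raise ValueError("expression input required when simulate is disabled")
        for attr in ("expression", "annotation", "centroids", "families",
                     "labels", "signature", "ratios"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    # output location is not part of the scientific configuration
    fields = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    blob = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in fixed order and return the study report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "stages": list(config.stages),
        }
    }

    expression = annotation = centroids = None
    families = labels = None
    ratio_table = None
    cohort = None

    if "simulate" in config.stages:
        params = dict(config.simulate_params)
        params.setdefault("seed", config.seed)
        sim_config = SyntheticConfig(**params)
        cohort = generate_cohort(sim_config)
        if config.methylation_gene and "methylation" in config.stages:
            generate_methylation(sim_config, cohort, config.methylation_gene)
        expression, annotation, centroids = (
            cohort.expression, cohort.annotation, cohort.centroids
        )
        families = cohort.families
        ratio_table = cohort.methylation
        fio.write_expression(expression, out / "expression.tsv")
        fio.write_annotation(annotation, out / "annotation.csv")
        fio.write_centroids(centroids, out / "centroids.csv")
        fio.write_families(families, out / "families.csv")
        if ratio_table is not None:
            fio.write_ratios(ratio_table, out / "methylation_ratios.csv")
        logger.info("simulate: %d genes x %d samples, %d families",
                    *expression.shape, len(families))
    else:
        if config.expression:
            expression = fio.read_expression(config.expression)
        if config.annotation:
            annotation = fio.read_annotation(config.annotation)
        if config.centroids:
            centroids = fio.read_centroids(config.centroids)
        if config.families:
            families = fio.read_families(config.families)
        if config.labels:
            labels = fio.read_labels(config.labels)
        if config.ratios:
            ratio_table = fio.read_ratios(config.ratios)

    subtype_calls = None
    if "classify" in config.stages:
        if expression is None or centroids is None:
            raise ValueError("classify stage needs expression and centroids")
        subtype_calls = classify_cohort(expression, centroids, method=config.classify_method)
        frame = calls_to_frame(subtype_calls)
        frame.to_csv(out / "subtype_calls.csv")
        labels = dict(zip(frame.index, frame["assigned_subtype"]))
        group_of = None
        if annotation is not None and "group" in annotation.columns:
            group_of = dict(zip(annotation["sample_id"], annotation["group"]))
        dist = subtype_distribution(subtype_calls, group_of)
        dist.to_csv(out / "subtype_distribution.csv")
        report["subtype_distribution"] = {
            f"{g}/{s}": int(r["count"]) for (g, s), r in dist.iterrows()
        }
        logger.info("classify: %d samples", len(subtype_calls))

    if "brca_like" in config.stages:
        if config.signature is None:
            raise ValueError("brca_like stage needs a signature file")
        if subtype_calls is None or expression is None:
            raise ValueError("brca_like stage needs classify stage outputs")
        model = fio.read_signature(config.signature)
        brca_calls = predict_brca_like(model, expression, subtype_calls)
        rows = [
            {"sample": c.sample_id, "score": c.decision_score, "class": c.predicted_class}
            for c in brca_calls
        ]
        fio.write_json(rows, out / "brca_like_calls.json")
        report["brca_like"] = {
            "n_scored": len(brca_calls),
            "n_positive": sum(c.predicted_class == model.positive_class for c in brca_calls),
            "applicable_subtype": model.applicable_subtype,
        }

    if "methylation" in config.stages:
        if ratio_table is None:
            raise ValueError("methylation stage needs a ratios input (or simulate)")
        meth_calls = call_methylation(ratio_table, threshold=config.methylation_threshold)
        positives = sample_positive(meth_calls)
        meth_report = {
            "threshold": config.methylation_threshold,
            "n_samples": len(positives),
            "n_positive": sum(positives.values()),
        }
        gene = config.methylation_gene
        if gene and expression is not None and gene in expression.index:
            assoc = expression_association(expression.loc[gene], meth_calls)
            meth_report["expression_association"] = {
                "gene": gene,
                "t_statistic": assoc.t_statistic,
                "p_value": assoc.p_value,
                "mean_methylated": assoc.mean_positive,
                "mean_unmethylated": assoc.mean_negative,
                "n_methylated": assoc.n_positive,
                "n_unmethylated": assoc.n_negative,
            }
        report["methylation"] = meth_report

    if "aggregation" in config.stages:
        if families is None:
            raise ValueError("aggregation stage needs families (input or simulated)")
        if labels is None:
            if cohort is not None:
                labels = cohort.true_labels()
            else:
                raise ValueError("aggregation stage needs subtype labels")
        params = dict(config.aggregation_params)
        params.setdefault("seed", config.seed)
        pool_policy = params.pop("pool_policy", "multicase_only")
        model = FamilialAggregation(families, labels, pool_policy=pool_policy)
        results = model.fit(**params)
        results.to_json(out / "aggregation_report.json")
        report["aggregation"] = {
            "observed_statistic": results.observed_statistic,
            "p_value": results.p_value,
            "n_replicates": results.n_replicates,
            "pool_policy": results.pool_policy,
            "seed": results.seed,
        }
        logger.info("aggregation: observed=%d p=%.3g",
                    results.observed_statistic, results.p_value)

    if "cluster" in config.stages:
        if expression is None:
            raise ValueError("cluster stage needs expression")
        cc = ClusterConfig(**config.cluster_params) if config.cluster_params else ClusterConfig()
        k = min(cc.k_genes, len(expression.index))
        genes = top_variant_genes(expression, k)
        standardized = standardize(expression.loc[genes])
        result = hierarchical_cluster(standardized, cc)
        (out / "dendrogram.nwk").write_text(result.to_newick() + "\n")
        report["cluster"] = {"k_genes": k, "metric": cc.metric, "linkage": cc.linkage}

    fio.write_json(report, out / "report.json")
    return report
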
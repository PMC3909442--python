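"""Synthetic cohorts with subtype structure, family structure and methylation.

The generator emulates the statistical structure the downstream analysis
assumes:

* expression: each sample is its subtype's centroid profile plus independent
  Gaussian noise on the log scale;
* centroids: block-structured — each subtype has a set of marker genes
  shifted by ``delta`` above a per-gene baseline;
* families: a founder subtype is drawn from the cohort prevalence; each
  member inherits it with probability ``rho`` (the within-family concordance)
  or draws independently from the prevalence.  ``rho = 0`` is the
  exchangeable null of the aggregation test; ``rho = 1`` forces perfect
  aggregation;
* methylation: promoter ratios straddle the 0.2 positivity threshold
  (methylated samples uniform on (0.3, 0.8), unmethylated on (0.0, 0.1)) and
  methylated samples lose ``methylation_knockdown`` log-units of the target
  gene's expression.

One master seed; each stage draws from its own deterministically derived
stream, so adding a stage never perturbs the draws of an earlier one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from famagg.aggregation import FamilyTable
from famagg.subtypes import INTRINSIC_SUBTYPES

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_centroids",
           "generate_cohort", "generate_methylation"]

#: Default subtype prevalence, in INTRINSIC_SUBTYPES order
#: (Basal-like, HER2-enriched, LumA, LumB, Normal-like): the distribution
#: observed in familial non-BRCA1/2 breast tumors (13%, 10%, 47%, 26%, 4%).
DEFAULT_PREVALENCE = (0.13, 0.10, 0.47, 0.26, 0.04)

#: Default family sizes: 47 single-case families, 10 two-case, 1 three-case,
#: mirroring a 58-family cohort contributing 70 tumors.
DEFAULT_FAMILY_SIZES = (1,) * 47 + (2,) * 10 + (3,)

# fixed per-stage spawn keys so streams are independent and stable
_STAGE = {"centroids": 0, "labels": 1, "noise": 2, "methylation": 3}

_BASELINE_MEAN = 7.0  # log2-scale baseline expression
_BASELINE_SD = 1.0


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE[stage],)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    delta is the marker-gene shift (log2 units) of a subtype's markers in its
    own centroid; sigma the per-gene Gaussian noise sd; rho the probability a
    family member inherits the family founder's subtype.
    """

    n_genes: int = 200
    n_markers_per_subtype: int = 10
    subtype_names: tuple[str, ...] = INTRINSIC_SUBTYPES
    prevalence: tuple[float, ...] = DEFAULT_PREVALENCE
    delta: float = 2.0
    sigma: float = 1.0
    family_sizes: tuple[int, ...] = DEFAULT_FAMILY_SIZES
    rho: float = 0.0
    methylated_fraction: float = 0.06
    methylation_knockdown: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_markers_per_subtype < 1:
            raise ValueError("n_genes and n_markers_per_subtype must be >= 1")
        names = tuple(self.subtype_names)
        if len(set(names)) != len(names):
            raise ValueError("subtype names must be distinct")
        prev = tuple(float(p) for p in self.prevalence)
        if len(prev) != len(names):
            raise ValueError("prevalence length must match subtype_names")
        if any(p < 0 for p in prev):
            raise ValueError("prevalence entries must be nonnegative")
        if abs(sum(prev) - 1.0) > 1e-9:
            raise ValueError(f"prevalence sums to {sum(prev)!r}, not 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.methylated_fraction <= 1.0:
            raise ValueError("methylated_fraction must be in [0, 1]")
        if self.delta < 0 or self.methylation_knockdown < 0:
            raise ValueError("delta and methylation_knockdown must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        sizes = tuple(int(k) for k in self.family_sizes)
        if not sizes or any(k < 1 for k in sizes):
            raise ValueError("family_sizes must be a nonempty list of positive counts")
        object.__setattr__(self, "subtype_names", names)
        object.__setattr__(self, "prevalence", prev)
        object.__setattr__(self, "family_sizes", sizes)
        if self.n_markers_per_subtype * len(names) > self.n_genes:
            raise ValueError(
                f"{self.n_markers_per_subtype} markers x {len(names)} subtypes "
                f"exceed n_genes={self.n_genes}"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.family_sizes)


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, annotation, families, true centroids."""

    expression: pd.DataFrame  # genes x samples
    annotation: pd.DataFrame  # sample_id, family_id, subtype (+ methylated)
    families: FamilyTable
    centroids: pd.DataFrame  # genes x subtypes
    methylation: pd.DataFrame | None = None  # long: sample, probe, ratio

    def true_labels(self) -> dict[str, str]:
        return dict(zip(self.annotation["sample_id"], self.annotation["subtype"]))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_centroids(config: SyntheticConfig) -> pd.DataFrame:
    """Block-structured centroid table: genes x subtypes.

    The first ``n_markers_per_subtype`` genes are markers of the first
    subtype, the next block markers of the second, and so on; a marker sits
    at baseline + delta in its own subtype's column and at baseline
    elsewhere.  Baselines are drawn per gene (one fixed stream), so the table
    is deterministic given the seed.
    """
    rng = _stage_rng(config.seed, "centroids")
    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=config.n_genes)
    values = np.tile(baseline[:, None], (1, len(config.subtype_names)))
    m = config.n_markers_per_subtype
    for j in range(len(config.subtype_names)):
        values[j * m : (j + 1) * m, j] += config.delta
    return pd.DataFrame(values, index=_gene_ids(config.n_genes),
                        columns=list(config.subtype_names))


def _draw_family_labels(config: SyntheticConfig, rng: np.random.Generator) -> list[list[int]]:
    prev = np.asarray(config.prevalence)
    k = len(prev)
    out = []
    for size in config.family_sizes:
        founder = rng.choice(k, p=prev)
        members = []
        for _ in range(size):
            if rng.random() < config.rho:
                members.append(int(founder))
            else:
                members.append(int(rng.choice(k, p=prev)))
        out.append(members)
    return out


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full cohort under the founder-subtype concordance model."""
    centroids = generate_centroids(config)
    label_rng = _stage_rng(config.seed, "labels")
    noise_rng = _stage_rng(config.seed, "noise")

    fam_labels = _draw_family_labels(config, label_rng)
    n = config.n_samples
    width = max(4, len(str(n)))
    fam_width = max(3, len(str(len(config.family_sizes))))

    families: dict[str, list[str]] = {}
    records = []
    i = 0
    for f, members in enumerate(fam_labels):
        fid = f"F{f + 1:0{fam_width}d}"
        families[fid] = []
        for lab in members:
            sid = f"S{i + 1:0{width}d}"
            i += 1
            families[fid].append(sid)
            records.append({"sample_id": sid, "family_id": fid,
                            "subtype": config.subtype_names[lab]})
    annotation = pd.DataFrame(records)

    subtype_idx = {name: j for j, name in enumerate(config.subtype_names)}
    cols = np.array([subtype_idx[r["subtype"]] for r in records])
    values = centroids.to_numpy()[:, cols] + noise_rng.normal(
        0.0, config.sigma, size=(config.n_genes, n)
    )
    expression = pd.DataFrame(values, index=centroids.index,
                              columns=annotation["sample_id"].tolist())
    return SyntheticCohort(
        expression=expression,
        annotation=annotation,
        families=FamilyTable(families),
        centroids=centroids,
    )


def generate_methylation(
    config: SyntheticConfig,
    cohort: SyntheticCohort,
    target_gene: str,
) -> pd.DataFrame:
    """Simulate promoter methylation ratios for one gene and silence it.

    A fraction ``methylated_fraction`` of samples is methylated: their ratio
    is uniform on (0.3, 0.8) — clearly above the 0.2 positivity threshold —
    and their expression of ``target_gene`` is reduced by
    ``methylation_knockdown``.  Unmethylated samples get ratios on
    (0.0, 0.1).  The cohort's expression matrix and annotation are modified
    in place; the long-format ratio table is returned and also stored on the
    cohort.
    """
    if target_gene not in cohort.expression.index:
        raise KeyError(f"gene {target_gene!r} not in expression matrix")
    rng = _stage_rng(config.seed, "methylation")
    samples = cohort.expression.columns
    methylated = rng.random(len(samples)) < config.methylated_fraction
    ratios = np.where(
        methylated,
        rng.uniform(0.3, 0.8, size=len(samples)),
        rng.uniform(0.0, 0.1, size=len(samples)),
    )
    cohort.expression.loc[target_gene, methylated] -= config.methylation_knockdown
    cohort.annotation["methylated"] = methylated
    table = pd.DataFrame({
        "sample": samples,
        "probe": f"{target_gene}_promoter",
        "ratio": ratios,
    })
    cohort.methylation = table
    return table
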
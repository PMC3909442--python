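"""Promoter-methylation calls from MS-MLPA ratios and expression association.

MS-MLPA reports a per-probe methylation ratio; a ratio strictly greater than
0.2 is a positive promoter-methylation call.  A sample is promoter-positive
for a gene if any of its probes for that promoter is positive.  The
expression association test compares expression of the silenced gene between
promoter-positive and negative samples with a two-sample t-test (Welch by
default: group sizes are typically very unbalanced).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethylationCall",
    "AssociationResult",
    "call_methylation",
    "sample_positive",
    "expression_association",
]

DEFAULT_THRESHOLD = 0.2


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    probe_id: str
    ratio: float
    positive: bool


@dataclass(frozen=True)
class AssociationResult:
    """Welch/Student t-test of expression between methylated and unmethylated."""

    t_statistic: float
    p_value: float
    mean_positive: float
    mean_negative: float
    n_positive: int
    n_negative: int
    equal_var: bool


def _validate_ratio_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "probe", "ratio"}
    if not required.issubset(table.columns):
        raise ValueError(f"ratio table needs columns {sorted(required)}")
    if (table["ratio"] < 0).any():
        bad = table.loc[table["ratio"] < 0]
        raise ValueError(
            f"negative methylation ratio for sample {bad['sample'].iloc[0]!r}, "
            f"probe {bad['probe'].iloc[0]!r}"
        )
    if table.duplicated(["sample", "probe"]).any():
        raise ValueError("duplicate (sample, probe) pair in ratio table")
    return table


def call_methylation(
    table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> list[MethylationCall]:
    """Threshold per-probe ratios: positive iff ratio > threshold (strict)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    _validate_ratio_table(table)
    return [
        MethylationCall(str(r.sample), str(r.probe), float(r.ratio),
                        bool(r.ratio > threshold))
        for r in table.itertuples()
    ]


def sample_positive(calls: Iterable[MethylationCall]) -> dict[str, bool]:
    """Gene-level positivity: a sample is positive if any probe call is."""
    out: dict[str, bool] = {}
    for c in calls:
        out[c.sample_id] = out.get(c.sample_id, False) or c.positive
    return out


def expression_association(
    expression_of_gene: pd.Series,
    calls: Iterable[MethylationCall],
    equal_var: bool = False,
) -> AssociationResult:
    """Two-sided t-test of gene expression, methylated vs unmethylated samples.

    ``expression_of_gene`` maps sample id -> expression of the gene whose
    promoter was assayed.  Samples are grouped by the any-probe positivity
    rule.  Welch's unequal-variance test by default; ``equal_var=True`` for
    the pooled (Student) variant.
    """
    pos_of = sample_positive(calls)
    missing = [s for s in pos_of if s not in expression_of_gene.index]
    if missing:
        raise ValueError(f"no expression value for samples: {missing[:5]}")
    pos = np.array([expression_of_gene[s] for s, p in pos_of.items() if p], float)
    neg = np.array([expression_of_gene[s] for s, p in pos_of.items() if not p], float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need >= 2 samples per group for the t-test; got "
            f"{len(pos)} methylation-positive and {len(neg)} negative"
        )
    t, p = stats.ttest_ind(pos, neg, equal_var=equal_var)
    return AssociationResult(
        t_statistic=float(t),
        p_value=float(p),
        mean_positive=float(pos.mean()),
        mean_negative=float(neg.mean()),
        n_positive=len(pos),
        n_negative=len(neg),
        equal_var=equal_var,
    )
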
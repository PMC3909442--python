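"""Permutation test for familial aggregation of tumor subtypes.

The question: do tumors from the same family share a molecular subtype more
often than expected if subtypes were assigned to families at random?

The statistic is the *concordance count*: the number of families containing
at least two tumors with an identical subtype label.  Singleton families can
never contribute.  Under the null, the observed multiset of subtype labels is
randomly re-partitioned into the observed family sizes; the empirical p-value
is the proportion of null replicates whose concordance count is at least the
observed one.  An exact null by enumeration over distinct label arrangements
is available for small instances and serves as the oracle for the
Monte-Carlo sampler.

`FamilialAggregation` is the model object (data + pool policy); its
:meth:`~FamilialAggregation.fit` runs the test and returns
:class:`AggregationResults`.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "FamilyTable",
    "NullDistribution",
    "AggregationResults",
    "FamilialAggregation",
    "concordance_statistic",
    "permutation_null",
    "exact_null",
    "empirical_pvalue",
    "run_aggregation_test",
]

DEFAULT_REPLICATES = 100_000
DEFAULT_ENUMERATION_BUDGET = 10**7


@dataclass(frozen=True)
class FamilyTable:
    """Family membership: family id -> ordered member sample ids.

    Sample ids must be globally unique across families and every family must
    have at least one member.
    """

    members: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        members = {str(f): tuple(str(s) for s in ss) for f, ss in dict(self.members).items()}
        object.__setattr__(self, "members", members)
        seen: set[str] = set()
        for fam, samples in members.items():
            if len(samples) == 0:
                raise ValueError(f"family {fam!r} has no members")
            for s in samples:
                if s in seen:
                    raise ValueError(f"sample id {s!r} appears in more than one family")
                seen.add(s)

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(self.members)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for ss in self.members.values() for s in ss)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(ss) for ss in self.members.values())

    def multicase(self) -> "FamilyTable":
        """Restrict to families contributing two or more samples."""
        return FamilyTable({f: ss for f, ss in self.members.items() if len(ss) >= 2})

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.items())


@dataclass(frozen=True)
class NullDistribution:
    """Distribution of the concordance count under random label reassignment.

    ``n_replicates`` is 0 for an exact (enumeration) null.  ``mass`` entries
    are probabilities summing to 1.
    """

    support: tuple[int, ...]
    mass: tuple[float, ...]
    n_replicates: int
    seed: int | None
    method: str  # "monte_carlo" | "exact"
    pool_policy: str | None = None

    def __post_init__(self) -> None:
        if len(self.support) != len(self.mass):
            raise ValueError("support and mass have different lengths")
        if any(m < 0 for m in self.mass):
            raise ValueError("negative probability mass")
        total = float(sum(self.mass))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"null masses sum to {total!r}, not 1")
        if self.method not in ("monte_carlo", "exact"):
            raise ValueError(f"unknown method {self.method!r}")

    def pvalue(self, observed: int, *, add_one: bool = False) -> float:
        return empirical_pvalue(self, observed, add_one=add_one)

    def mean(self) -> float:
        return float(sum(s * m for s, m in zip(self.support, self.mass)))

    def as_dict(self) -> dict:
        return {
            "support": list(self.support),
            "mass": list(self.mass),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "method": self.method,
            "pool_policy": self.pool_policy,
        }


def _validate_labels(families: FamilyTable, labels: Mapping[str, str]) -> None:
    for fam, samples in families:
        for s in samples:
            if s not in labels:
                raise ValueError(f"sample {s!r} (family {fam!r}) has no subtype label")


def concordance_statistic(families: FamilyTable, labels: Mapping[str, str]) -> int:
    """Number of families with at least two members sharing a subtype label.

    This is the aggregation measure: a family of size >= 2 contributes 1 if
    any subtype appears twice or more among its members, else 0.  Whether two
    or all three members of a trio agree makes no difference.
    """
    _validate_labels(families, labels)
    count = 0
    for _, samples in families:
        if len(samples) < 2:
            continue
        tally = Counter(labels[s] for s in samples)
        if max(tally.values()) >= 2:
            count += 1
    return count


def _encode_labels(label_multiset: Sequence[str]) -> np.ndarray:
    _, codes = np.unique(np.asarray(list(label_multiset)), return_inverse=True)
    return codes.astype(np.int64)


def permutation_null(
    label_multiset: Sequence[str],
    family_sizes: Sequence[int],
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = 0,
    pool_policy: str | None = None,
) -> NullDistribution:
    """Monte-Carlo null: random re-partitions of the labels into the families.

    Each replicate permutes the label multiset uniformly at random and splits
    it into consecutive blocks of the given family sizes; the concordance
    count is recorded.  Reproducible given ``seed``.
    """
    sizes = [int(k) for k in family_sizes]
    if any(k < 1 for k in sizes):
        raise ValueError("family sizes must be positive")
    if sum(sizes) != len(label_multiset):
        raise ValueError(
            f"family sizes sum to {sum(sizes)} but {len(label_multiset)} labels supplied"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    codes = _encode_labels(label_multiset)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_replicates, 1)), axis=1)

    concordant = np.zeros(n_replicates, dtype=np.int64)
    offset = 0
    for k in sizes:
        if k >= 2:
            fam = np.sort(perms[:, offset : offset + k], axis=1)
            concordant += (fam[:, 1:] == fam[:, :-1]).any(axis=1)
        offset += k

    freq = np.bincount(concordant, minlength=1)
    support = np.flatnonzero(freq)
    mass = freq[support] / n_replicates
    return NullDistribution(
        support=tuple(int(s) for s in support),
        mass=tuple(float(m) for m in mass),
        n_replicates=n_replicates,
        seed=seed,
        method="monte_carlo",
        pool_policy=pool_policy,
    )


def n_distinct_arrangements(label_counts: Sequence[int]) -> int:
    """Number of distinct ordered arrangements of a label multiset."""
    n = sum(label_counts)
    total = math.factorial(n)
    for c in label_counts:
        total //= math.factorial(c)
    return total


def exact_null(
    label_multiset: Sequence[str],
    family_sizes: Sequence[int],
    budget: int = DEFAULT_ENUMERATION_BUDGET,
    pool_policy: str | None = None,
) -> NullDistribution:
    """Exact null distribution by enumeration over distinct label arrangements.

    Counts arrangements by a memoized recursion, family by family: for each
    family the multiset of labels it receives is enumerated, weighted by the
    number of orderings, and the residual counts recurse on the remaining
    families.  Arrangement counts are exact integers, so the returned masses
    are exact rationals rounded only at the final float division.

    Raises if the number of distinct arrangements exceeds ``budget``; use
    :func:`permutation_null` for such instances.
    """
    sizes = tuple(sorted(int(k) for k in family_sizes))
    if any(k < 1 for k in sizes):
        raise ValueError("family sizes must be positive")
    if sum(sizes) != len(label_multiset):
        raise ValueError(
            f"family sizes sum to {sum(sizes)} but {len(label_multiset)} labels supplied"
        )
    counts = tuple(sorted(Counter(label_multiset).values()))
    total_arrangements = n_distinct_arrangements(counts)
    if total_arrangements > budget:
        raise ValueError(
            f"{total_arrangements} distinct arrangements exceed the enumeration "
            f"budget of {budget}; use permutation_null (Monte Carlo) instead"
        )

    @lru_cache(maxsize=None)
    def arrange(counts: tuple[int, ...], sizes: tuple[int, ...]) -> dict[int, int]:
        # -> {concordance count: number of distinct ordered arrangements}
        if not sizes:
            return {0: 1}
        s, rest = sizes[0], sizes[1:]
        out: dict[int, int] = {}

        def compositions(i: int, remaining: int, cur: list[int]):
            if i == len(counts):
                if remaining == 0:
                    yield tuple(cur)
                return
            for k in range(min(counts[i], remaining) + 1):
                cur.append(k)
                yield from compositions(i + 1, remaining - k, cur)
                cur.pop()

        for ks in compositions(0, s, []):
            ways = math.factorial(s)
            for k in ks:
                ways //= math.factorial(k)
            bump = 1 if max(ks) >= 2 else 0
            sub = arrange(tuple(c - k for c, k in zip(counts, ks)), rest)
            for stat, cnt in sub.items():
                out[stat + bump] = out.get(stat + bump, 0) + ways * cnt
        return out

    dist = arrange(counts, sizes)
    assert sum(dist.values()) == total_arrangements
    support = sorted(dist)
    mass = [dist[s] / total_arrangements for s in support]
    return NullDistribution(
        support=tuple(support),
        mass=tuple(mass),
        n_replicates=0,
        seed=None,
        method="exact",
        pool_policy=pool_policy,
    )


def empirical_pvalue(null: NullDistribution, observed: int, *, add_one: bool = False) -> float:
    """Upper-tail probability of the null at the observed concordance count.

    Plain-proportion convention by default: the total mass at support values
    greater than or equal to ``observed``.  With ``add_one=True`` the
    (r+1)/(n+1) convention is used instead (Monte-Carlo nulls only).
    """
    tail = sum(m for s, m in zip(null.support, null.mass) if s >= observed)
    if not add_one:
        return float(tail)
    if null.method != "monte_carlo":
        raise ValueError("the (r+1)/(n+1) convention applies to Monte-Carlo nulls only")
    n = null.n_replicates
    r = round(tail * n)
    return (r + 1) / (n + 1)


@dataclass(frozen=True)
class AggregationResults:
    """Results of the familial-aggregation test.

    Attributes
    ----------
    observed_statistic : number of families with >= 2 same-subtype tumors.
    p_value : proportion of null replicates with a statistic at least as large.
    null : the null distribution used (Monte Carlo or exact).
    family_sizes : sizes of the families in the permutation pool.
    label_counts : subtype -> multiplicity in the permutation pool.
    pool_policy : "multicase_only" or "all_samples".
    """

    observed_statistic: int
    p_value: float
    null: NullDistribution
    family_sizes: tuple[int, ...]
    label_counts: Mapping[str, int]
    pool_policy: str
    n_replicates: int
    seed: int | None
    add_one: bool = False

    def summary(self) -> str:
        lines = [
            "Familial aggregation of tumor subtypes",
            "=" * 46,
            f"Families in pool:        {len(self.family_sizes)}"
            f"  (sizes: {_format_sizes(self.family_sizes)})",
            f"Samples in pool:         {sum(self.family_sizes)}",
            "Label pool:              "
            + ", ".join(f"{k}: {v}" for k, v in self.label_counts.items()),
            f"Pool policy:             {self.pool_policy}",
            f"Null method:             {self.null.method}"
            + (f" ({self.n_replicates} replicates, seed={self.seed})"
               if self.null.method == "monte_carlo" else " (enumeration)"),
            "-" * 46,
            f"Observed concordant families:  {self.observed_statistic}",
            f"Expected under null:           {self.null.mean():.2f}",
            f"Empirical p-value:             {self.p_value:.3g}",
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "observed_statistic": self.observed_statistic,
            "p_value": self.p_value,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "pool_policy": self.pool_policy,
            "add_one": self.add_one,
            "family_sizes": list(self.family_sizes),
            "label_counts": dict(self.label_counts),
            "null": self.null.as_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def _format_sizes(sizes: Sequence[int]) -> str:
    tally = Counter(sizes)
    return ", ".join(f"{n}x{k}" for k, n in sorted(tally.items()))


class FamilialAggregation:
    """Familial-aggregation test model.

    Parameters
    ----------
    families : FamilyTable or mapping family id -> member sample ids.
    labels : mapping sample id -> subtype label; must cover every member.
    pool_policy : which samples form the permutation pool.
        ``"multicase_only"`` (default) uses only families with >= 2 members —
        the only construction computable from published per-family subtype
        tables; ``"all_samples"`` permutes every sample over every family.
        The observed statistic is identical under both (singletons never
        contribute); only the null differs.

    Examples
    --------
    >>> fams, labels = load_table3()  # doctest: +SKIP
    >>> res = FamilialAggregation(fams, labels).fit(seed=1)  # doctest: +SKIP
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        families: FamilyTable | Mapping[str, Sequence[str]],
        labels: Mapping[str, str],
        pool_policy: str = "multicase_only",
    ) -> None:
        if not isinstance(families, FamilyTable):
            families = FamilyTable(families)
        if pool_policy not in ("multicase_only", "all_samples"):
            raise ValueError(f"unknown pool_policy {pool_policy!r}")
        _validate_labels(families, labels)
        self.families = families
        self.labels = dict(labels)
        self.pool_policy = pool_policy

        pool = families.multicase() if pool_policy == "multicase_only" else families
        if len(pool.multicase()) < 1:
            raise ValueError(
                "the aggregation test is undefined without at least one family "
                "of two or more samples"
            )
        self._pool = pool
        self._pool_labels = [self.labels[s] for s in pool.sample_ids]

    @property
    def observed_statistic(self) -> int:
        return concordance_statistic(self.families, self.labels)

    def null_distribution(
        self,
        method: str = "monte_carlo",
        n_replicates: int = DEFAULT_REPLICATES,
        seed: int | None = 0,
        budget: int = DEFAULT_ENUMERATION_BUDGET,
    ) -> NullDistribution:
        sizes = self._pool.sizes()
        if method == "monte_carlo":
            return permutation_null(
                self._pool_labels, sizes, n_replicates=n_replicates, seed=seed,
                pool_policy=self.pool_policy,
            )
        if method == "exact":
            return exact_null(
                self._pool_labels, sizes, budget=budget, pool_policy=self.pool_policy
            )
        raise ValueError(f"unknown method {method!r}")

    def fit(
        self,
        n_replicates: int = DEFAULT_REPLICATES,
        seed: int | None = 0,
        method: str = "monte_carlo",
        add_one: bool = False,
        budget: int = DEFAULT_ENUMERATION_BUDGET,
    ) -> AggregationResults:
        """Run the test and return :class:`AggregationResults`."""
        null = self.null_distribution(
            method=method, n_replicates=n_replicates, seed=seed, budget=budget
        )
        observed = self.observed_statistic
        p = empirical_pvalue(null, observed, add_one=add_one)
        return AggregationResults(
            observed_statistic=observed,
            p_value=p,
            null=null,
            family_sizes=self._pool.sizes(),
            label_counts=dict(Counter(self._pool_labels)),
            pool_policy=self.pool_policy,
            n_replicates=null.n_replicates,
            seed=null.seed,
            add_one=add_one,
        )


def run_aggregation_test(
    families: FamilyTable | Mapping[str, Sequence[str]],
    labels: Mapping[str, str],
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = 0,
    pool_policy: str = "multicase_only",
    method: str = "monte_carlo",
    add_one: bool = False,
) -> AggregationResults:
    """One-call interface: build :class:`FamilialAggregation` and fit it."""
    model = FamilialAggregation(families, labels, pool_policy=pool_policy)
    return model.fit(n_replicates=n_replicates, seed=seed, method=method, add_one=add_one)
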
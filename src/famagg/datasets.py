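"""Bundled family/subtype tables.

Two small per-family subtype tables ship with the package so the headline
aggregation p-values are reproducible offline:

* ``table3``: 11 multi-case non-BRCA1/2 breast-cancer families (ten of two
  tumors, one of three) with PAM50-style subtype calls.
* ``table4``: the five multi-case families of an independent confirmation
  cohort (sizes 2, 2, 2, 3, 3).

Sample ids are synthesized as ``<family>-<n>``; the published tables report
per-family subtype counts, not per-sample identifiers.
"""

from importlib import resources

import pandas as pd

from famagg.aggregation import FamilyTable

__all__ = ["load_table3", "load_table4"]


def _load(name: str) -> tuple[FamilyTable, dict[str, str]]:
    with resources.files("famagg").joinpath("data", name).open() as fh:
        df = pd.read_csv(fh, dtype=str)
    fams: dict[str, list[str]] = {}
    for fam, sample in zip(df["family_id"], df["sample_id"]):
        fams.setdefault(fam, []).append(sample)
    labels = dict(zip(df["sample_id"], df["subtype"]))
    return FamilyTable(fams), labels


def load_table3() -> tuple[FamilyTable, dict[str, str]]:
    """The 11 multi-case discovery families and their subtype labels."""
    return _load("table3.csv")


def load_table4() -> tuple[FamilyTable, dict[str, str]]:
    """The 5 multi-case confirmation families and their subtype labels."""
    return _load("table4.csv")
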
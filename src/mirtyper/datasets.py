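"""Small reference tables used by the worked examples.

``COHORT_TABLE`` is the receptor-status composition of the 186-tumor
breast-cancer small RNA-seq cohort this package's analyses are modeled
on: patient counts cross-tabulated by intrinsic subtype (Basal-like,
HER2-enriched, Luminal A, Luminal B) and estrogen / HER2 / progesterone
receptor status.  Two of the 186 tumors had too low a correlation to
every subtype centroid to receive a call and are absent from the table,
which therefore totals 184.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["COHORT_TABLE", "cohort_table", "subtype_totals"]

# (subtype, ER, HER2, PR) -> patient count
COHORT_TABLE: list[tuple[str, str, str, str, int]] = [
    ("Basal", "ER-", "HER2-", "PR-", 45),
    ("Basal", "ER-", "HER2+", "PR-", 4),
    ("Her2",  "ER-", "HER2-", "PR-", 1),
    ("Her2",  "ER-", "HER2+", "PR-", 29),
    ("Her2",  "ER+", "HER2-", "PR-", 1),
    ("Her2",  "ER+", "HER2-", "PR+", 3),
    ("Her2",  "ER+", "HER2+", "PR-", 5),
    ("Her2",  "ER+", "HER2+", "PR+", 3),
    ("LumA",  "ER-", "HER2-", "PR-", 1),
    ("LumA",  "ER+", "HER2-", "PR+", 30),
    ("LumA",  "ER+", "HER2+", "PR+", 9),
    ("LumB",  "ER-", "HER2-", "PR-", 1),
    ("LumB",  "ER+", "HER2-", "PR+", 36),
    ("LumB",  "ER+", "HER2+", "PR-", 4),
    ("LumB",  "ER+", "HER2+", "PR+", 12),
]


def cohort_table() -> pd.DataFrame:
    """The receptor-status table as a tidy DataFrame."""
    return pd.DataFrame(
        COHORT_TABLE, columns=["subtype", "ER", "HER2", "PR", "n"]
    )


def subtype_totals() -> pd.Series:
    """Patient count per intrinsic subtype (sums the receptor rows)."""
    return cohort_table().groupby("subtype")["n"].sum()
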
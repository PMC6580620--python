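"""Nearest-centroid subtype classification with fixed-reference gene
centering, scored against the simulated cohort's true labels."""

import pandas as pd

from common import outdir

from mirtyper import subtype


def main():
    res = outdir("cohort")
    expr = pd.read_csv(res / "expression.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(res / "labels.tsv", sep="\t", index_col=0)["subtype"]
    cents = subtype.CentroidSet(
        pd.read_csv(res / "centroids.tsv", sep="\t", index_col=0))

    calls = subtype.classify_cohort(expr, cents, reference=expr,
                                    metric="spearman", threshold=0.1)
    calls.to_csv(res / "subtype_calls.tsv", sep="\t")
    assigned = calls["label"].notna()
    acc = (calls.loc[assigned, "label"] ==
           labels.reindex(calls.index)[assigned]).mean()
    print(f"{assigned.sum()}/{len(calls)} samples assigned; "
          f"accuracy among assigned: {100 * acc:.1f}%; "
          f"median call margin {calls['margin'].median():.3f}")


if __name__ == "__main__":
    main()
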
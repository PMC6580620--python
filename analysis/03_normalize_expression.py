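"""Normalize counts to log2-CPM (library-scaled pseudo-count 0.25) and
summarise expression complexity over the -5..20 log2-CPM interval."""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from common import FIG_DIR, outdir

from mirtyper import normalize


def main():
    res = outdir("reads")
    FIG_DIR.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(res / "counts.tsv", sep="\t", index_col=0)
    expr = normalize.log2_cpm(counts, prior=0.25)
    expr.values.to_csv(res / "expression.tsv", sep="\t",
                       index_label="mature_id")
    curve = normalize.expressed_counts(expr, lo=-5, hi=20, step=0.5)
    curve.to_csv(res / "complexity.tsv", sep="\t")

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in counts.columns:
        ax.plot(curve.index, curve[c], color="grey", lw=0.8)
    ax.plot(curve.index, curve["mean"], color="black", lw=2, label="mean")
    ax.set_xlabel("log2-CPM threshold")
    ax.set_ylabel("miRNAs expressed above threshold")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG_DIR / "complexity.png", dpi=120)

    n_at_zero = curve.loc[0.0, "mean"]
    print(f"mean miRNAs expressed at log2-CPM >= 0: {n_at_zero:.1f} "
          f"of {len(counts)} annotated")


if __name__ == "__main__":
    main()
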
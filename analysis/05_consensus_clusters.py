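"""Consensus-cluster the cohort on the signature miRNAs, pick k from the
delta-area curve, and test cluster/subtype association by chi-square.
Also cut a row-standardized Euclidean/Ward tree for the heatmap view."""

import pandas as pd

from common import SEED, outdir

from mirtyper import cluster, normalize


def main():
    res = outdir("cohort")
    expr = pd.read_csv(res / "expression.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(res / "labels.tsv", sep="\t", index_col=0)["subtype"]
    sig = pd.read_csv(res / "signature.tsv", sep="\t")["mature_id"]
    X = expr.loc[sig]

    cons = cluster.consensus_cluster(X, max_k=6, reps=200, p_item=0.8,
                                     seed=SEED + 200)
    curve = pd.DataFrame({
        "k": sorted(cons.areas),
        "area": [cons.areas[k] for k in sorted(cons.areas)],
        "delta": [cons.deltas[k] for k in sorted(cons.areas)],
    })
    curve.to_csv(res / "consensus_curve.tsv", sep="\t", index=False)
    k = cluster.select_k(cons)
    lab = cons.labels[k]
    out = pd.DataFrame({"cluster": lab, "item_consensus":
                        cons.item_consensus[k], "subtype": labels})
    out.to_csv(res / "consensus_clusters.tsv", sep="\t",
               index_label="sample_id")
    stat, dof, p, _ = cluster.chi2_enrichment(lab, labels)

    ward = cluster.ward_cluster(normalize.standardize_rows(X),
                                cut_rows=5, cut_cols=4)
    ward.row_labels.to_frame().to_csv(res / "mirna_clusters.tsv", sep="\t",
                                      index_label="mature_id")
    ward.col_labels.to_frame().to_csv(res / "sample_clusters.tsv", sep="\t",
                                      index_label="sample_id")

    print(f"delta-area curve:\n{curve.to_string(index=False)}")
    print(f"selected k={k}; subtype enrichment chi2={stat:.1f} "
          f"(df={dof}, p={p:.3g})")
    print(f"ward cut: {ward.row_labels.nunique()} miRNA clusters, "
          f"{ward.col_labels.nunique()} sample clusters")


if __name__ == "__main__":
    main()
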
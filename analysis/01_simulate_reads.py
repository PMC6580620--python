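"""Simulate a small RNA-seq experiment: toy miRNA annotation plus
name-sorted per-sample alignments with isomiR end offsets, non-templated
3' additions, paralog multi-mappers, and decoy loci."""

import json

from common import ISOMIR_SD, MIN_READS, N_READS, N_SAMPLES, NTA_PROB, READS_DIR, SEED, outdir

from mirtyper import annotation, simulate


def main():
    res = outdir("reads")
    READS_DIR.mkdir(parents=True, exist_ok=True)
    sim = simulate.simulate_annotation(
        n_mirnas=20, n_paralog_groups=2, n_decoy_groups=1, seed=SEED
    )
    annotation.write_mirbase_gff3(sim.ann, res / "annotation.gff3")
    truths = {}
    for i in range(N_SAMPLES):
        sam = READS_DIR / f"sample{i + 1}.sam"
        _, truth = simulate.simulate_alignments(
            sim, n_reads=N_READS, isomir_sd=ISOMIR_SD, nta_prob=NTA_PROB,
            seed=SEED + 1 + i, sample_id=sam.stem, sam_path=sam,
        )
        truth.true_counts.to_csv(res / f"truth_{sam.stem}.tsv", sep="\t",
                                 header=["true_count"])
        truths[sam.stem] = int(truth.true_counts.sum())
    meta = {
        "n_mirnas": len(sim.ann.matures),
        "paralog_matures": sim.paralog_ids,
        "decoy_groups": sim.decoy_groups,
        "reads_per_sample": truths,
        "min_reads_qc": MIN_READS,
    }
    (res / "simulation_meta.json").write_text(json.dumps(meta, indent=2))
    print(f"wrote annotation with {meta['n_mirnas']} matures "
          f"({len(sim.paralog_ids)} paralog groups, "
          f"{len(sim.decoy_groups)} decoy pair) and "
          f"{N_SAMPLES} x {N_READS} reads to {READS_DIR}/")


if __name__ == "__main__":
    main()
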
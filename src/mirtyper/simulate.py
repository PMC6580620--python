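"""Synthetic-data generators for every pipeline stage.

Each generator is seed-deterministic and returns its ground truth next to
the data, so recovery can be asserted exactly:

* :func:`simulate_annotation` — toy chromosomes with mature miRNA loci,
  including paralog groups (several loci, one identical mature sequence —
  rescuable multi-mappers) and decoy groups (near-identical but distinct
  sequences — never rescuable).
* :func:`simulate_alignments` — reads drawn from an expression profile
  with discretized Gaussian 5'/3' end offsets (isomiRs) and occasional
  1-3 nt non-templated 3' additions emitted as soft-clips; paralog and
  decoy reads carry all of their genomic alignments.  Output is
  name-sorted SAM.
* :func:`simulate_cohort` — subtype-structured log2-expression matrices
  around per-subtype centroids with planted marker shifts.
* :func:`simulate_survival` — exponential event times with a
  multiplicative group effect and independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import AnnotationSet, GenomicInterval, MatureMiRNA

__all__ = [
    "SimulatedAnnotation",
    "SimulationTruth",
    "CohortTruth",
    "simulate_annotation",
    "simulate_alignments",
    "simulate_cohort",
    "simulate_survival",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

MATURE_LEN = 22
PRECURSOR_LEN = 80
SPACING = 200


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _rna(dna: str, strand: str) -> str:
    s = dna if strand == "+" else _revcomp(dna)
    return s.replace("T", "U")


@dataclass
class SimulatedAnnotation:
    """An AnnotationSet plus the toy genome and group bookkeeping."""

    ann: AnnotationSet
    genome: dict[str, str]
    paralog_ids: list[str]              # matures with >1 locus, one sequence
    decoy_groups: list[tuple[str, str]]  # mature pairs with distinct sequences
    alt_loci: dict[str, list[GenomicInterval]]  # extra alignment sites per mature

    def locus_dna(self, iv: GenomicInterval) -> str:
        return self.genome[iv.chrom][iv.start:iv.end]


def simulate_annotation(
    n_mirnas: int = 20,
    n_paralog_groups: int = 2,
    n_decoy_groups: int = 1,
    seed: int | None = None,
    n_chroms: int = 2,
) -> SimulatedAnnotation:
    """Toy annotation: ``n_mirnas`` matures on ``n_chroms`` chromosomes.

    The first ``n_paralog_groups`` matures each get a second genomic
    locus carrying an identical mature sequence; the next
    ``2 * n_decoy_groups`` matures are paired into decoy groups whose
    sequences differ at one internal base but whose reads co-align.
    Both strands are represented.
    """
    if n_mirnas < n_paralog_groups + 2 * n_decoy_groups:
        raise ValueError("n_mirnas too small for the requested groups")
    rng = np.random.default_rng(seed)
    n_slots = n_mirnas + n_paralog_groups  # paralogs occupy two slots
    per_chrom = -(-n_slots // n_chroms)
    chrom_len = SPACING * (per_chrom + 2)
    genome = {
        f"chr{c + 1}": "".join(rng.choice(_BASES, size=chrom_len))
        for c in range(n_chroms)
    }

    slots: list[GenomicInterval] = []
    for i in range(n_slots):
        chrom = f"chr{i % n_chroms + 1}"
        pos = SPACING * (i // n_chroms) + 50
        strand = "+" if (i // n_chroms) % 2 == 0 else "-"
        slots.append(GenomicInterval(chrom, pos + 10, pos + 10 + MATURE_LEN, strand))

    matures: list[MatureMiRNA] = []
    precursors: dict[str, GenomicInterval] = {}
    precursor_names: dict[str, str] = {}
    alt_loci: dict[str, list[GenomicInterval]] = {}
    paralog_ids: list[str] = []
    decoy_groups: list[tuple[str, str]] = []

    def add_precursor(idx: int, locus: GenomicInterval, suffix: str = "") -> str:
        pid = f"SIM-MI{idx:04d}{suffix}"
        precursors[pid] = GenomicInterval(
            locus.chrom, locus.start - 10, locus.start - 10 + PRECURSOR_LEN,
            locus.strand,
        )
        precursor_names[pid] = f"sim-mir-{idx}{suffix}"
        return pid

    slot_iter = iter(slots)
    mirna_idx = 0

    def plant(locus: GenomicInterval, dna: str) -> None:
        g = genome[locus.chrom]
        genome[locus.chrom] = g[:locus.start] + dna + g[locus.end:]

    # paralog groups: one mature_id, two loci, forced-identical sequence
    for _ in range(n_paralog_groups):
        l1, l2 = next(slot_iter), next(slot_iter)
        l2 = GenomicInterval(l2.chrom, l2.start, l2.end, l1.strand)
        dna = genome[l1.chrom][l1.start:l1.end]
        plant(l2, dna)
        mid = f"SIM-MIMAT{mirna_idx:04d}"
        p1 = add_precursor(mirna_idx, l1, "-1")
        p2 = add_precursor(mirna_idx, l2, "-2")
        matures.append(MatureMiRNA(mid, f"sim-miR-{mirna_idx}", _rna(dna, l1.strand),
                                   [l1, l2], [p1, p2]))
        alt_loci[mid] = []  # both loci already on the record
        paralog_ids.append(mid)
        mirna_idx += 1

    # decoy groups: two matures, sequences differing at one internal base,
    # reads cross-align between the two loci
    for _ in range(n_decoy_groups):
        l1, l2 = next(slot_iter), next(slot_iter)
        l2 = GenomicInterval(l2.chrom, l2.start, l2.end, l1.strand)
        dna1 = genome[l1.chrom][l1.start:l1.end]
        mid_pos = MATURE_LEN // 2
        alt_base = next(b for b in "ACGT" if b != dna1[mid_pos])
        dna2 = dna1[:mid_pos] + alt_base + dna1[mid_pos + 1:]
        plant(l2, dna2)
        ids = []
        for j, (locus, dna) in enumerate(((l1, dna1), (l2, dna2))):
            mid = f"SIM-MIMAT{mirna_idx:04d}"
            pid = add_precursor(mirna_idx, locus)
            matures.append(MatureMiRNA(mid, f"sim-miR-{mirna_idx}",
                                       _rna(dna, locus.strand), [locus], [pid]))
            ids.append(mid)
            mirna_idx += 1
        alt_loci[ids[0]] = [matures[-1].loci[0]]
        alt_loci[ids[1]] = [matures[-2].loci[0]]
        decoy_groups.append((ids[0], ids[1]))

    # plain single-locus matures
    while mirna_idx < n_mirnas:
        locus = next(slot_iter)
        dna = genome[locus.chrom][locus.start:locus.end]
        mid = f"SIM-MIMAT{mirna_idx:04d}"
        pid = add_precursor(mirna_idx, locus)
        matures.append(MatureMiRNA(mid, f"sim-miR-{mirna_idx}",
                                   _rna(dna, locus.strand), [locus], [pid]))
        mirna_idx += 1

    ann = AnnotationSet(matures=matures, precursors=precursors,
                        precursor_names=precursor_names, version_tag="sim")
    return SimulatedAnnotation(ann, genome, paralog_ids, decoy_groups, alt_loci)


@dataclass
class SimulationTruth:
    """Per-read provenance and the true per-mature counts."""

    reads: pd.DataFrame     # read_id, mature_id, d_start, d_end, nta, n_alignments
    true_counts: pd.Series  # per mature_id

    def __post_init__(self) -> None:
        agg = self.reads.groupby("mature_id").size()
        assert self.true_counts[self.true_counts > 0].sort_index().equals(
            agg.sort_index().astype(self.true_counts.dtype)
        ), "true_counts must aggregate the read truths"


def simulate_alignments(
    sim: SimulatedAnnotation,
    n_reads: int = 10_000,
    profile: pd.Series | None = None,
    isomir_sd: float = 1.0,
    nta_prob: float = 0.1,
    max_offset: int = 3,
    seed: int | None = None,
    sample_id: str = "sample",
    sam_path: str | Path | None = None,
) -> tuple[list, SimulationTruth]:
    """Draw reads from the annotation and emit name-sorted alignments.

    ``profile`` gives per-mature expected proportions (uniform when
    omitted); end offsets are round(N(0, isomir_sd)) truncated to
    ±``max_offset``; with probability ``nta_prob`` a 1-3 nt non-templated
    addition is appended at the read 3' end as a soft-clip whose bases
    are guaranteed to mismatch the adjacent genome.  Reads from paralog
    matures are reported at every locus of the shared sequence; decoy
    reads also report their near-identical partner locus.  When
    ``sam_path`` is given a valid name-sorted SAM file is written.
    """
    rng = np.random.default_rng(seed)
    ann = sim.ann
    mature_ids = [m.mature_id for m in ann.matures]
    if profile is None:
        probs = np.full(len(mature_ids), 1.0 / len(mature_ids))
    else:
        probs = profile.reindex(mature_ids).fillna(0.0).to_numpy(dtype=float)
        probs = probs / probs.sum()
    draws = rng.multinomial(n_reads, probs)

    by_id = {m.mature_id: m for m in ann.matures}
    width = len(str(max(n_reads, 1)))
    records: list[dict] = []
    truth_rows: list[dict] = []
    read_no = 0
    for mid, count in zip(mature_ids, draws):
        m = by_id[mid]
        for _ in range(count):
            rid = f"r{read_no:0{width}d}"
            read_no += 1
            if isomir_sd > 0:
                ds = int(np.clip(round(rng.normal(0, isomir_sd)), -max_offset,
                                 max_offset))
                de = int(np.clip(round(rng.normal(0, isomir_sd)), -max_offset,
                                 max_offset))
            else:
                ds = de = 0
            nta = int(rng.integers(1, 4)) if rng.random() < nta_prob else 0
            loci = list(m.loci) + sim.alt_loci.get(mid, [])
            n_aln = len(loci)
            truth_rows.append(dict(read_id=rid, mature_id=mid, d_start=ds,
                                   d_end=de, nta=nta, n_alignments=n_aln))
            for locus in loci:
                start = locus.start + ds
                end = locus.end + de
                if start >= end:
                    end = start + 1
                records.append(dict(read_id=rid, chrom=locus.chrom, start=start,
                                    end=end, strand=locus.strand, nta=nta,
                                    n_alignments=n_aln))

    records.sort(key=lambda r: (r["read_id"], r["chrom"], r["start"]))
    truth_rows.sort(key=lambda r: r["read_id"])
    reads_df = pd.DataFrame(
        truth_rows,
        columns=["read_id", "mature_id", "d_start", "d_end", "nta", "n_alignments"],
    )
    true_counts = pd.Series(draws, index=mature_ids, name=sample_id)
    truth = SimulationTruth(reads=reads_df, true_counts=true_counts)

    if sam_path is not None:
        _write_sam(sim, records, sam_path, rng)
    return records, truth


def as_alignment_records(records: list[dict]):
    """Convert simulated alignment dicts to quantify.AlignmentRecord.

    Non-templated additions are soft-clips and never consume reference,
    so no terminal trimming is needed on the simulated records.
    """
    from .quantify import AlignmentRecord

    return [
        AlignmentRecord(
            read_id=r["read_id"],
            interval=GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
            n_alignments=r["n_alignments"],
        )
        for r in records
    ]


def _write_sam(sim: SimulatedAnnotation, records: list[dict],
               path: str | Path, rng: np.random.Generator) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(sim.genome.items())],
    }
    chrom_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            g = sim.genome[rec["chrom"]]
            span = rec["end"] - rec["start"]
            dna = g[rec["start"]:rec["end"]]
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["read_id"]
            a.reference_id = chrom_ids[rec["chrom"]]
            a.reference_start = rec["start"]
            a.mapping_quality = 0 if rec["n_alignments"] > 1 else 60
            a.flag = 16 if rec["strand"] == "-" else 0
            nta = rec["nta"]
            if nta:
                # 3' addition guaranteed to mismatch the flanking genome
                if rec["strand"] == "+":
                    flank = g[rec["end"]:rec["end"] + nta].ljust(nta, "A")
                    add = "".join(
                        rng.choice([b for b in "ACGT" if b != f]) for f in flank
                    )
                    a.query_sequence = dna + add
                    a.cigarstring = f"{span}M{nta}S"
                else:
                    flank = g[max(0, rec["start"] - nta):rec["start"]].rjust(nta, "A")
                    add = "".join(
                        rng.choice([b for b in "ACGT" if b != f]) for f in flank
                    )
                    a.query_sequence = add + dna
                    a.cigarstring = f"{nta}S{span}M"
            else:
                a.query_sequence = dna
                a.cigarstring = f"{span}M"
            a.set_tag("MD", str(span))
            a.set_tag("NH", rec["n_alignments"])
            out.write(a)


@dataclass
class CohortTruth:
    centroids: pd.DataFrame          # feature x subtype mean matrix
    markers: dict[str, list[str]]    # planted marker features per subtype
    labels: pd.Series                # sample -> subtype


DEFAULT_SUBTYPE_N = {"Basal": 49, "Her2": 42, "LumA": 40, "LumB": 53}


def simulate_cohort(
    n_per_subtype: dict[str, int] | None = None,
    n_features: int = 150,
    n_markers: int = 15,
    marker_shift: float = 3.0,
    sigma: float = 1.0,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    centroids: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Subtype-structured log2-expression cohort around centroids.

    When ``centroids`` (feature x subtype) is given, samples are drawn
    N(centroid, sigma) around it.  Otherwise each subtype's centroid is
    a shared baseline (log2-CPM-like, N(4, 2) per feature) plus
    ``marker_shift`` on its own ``n_markers`` planted marker features.
    Samples add i.i.d. N(0, sigma) noise either way.  The default group
    sizes mirror a four-subtype breast-tumor cohort.
    """
    rng = np.random.default_rng(seed)
    markers: dict[str, list[str]] = {}
    if centroids is not None:
        n_per_subtype = dict(n_per_subtype
                             or {st: DEFAULT_SUBTYPE_N.get(st, 50)
                                 for st in centroids.columns})
        missing = set(n_per_subtype) - set(centroids.columns)
        if missing:
            raise ValueError(f"no centroid for subtype(s): {sorted(missing)}")
        subtypes = sorted(n_per_subtype)
        centroids = centroids.copy()
        feature_names = list(centroids.index)
        n_features = len(feature_names)
    else:
        n_per_subtype = dict(n_per_subtype or DEFAULT_SUBTYPE_N)
        subtypes = sorted(n_per_subtype)
        if n_features < n_markers * len(subtypes):
            raise ValueError("n_features too small for the planted markers")
        if feature_names is None:
            feature_names = [f"sim-miR-{i:03d}" for i in range(n_features)]
        baseline = rng.normal(4.0, 2.0, size=n_features)
        centroids = pd.DataFrame(
            {st: baseline.copy() for st in subtypes}, index=feature_names
        )
        for i, st in enumerate(subtypes):
            idx = list(range(i * n_markers, (i + 1) * n_markers))
            markers[st] = [feature_names[j] for j in idx]
            centroids.loc[markers[st], st] += marker_shift

    cols, labels = {}, {}
    for st in subtypes:
        for j in range(n_per_subtype[st]):
            sid = f"{st}_{j:03d}"
            cols[sid] = centroids[st].to_numpy() + rng.normal(0, sigma, n_features)
            labels[sid] = st
    expr = pd.DataFrame(cols, index=feature_names)
    truth = CohortTruth(centroids=centroids, markers=markers,
                        labels=pd.Series(labels, name="subtype"))
    return expr, truth


def simulate_survival(
    groups: pd.Series,
    baseline_hazard: float = 0.05,
    hazard_ratio: float | dict[str, float] = 1.0,
    censor_rate: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival with a multiplicative group effect.

    ``groups`` maps sample -> group label.  ``hazard_ratio`` is either a
    mapping {label: ratio} or a single float applied to every label
    except the lexicographically first (the reference).  Censoring is an
    independent Exp(``censor_rate``) time; ``censor_rate=0`` observes
    every event.  Time units follow 1/``baseline_hazard``.
    """
    rng = np.random.default_rng(seed)
    levels = sorted(pd.Series(groups).dropna().unique())
    if isinstance(hazard_ratio, dict):
        ratios = {lv: float(hazard_ratio.get(lv, 1.0)) for lv in levels}
    else:
        ratios = {lv: (1.0 if i == 0 else float(hazard_ratio))
                  for i, lv in enumerate(levels)}
    rows = {}
    for sid, g in groups.items():
        h = baseline_hazard * ratios[g]
        t_event = rng.exponential(1.0 / h)
        t_cens = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else np.inf
        rows[sid] = dict(
            time=min(t_event, t_cens),
            event=int(t_event <= t_cens),
            group=g,
        )
    return pd.DataFrame.from_dict(rows, orient="index")
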
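"""Read-to-mature-miRNA counting.

The assignment rule: a read's *effective* genomic interval — its aligned
reference span after trimming any run of mismatching bases at the read
start and end — is compared to every annotated mature locus on the same
strand.  The read matches a locus when |Δstart| + |Δend| <= ``max_dev``
(default 4 nt).  Terminal mismatches and soft-clipped bases are excluded
from the comparison because they typically represent non-templated
nucleotide additions, not genomic position.

Multi-mapping reads are discarded unless every one of their alignments
matches an annotated mature locus and all matched matures carry one
identical mature sequence (true paralogs); such reads are counted once,
toward the lexicographically smallest mature ID.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .annotation import AnnotationSet, GenomicInterval, LocusIndex, MatureLocus

__all__ = [
    "AlignmentRecord",
    "ReadAssignment",
    "QCReport",
    "match_alignment",
    "resolve_read",
    "quantify_sample",
    "quantify_sam",
    "read_sam_records",
]

DEFAULT_MAX_DEV = 4
DEFAULT_MIN_READS = 500_000


@dataclass(frozen=True)
class AlignmentRecord:
    """One genomic alignment of one read.

    ``interval`` is the aligned reference span (soft-clipped bases never
    consume reference and are already outside it).  ``trim_start`` /
    ``trim_end`` count terminal reference bases that mismatch the genome
    (from the MD tag) and are removed before coordinate comparison.
    """

    read_id: str
    interval: GenomicInterval
    trim_start: int = 0
    trim_end: int = 0
    n_alignments: int = 1  # total alignments reported for this read

    def effective_interval(self) -> GenomicInterval | None:
        """Reference span after trimming terminal mismatching bases.

        On the minus strand the read's 5' end is the interval's high
        coordinate; trimming is strand-aware so that ``trim_start``
        always refers to the read start.
        """
        if self.interval.strand == "+":
            s = self.interval.start + self.trim_start
            e = self.interval.end - self.trim_end
        else:
            s = self.interval.start + self.trim_end
            e = self.interval.end - self.trim_start
        if s >= e:
            return None
        return GenomicInterval(self.interval.chrom, s, e, self.interval.strand)


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of resolving one read's alignment group."""

    read_id: str
    status: str  # assigned | unannotated | ambiguous_discard
    mature_id: str | None = None
    total_deviation: int | None = None

    def __post_init__(self) -> None:
        assert (self.status == "assigned") == (self.mature_id is not None)


@dataclass
class QCReport:
    """Per-sample accounting; assigned+unannotated+discarded = reads seen."""

    sample_id: str
    n_reads: int = 0
    n_assigned: int = 0
    n_unannotated: int = 0
    n_discarded: int = 0
    min_reads: int = DEFAULT_MIN_READS

    @property
    def below_threshold(self) -> bool:
        return self.n_reads < self.min_reads


def match_alignment(
    aln: AlignmentRecord, index: LocusIndex, max_dev: int = DEFAULT_MAX_DEV,
    dev_mode: str = "sum",
) -> list[tuple[MatureLocus, int]]:
    """Mature loci within ``max_dev`` total end deviation of the alignment.

    The total deviation combines |Δstart| and |Δend| between the
    effective interval and the annotated locus — their sum by default,
    or their maximum with ``dev_mode="max"``.  Candidates are returned
    sorted by (deviation, mature_id, locus start).
    """
    if dev_mode not in ("sum", "max"):
        raise ValueError(f"dev_mode must be 'sum' or 'max', got {dev_mode!r}")
    eff = aln.effective_interval()
    if eff is None:
        return []
    probe = GenomicInterval(
        eff.chrom, max(0, eff.start - max_dev), eff.end + max_dev, eff.strand
    )
    out = []
    for ml in index.query(probe):
        ds = abs(ml.interval.start - eff.start)
        de = abs(ml.interval.end - eff.end)
        dev = ds + de if dev_mode == "sum" else max(ds, de)
        if dev <= max_dev:
            out.append((ml, dev))
    out.sort(key=lambda t: (t[1], t[0].mature_id, t[0].interval.start))
    return out


def resolve_read(
    alignments: list[AlignmentRecord],
    index: LocusIndex,
    max_dev: int = DEFAULT_MAX_DEV,
    dev_mode: str = "sum",
) -> ReadAssignment:
    """Apply the unique/multi-mapper assignment rule to one read group."""
    if not alignments:
        raise ValueError("empty alignment group")
    read_id = alignments[0].read_id
    if any(a.read_id != read_id for a in alignments):
        raise ValueError("alignment group mixes read_ids")

    per_aln = [match_alignment(a, index, max_dev, dev_mode) for a in alignments]

    if len(alignments) == 1:
        cands = per_aln[0]
        if not cands:
            return ReadAssignment(read_id, "unannotated")
        best_dev = cands[0][1]
        best_ids = {ml.mature_id for ml, d in cands if d == best_dev}
        if len(best_ids) > 1:
            # e.g. overlapping -5p/-3p annotations at equal deviation
            return ReadAssignment(read_id, "ambiguous_discard")
        return ReadAssignment(read_id, "assigned", cands[0][0].mature_id, best_dev)

    # multi-mapper: rescued only if every alignment hits annotation and
    # all matched matures share one identical sequence
    if any(not c for c in per_aln):
        return ReadAssignment(read_id, "ambiguous_discard")
    matched = {ml.mature_id: ml.sequence for cands in per_aln for ml, _ in cands}
    if len(set(matched.values())) != 1:
        return ReadAssignment(read_id, "ambiguous_discard")
    target = min(matched)
    dev = min(d for cands in per_aln for ml, d in cands if ml.mature_id == target)
    return ReadAssignment(read_id, "assigned", target, dev)


def _group_by_read(records: Iterable[AlignmentRecord]) -> Iterator[list[AlignmentRecord]]:
    """Group a name-sorted stream; error if a read_id recurs non-contiguously."""
    seen: set[str] = set()
    group: list[AlignmentRecord] = []
    for rec in records:
        if group and rec.read_id != group[-1].read_id:
            yield group
            group = []
        if not group:
            if rec.read_id in seen:
                raise ValueError(
                    f"read {rec.read_id} is not contiguous in the stream; "
                    "sort the input by read name (samtools sort -n)"
                )
            seen.add(rec.read_id)
        group.append(rec)
    if group:
        yield group


def quantify_sample(
    alignments: Iterable[AlignmentRecord],
    ann: AnnotationSet,
    index: LocusIndex,
    sample_id: str = "sample",
    max_dev: int = DEFAULT_MAX_DEV,
    min_reads: int = DEFAULT_MIN_READS,
    dev_mode: str = "sum",
) -> tuple[pd.Series, QCReport]:
    """Count mature miRNAs in one sample's name-sorted alignment stream.

    Each read contributes at most one count.  The returned Series is
    indexed by every mature_id in ``ann`` (zeros included) so samples
    stack into a matrix; the QC report flags samples below the library
    size threshold.
    """
    counts = {m.mature_id: 0 for m in ann.matures}
    qc = QCReport(sample_id=sample_id, min_reads=min_reads)
    for group in _group_by_read(alignments):
        qc.n_reads += 1
        res = resolve_read(group, index, max_dev, dev_mode)
        if res.status == "assigned":
            counts[res.mature_id] += 1
            qc.n_assigned += 1
        elif res.status == "unannotated":
            qc.n_unannotated += 1
        else:
            qc.n_discarded += 1
    vec = pd.Series(counts, name=sample_id).sort_index()
    return vec, qc


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _terminal_mismatch_runs(md: str) -> tuple[int, int]:
    """Lengths of the mismatch runs at the two ends of the aligned span.

    Parses an MD tag into per-reference-base match/mismatch flags
    (deleted reference bases count as internal, never terminal).
    """
    flags: list[bool] = []  # True = mismatch
    for num, deletion, sub in _MD_TOKEN.findall(md):
        if num:
            flags.extend([False] * int(num))
        elif deletion:
            flags.extend([False] * (len(deletion) - 1))
        else:
            flags.append(True)
    lead = 0
    for f in flags:
        if not f:
            break
        lead += 1
    tail = 0
    for f in reversed(flags):
        if not f:
            break
        tail += 1
    if lead == len(flags):
        tail = 0
    return lead, tail


def read_sam_records(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a (name-sorted) SAM/BAM file.

    Terminal mismatches come from the MD tag when present; without MD only
    soft-clips (which never consume reference) separate non-templated
    additions from genomic bases, so trims default to 0.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for r in fh:
            if r.is_unmapped:
                continue
            strand = "-" if r.is_reverse else "+"
            lead = tail = 0
            if r.has_tag("MD"):
                lead, tail = _terminal_mismatch_runs(str(r.get_tag("MD")))
            # MD runs are in reference orientation; map to read orientation
            trim_start, trim_end = (tail, lead) if r.is_reverse else (lead, tail)
            n_aln = int(r.get_tag("NH")) if r.has_tag("NH") else 1
            yield AlignmentRecord(
                read_id=r.query_name,
                interval=GenomicInterval(
                    r.reference_name, r.reference_start, r.reference_end, strand
                ),
                trim_start=trim_start,
                trim_end=trim_end,
                n_alignments=n_aln,
            )


def quantify_sam(
    paths: list[str | Path],
    ann: AnnotationSet,
    index: LocusIndex,
    max_dev: int = DEFAULT_MAX_DEV,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[pd.DataFrame, list[QCReport]]:
    """Quantify several name-sorted SAM/BAM files into a count matrix.

    Samples flagged below ``min_reads`` are retained in the matrix but
    marked in their QC report; callers decide on exclusion.
    """
    cols, reports = [], []
    for p in paths:
        sid = Path(p).name.rsplit(".", 1)[0]
        vec, qc = quantify_sample(
            read_sam_records(p), ann, index, sample_id=sid,
            max_dev=max_dev, min_reads=min_reads,
        )
        cols.append(vec)
        reports.append(qc)
    return pd.concat(cols, axis=1), reports
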
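"""miRNA annotation handling: parsing, correction, indexing, remapping.

All genomic intervals are stored 0-based half-open internally.  The two
external coordinate dialects this package meets are converted at the
boundary and nowhere else:

* GFF3 (miRBase): 1-based, fully inclusive.  ``[100, 121]`` in GFF3 is
  ``[99, 121)`` internally (length 22).
* TCGA isoform tables: 1-based, half-closed/half-open — the start
  coordinate is included, the end excluded.  ``[100, 122)`` in that
  dialect is ``[99, 121)`` internally.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "MatureMiRNA",
    "AnnotationSet",
    "IsoformRecord",
    "LocusIndex",
    "RemapReport",
    "parse_mirbase_gff3",
    "write_mirbase_gff3",
    "correct_duplicate_ids",
    "build_locus_index",
    "remap_isoforms",
]

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    # -- dialect conversions (each pair is an involution) ------------------

    @classmethod
    def from_gff3(cls, chrom: str, start: int, end: int, strand: str) -> "GenomicInterval":
        """From GFF3 1-based inclusive coordinates."""
        return cls(chrom, start - 1, end, strand)

    def to_gff3(self) -> tuple[int, int]:
        return self.start + 1, self.end

    @classmethod
    def from_tcga(cls, chrom: str, start: int, end: int, strand: str) -> "GenomicInterval":
        """From the TCGA isoform dialect: 1-based, start included, end excluded."""
        return cls(chrom, start - 1, end - 1, strand)

    def to_tcga(self) -> tuple[int, int]:
        return self.start + 1, self.end + 1


@dataclass
class MatureMiRNA:
    """A mature miRNA: one sequence, one or more genomic loci (paralogs)."""

    mature_id: str
    name: str
    sequence: str
    loci: list[GenomicInterval]
    precursor_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sequence) < 14:
            raise AnnotationError(
                f"{self.mature_id}: mature sequence shorter than 14 nt"
            )
        if not self.loci:
            raise AnnotationError(f"{self.mature_id}: no loci")
        for loc in self.loci:
            if len(loc) != len(self.sequence):
                raise AnnotationError(
                    f"{self.mature_id}: locus length {len(loc)} != sequence "
                    f"length {len(self.sequence)}"
                )


@dataclass
class AnnotationSet:
    """Precursor and mature miRNA records for one annotation version."""

    matures: list[MatureMiRNA]
    precursors: dict[str, GenomicInterval]
    precursor_names: dict[str, str] = field(default_factory=dict)
    version_tag: str = "miRBase22"

    def __post_init__(self) -> None:
        ids = [m.mature_id for m in self.matures]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate mature_id values: {dup}")
        for m in self.matures:
            for pid in m.precursor_ids:
                if pid not in self.precursors:
                    raise AnnotationError(
                        f"mature {m.mature_id} references unknown precursor {pid}"
                    )

    def mature_by_id(self, mature_id: str) -> MatureMiRNA:
        for m in self.matures:
            if m.mature_id == mature_id:
                return m
        raise KeyError(mature_id)


@dataclass
class IsoformRecord:
    """One isoform-level quantification row from an external table."""

    sample_id: str
    interval: GenomicInterval
    read_count: int
    source_mature_id: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise AnnotationError("read_count must be non-negative")


# ---------------------------------------------------------------------------
# GFF3 reading / writing
# ---------------------------------------------------------------------------

_REQUIRED_TYPES = {"miRNA_primary_transcript", "miRNA"}


def _prescan_gff3(path: Path) -> None:
    """Reject malformed lines before handing the file to gffutils.

    gffutils reports parse failures without positional context; the
    pre-scan names the offending line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if cols[2] not in _REQUIRED_TYPES:
                continue
            for item in cols[8].split(";"):
                item = item.strip()
                if item and "=" not in item:
                    raise AnnotationError(
                        f"{path}:{lineno}: malformed attribute {item!r} "
                        "(expected key=value)"
                    )


def parse_mirbase_gff3(
    path: str | Path,
    sequences: dict[str, str] | None = None,
    version_tag: str = "miRBase22",
) -> AnnotationSet:
    """Parse a miRBase-dialect GFF3 into an :class:`AnnotationSet`.

    miRBase GFF3 carries no sequences, so mature sequences are either
    looked up in ``sequences`` (mature ID -> RNA string) or, when absent,
    synthesised as a placeholder of the correct locus length.  Mature
    features attach to precursors via ``Derives_from``; matures sharing an
    ID are merged into one record with multiple loci (paralogs sharing one
    mature sequence, e.g. let-7a-5p).
    """
    path = Path(path)
    _prescan_gff3(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    precursors: dict[str, GenomicInterval] = {}
    precursor_names: dict[str, str] = {}
    for f in db.features_of_type("miRNA_primary_transcript"):
        pid = f.attributes["ID"][0]
        iv = GenomicInterval.from_gff3(f.seqid, f.start, f.end, f.strand)
        if pid in precursors and precursors[pid] != iv:
            # release-22-style error: one ID on distinct primary loci.
            # Park the extra locus under a provisional key; resolved by
            # correct_duplicate_ids.
            n = 2
            while f"{pid}__dup{n}" in precursors:
                n += 1
            key = f"{pid}__dup{n}"
        else:
            key = pid
        precursors[key] = iv
        precursor_names[key] = f.attributes.get("Name", [pid])[0]

    by_id: dict[str, MatureMiRNA] = {}
    for f in db.features_of_type("miRNA"):
        mid = f.attributes["ID"][0]
        name = f.attributes.get("Name", [mid])[0]
        derives = f.attributes.get("Derives_from", [None])[0]
        if derives is None or derives not in precursors:
            raise AnnotationError(
                f"mature {mid} has unknown Derives_from ({derives!r})"
            )
        locus = GenomicInterval.from_gff3(f.seqid, f.start, f.end, f.strand)
        if mid in by_id:
            rec = by_id[mid]
            rec.loci.append(locus)
            rec.precursor_ids.append(derives)
            if len(locus) != len(rec.sequence):
                raise AnnotationError(
                    f"{mid}: paralog loci of unequal length"
                )
        else:
            if sequences and mid in sequences:
                seq = sequences[mid].upper().replace("T", "U")
            else:
                seq = "N" * len(locus)
            by_id[mid] = MatureMiRNA(
                mature_id=mid,
                name=name,
                sequence=seq,
                loci=[locus],
                precursor_ids=[derives],
            )

    return AnnotationSet(
        matures=list(by_id.values()),
        precursors=precursors,
        precursor_names=precursor_names,
        version_tag=version_tag,
    )


def write_mirbase_gff3(ann: AnnotationSet, path: str | Path) -> None:
    """Serialise an :class:`AnnotationSet` back to miRBase-dialect GFF3."""
    lines = ["##gff-version 3", f"# {ann.version_tag}"]
    for pid in sorted(ann.precursors, key=lambda p: (ann.precursors[p].chrom,
                                                     ann.precursors[p].start, p)):
        iv = ann.precursors[pid]
        s, e = iv.to_gff3()
        name = ann.precursor_names.get(pid, pid)
        lines.append(
            f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{s}\t{e}\t.\t"
            f"{iv.strand}\t.\tID={pid};Name={name}"
        )
    for m in sorted(ann.matures, key=lambda m: m.mature_id):
        for iv, pid in zip(m.loci, m.precursor_ids):
            s, e = iv.to_gff3()
            lines.append(
                f"{iv.chrom}\t.\tmiRNA\t{s}\t{e}\t.\t{iv.strand}\t.\t"
                f"ID={m.mature_id};Name={m.name};Derives_from={pid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Duplicate-ID correction
# ---------------------------------------------------------------------------

def correct_duplicate_ids(ann: AnnotationSet) -> AnnotationSet:
    """Disambiguate IDs assigned to distinct loci (e.g. the release-22
    mir-4477a/mir-4477b/mir-10401 precursor errors).

    Any precursor ID (or precursor Name) shared by features at distinct
    genomic loci gets a deterministic ``-1``, ``-2``, ... suffix in
    (chrom, start) order.  Mature records referencing the renamed
    precursors are updated; everything else is returned unchanged.
    """
    def base_id(pid: str) -> str:
        return pid.split("__dup")[0]

    # Group by Name: distinct legitimate paralog precursors carry distinct
    # names (mir-125b-1 vs mir-125b-2); one Name on several distinct loci
    # is the annotation error to repair.
    by_name: dict[str, list[str]] = {}
    for pid in ann.precursors:
        by_name.setdefault(ann.precursor_names.get(pid, base_id(pid)), []).append(pid)

    rename: dict[str, tuple[str, str]] = {}  # old key -> (new pid, new name)
    for name, pids in by_name.items():
        loci = {ann.precursors[p] for p in pids}
        if len(pids) > 1 and len(loci) > 1:
            ordered = sorted(pids, key=lambda p: (ann.precursors[p].chrom,
                                                  ann.precursors[p].start, p))
            for i, pid in enumerate(ordered, start=1):
                rename[pid] = (f"{base_id(pid)}-{i}", f"{name}-{i}")

    if not rename:
        return ann

    new_prec: dict[str, GenomicInterval] = {}
    new_names: dict[str, str] = {}
    for pid, iv in ann.precursors.items():
        npid, nname = rename.get(pid, (pid, ann.precursor_names.get(pid, pid)))
        if npid in new_prec:
            raise AnnotationError(f"suffixing produced a collision on {npid}")
        new_prec[npid] = iv
        new_names[npid] = nname
    new_matures = [
        replace(
            m,
            loci=list(m.loci),
            precursor_ids=[rename.get(p, (p, ""))[0] for p in m.precursor_ids],
        )
        for m in ann.matures
    ]

    # Mature IDs shared across loci within one record are the paralog case
    # (legitimate); distinct records cannot share an ID by AnnotationSet's
    # invariant, so precursor renaming is the whole correction.
    return AnnotationSet(
        matures=new_matures,
        precursors=new_prec,
        precursor_names=new_names,
        version_tag=ann.version_tag + "+idfix",
    )


# ---------------------------------------------------------------------------
# Locus index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureLocus:
    """One indexed mature locus (a mature may own several)."""

    mature_id: str
    sequence: str
    interval: GenomicInterval


class LocusIndex:
    """Strand-aware interval index over all mature loci.

    One interval tree per (chrom, strand); query cost O(log n + hits).
    """

    def __init__(self, loci: Iterable[MatureLocus]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self.loci = list(loci)
        for ml in self.loci:
            key = (ml.interval.chrom, ml.interval.strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                ml.interval.start, ml.interval.end, ml
            )

    def query(self, interval: GenomicInterval) -> list[MatureLocus]:
        """All mature loci overlapping ``interval`` on the same strand."""
        tree = self._trees.get((interval.chrom, interval.strand))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        hits.sort(key=lambda ml: (ml.interval.start, ml.interval.end, ml.mature_id))
        return hits


def build_locus_index(ann: AnnotationSet) -> LocusIndex:
    return LocusIndex(
        MatureLocus(m.mature_id, m.sequence, iv)
        for m in ann.matures
        for iv in m.loci
    )


# ---------------------------------------------------------------------------
# Cross-version isoform remapping
# ---------------------------------------------------------------------------

@dataclass
class RemapReport:
    """Mass accounting for :func:`remap_isoforms`."""

    assigned_reads: int = 0
    dropped_no_match: int = 0
    dropped_ambiguous: int = 0
    n_records: int = 0
    n_assigned_records: int = 0

    @property
    def total_reads(self) -> int:
        return self.assigned_reads + self.dropped_no_match + self.dropped_ambiguous


def remap_isoforms(
    records: list[IsoformRecord],
    target: AnnotationSet,
    max_dev: int = 4,
    index: LocusIndex | None = None,
) -> tuple[pd.DataFrame, RemapReport]:
    """Reassign isoform read counts to mature miRNAs of ``target``.

    A record matches a mature locus when strand and chromosome agree and
    |Δstart| + |Δend| <= ``max_dev``.  Multiple matches resolve to the
    minimal-deviation locus; exact deviation ties between distinct matures
    drop the record.  Returns a mature × sample count matrix plus a report
    whose categories conserve the input read mass.
    """
    if max_dev < 0:
        raise ValueError("max_dev must be non-negative")
    if index is None:
        index = build_locus_index(target)

    report = RemapReport(n_records=len(records))
    counts: dict[tuple[str, str], int] = {}
    samples: list[str] = []
    for rec in records:
        if rec.sample_id not in samples:
            samples.append(rec.sample_id)
        iv = rec.interval
        # widen the query so near-miss loci within max_dev are visible
        probe = GenomicInterval(iv.chrom, max(0, iv.start - max_dev),
                                iv.end + max_dev, iv.strand)
        best: list[MatureLocus] = []
        best_dev = max_dev + 1
        for ml in index.query(probe):
            dev = abs(ml.interval.start - iv.start) + abs(ml.interval.end - iv.end)
            if dev < best_dev:
                best, best_dev = [ml], dev
            elif dev == best_dev:
                best.append(ml)
        matched_ids = sorted({ml.mature_id for ml in best})
        if best_dev > max_dev or not matched_ids:
            report.dropped_no_match += rec.read_count
        elif len(matched_ids) > 1:
            report.dropped_ambiguous += rec.read_count
        else:
            key = (matched_ids[0], rec.sample_id)
            counts[key] = counts.get(key, 0) + rec.read_count
            report.assigned_reads += rec.read_count
            report.n_assigned_records += 1

    mature_ids = sorted(m.mature_id for m in target.matures)
    mat = pd.DataFrame(0, index=mature_ids, columns=samples, dtype=int)
    for (mid, sid), c in counts.items():
        mat.loc[mid, sid] = c
    return mat, report
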
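"""Transcript annotation model and positional queries.

All coordinates are internal 0-based half-open; GTF input/output converts
at the boundary (GTF is 1-based inclusive). The 3' end (TES) of a
transcript is the coordinate one past the last transcribed base in
transcription direction: on the + strand this is the span end, on the
- strand the span start. With this convention the k-th downstream window
is a simple offset of the TES on either strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation input or inconsistent transcripts."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon-structured stranded transcript with a defined 3' end."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    source_line_span: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons on mixed "
                    "chromosomes or strands"
                )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        merged = _merge_overlapping(self.exons)
        if len(merged) < len(self.exons):
            logger.warning(
                "transcript %s: merged %d overlapping exon(s)",
                self.transcript_id,
                len(self.exons) - len(merged),
            )
            self.exons = merged

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def tes(self) -> int:
        """3' end: one past the last transcribed base in transcription direction."""
        return self.span.end if self.strand == "+" else self.span.start


def _merge_overlapping(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for ex in exons:
        if out and ex.start < out[-1].end:
            prev = out.pop()
            ex = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, ex.end), prev.strand
            )
        out.append(ex)
    return out


class AnnotationSet:
    """Collection of transcripts with a per-(chrom, strand) interval index."""

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel],
        chrom_sizes: Optional[dict[str, int]] = None,
    ) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        self._index: Optional[dict[tuple[str, str], IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(
            (self.transcripts[tid] for tid in transcript_ids),
            chrom_sizes=self.chrom_sizes,
        )

    def _build_index(self) -> dict[tuple[str, str], IntervalTree]:
        if self._index is None:
            index: dict[tuple[str, str], IntervalTree] = {}
            for t in self:
                tree = index.setdefault((t.chrom, t.strand), IntervalTree())
                tree.addi(t.span.start, t.span.end, t.transcript_id)
            self._index = index
        return self._index

    def overlapping(
        self, chrom: str, strand: str, start: int, end: int
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end) on (chrom, strand)."""
        tree = self._build_index().get((chrom, strand))
        if tree is None or start >= end:
            return []
        return [self.transcripts[iv.data] for iv in tree.overlap(start, end)]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str, chrom_sizes: Optional[dict[str, int]] = None) -> AnnotationSet:
    """Parse exon features of a GTF file into an :class:`AnnotationSet`.

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open. Non-exon features and ``#`` comment lines are skipped.
    Exon features must carry ``transcript_id`` and ``gene_id`` attributes.
    """
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    gene_by_tid: dict[str, str] = {}
    lines_by_tid: dict[str, list[int]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields
            )
            if feature != "exon":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if strand not in STRANDS:
                raise AnnotationError(f"{path}:{lineno}: invalid strand {strand!r}")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise AnnotationError(
                    f"{path}:{lineno}: exon feature missing transcript_id "
                    "or gene_id attribute"
                )
            try:
                iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            exons_by_tid.setdefault(tid, []).append(iv)
            gene_by_tid[tid] = gid
            lines_by_tid.setdefault(tid, []).append(lineno)

    if n_lines == 0:
        logger.warning("%s: no feature lines found; annotation is empty", path)

    transcripts = []
    for tid, exons in exons_by_tid.items():
        lines = lines_by_tid[tid]
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_by_tid[tid],
                    chrom=exons[0].chrom,
                    strand=exons[0].strand,
                    exons=exons,
                    source_line_span=f"{path}:{min(lines)}-{max(lines)}",
                )
            )
        except AnnotationError as exc:
            raise AnnotationError(str(exc)) from None
    return AnnotationSet(transcripts, chrom_sizes=chrom_sizes)


def write_gtf(ann: AnnotationSet, path: str, source: str = "readthrough") -> None:
    """Write exon features back to GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for t in sorted(ann, key=lambda t: (t.chrom, t.span.start, t.transcript_id)):
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column chrom<TAB>length file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 'chrom<TAB>length'"
                )
            sizes[parts[0]] = int(parts[1])
    return sizes


def downstream_clearance(
    t: TranscriptModel, ann: AnnotationSet, distance: int
) -> bool:
    """True iff no other same-strand transcript overlaps the ``distance`` nt
    immediately downstream of ``t``'s 3' end.

    Downstream means increasing coordinates on +, decreasing on -. Signal is
    strand-specific, so opposite-strand neighbors are ignored, as are
    same-gene transcripts sharing the identical 3' end.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if t.transcript_id not in ann or ann[t.transcript_id] is not t:
        if t.transcript_id not in ann:
            raise AnnotationError(
                f"transcript {t.transcript_id} not in annotation set"
            )
    if t.strand == "+":
        start, end = t.tes, t.tes + distance
    else:
        start, end = max(0, t.tes - distance), t.tes
    for other in ann.overlapping(t.chrom, t.strand, start, end):
        if other.transcript_id == t.transcript_id:
            continue
        if other.gene_id == t.gene_id and other.tes == t.tes:
            continue
        return False
    return True
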
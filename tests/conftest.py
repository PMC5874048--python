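"""Shared builders: toy annotations, sparse coverage, genome mirroring."""

from __future__ import annotations

import numpy as np
import pytest

from readthrough import (
    AnnotationSet,
    GenomicInterval,
    StrandedCoverage,
    TranscriptModel,
)


def make_transcript(
    tid="T1",
    gene="G1",
    chrom="chr1",
    strand="+",
    exons=((0, 100), (200, 300)),
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


def coverage_from_dict(values: dict[tuple[str, str, int], float]) -> StrandedCoverage:
    """Coverage from {(chrom, strand, position): value}; everything else 0."""
    dense: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand, pos), v in values.items():
        key = (chrom, strand)
        size = max(pos + 1, dense[key].size if key in dense else 0)
        if key not in dense or dense[key].size < size:
            grown = np.zeros(size)
            if key in dense:
                grown[: dense[key].size] = dense[key]
            dense[key] = grown
        dense[key][pos] = v
    return StrandedCoverage.from_dense(dense)


def brute_force_interval_sum(
    values: dict[tuple[str, str, int], float], iv: GenomicInterval
) -> float:
    """Independent per-base oracle for interval sums."""
    return sum(
        v
        for (chrom, strand, pos), v in values.items()
        if chrom == iv.chrom and strand == iv.strand and iv.start <= pos < iv.end
    )


def mirror_annotation(ann: AnnotationSet, length: int) -> AnnotationSet:
    """Reflect every transcript through pos -> length - pos, swapping strands."""
    flipped = {"+": "-", "-": "+"}
    out = []
    for t in ann:
        strand = flipped[t.strand]
        exons = [
            GenomicInterval(t.chrom, length - e.end, length - e.start, strand)
            for e in t.exons
        ]
        out.append(
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=strand,
                exons=exons,
            )
        )
    sizes = dict(ann.chrom_sizes) if ann.chrom_sizes else None
    return AnnotationSet(out, chrom_sizes=sizes)


def mirror_coverage(cov: StrandedCoverage, chrom: str, length: int) -> StrandedCoverage:
    """Reflect coverage through pos -> length - pos, swapping strands."""
    runs = {}
    for src, dst in (("+", "-"), ("-", "+")):
        starts, ends, values = cov.runs(chrom, src)
        runs[(chrom, dst)] = (
            (length - ends)[::-1].copy(),
            (length - starts)[::-1].copy(),
            values[::-1].copy(),
        )
    return StrandedCoverage.from_runs(runs)


@pytest.fixture
def toy_gtf(tmp_path):
    """Two-exon + transcript (1..100, 201..300) and a minus-strand one."""
    path = tmp_path / "toy.gtf"
    path.write_text(
        "# comment line\n"
        'chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        'chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        'chr1\ttest\tgene\t1\t300\t.\t+\t.\tgene_id "G1";\n'
        'chr1\ttest\texon\t501\t600\t.\t-\t.\tgene_id "G2"; transcript_id "T2";\n'
        'chr1\ttest\texon\t701\t800\t.\t-\t.\tgene_id "G2"; transcript_id "T2";\n'
    )
    return str(path)
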
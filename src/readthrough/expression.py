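"""Coverage-based TPM and the transcript selection filter.

TPM is computed from per-base exonic coverage rather than read counts: the
pipeline's canonical input is a coverage track, so the per-transcript rate
is exonic signal divided by exonic length, normalized so rates sum to one
million. This diverges from count-based TPM only by the constant relating
signal units to fragments, which cancels in the normalization.

The selection filter keeps highly expressed (TPM strictly above the
threshold), spliced transcripts whose downstream windows are clear of other
same-strand transcription; every exclusion is recorded with a reason.
"""

from __future__ import annotations

import pandas as pd

from .config import PipelineConfig
from .coverage import StrandedCoverage
from .genome import AnnotationSet, downstream_clearance


def compute_tpm(ann: AnnotationSet, cov: StrandedCoverage) -> dict[str, float]:
    """Per-transcript TPM from exonic coverage.

    rate_t = exonic_signal_t / exonic_length_t; TPM_t = 10^6 * rate_t / sum(rates).
    All-zero coverage yields TPM 0 everywhere.
    """
    if len(ann) == 0:
        raise ValueError("annotation set is empty")
    rates = {}
    for t in ann:
        signal = sum(cov.interval_sum(ex) for ex in t.exons)
        rates[t.transcript_id] = signal / t.exonic_length
    total = sum(rates.values())
    if total == 0:
        return {tid: 0.0 for tid in rates}
    return {tid: rate / total * 1e6 for tid, rate in rates.items()}


def exonic_signal(ann: AnnotationSet, cov: StrandedCoverage) -> dict[str, float]:
    """Summed per-base signal over each transcript's exons (its strand)."""
    return {
        t.transcript_id: sum(cov.interval_sum(ex) for ex in t.exons) for t in ann
    }


def filter_transcripts(
    ann: AnnotationSet, tpm: dict[str, float], cfg: PipelineConfig
) -> tuple[AnnotationSet, pd.DataFrame]:
    """Apply the selection filter; return (retained subset, audit table).

    A transcript is retained iff TPM > threshold (strict), it is spliced
    (when required), and its downstream clearance window holds no other
    same-strand transcript. The audit table records one row per transcript
    with the first failing rule as ``exclusion_reason``
    (expression > monoexonic > clearance).
    """
    missing = [t.transcript_id for t in ann if t.transcript_id not in tpm]
    if missing:
        raise ValueError(f"tpm map missing transcripts: {missing[:5]}")
    rows = []
    retained_ids = []
    for t in ann:
        reason = ""
        if not tpm[t.transcript_id] > cfg.tpm_threshold:
            reason = "expression"
        elif cfg.require_spliced and not t.spliced:
            reason = "monoexonic"
        elif not downstream_clearance(t, ann, cfg.clearance):
            reason = "clearance"
        if not reason:
            retained_ids.append(t.transcript_id)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "exonic_length": t.exonic_length,
                "tpm": tpm[t.transcript_id],
                "retained": not reason,
                "exclusion_reason": reason,
            }
        )
    table = pd.DataFrame(rows).sort_values("transcript_id", ignore_index=True)
    return ann.subset(retained_ids), table
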
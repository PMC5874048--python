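"""Windowed, terminal-normalized read-through profiles and meta-gene curves.

The statistic anchors every transcript at its 3' end (TES), sums
strand-specific signal in K contiguous W-nt genomic windows placed directly
downstream, and normalizes each window by the signal in the last W nt of
the transcript (the terminal reference window). Failed termination leaves
RNA downstream of the TES, so the normalized downstream profile rises when
5'->3' torpedo degradation (XRN2) is lost, while gene-body levels — which
the terminal window captures — are unchanged by construction of the ratio.

Windows are genomic: they are placed on chromosome coordinates regardless
of the exon structure of other isoforms, and the terminal window is taken
on the transcript's genomic span. Two aggregation modes are provided:
``mean_of_ratios`` averages per-transcript normalized profiles;
``pooled_ratio`` sums window signal across transcripts and divides by the
summed terminal signal (cumulative-signal reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .coverage import StrandedCoverage
from .genome import GenomicInterval, TranscriptModel


@dataclass
class TranscriptProfile:
    """One transcript's downstream window signals and their normalization."""

    transcript_id: str
    terminal_signal: float
    window_signals: np.ndarray  # raw signal per downstream window, k = 1..K
    normalized: Optional[np.ndarray]  # window_signals / terminal_signal
    valid: bool
    reason: str = ""  # why invalid: "terminal-floor" or "window-bounds"


@dataclass
class MetaGeneProfile:
    """Cross-transcript aggregate per downstream window position."""

    condition: str
    replicate: str
    mean: np.ndarray  # per window k
    sd: np.ndarray
    n_transcripts: int
    mode: str  # aggregation mode tag
    window_size: int = 250


@dataclass
class ConditionComparison:
    """Per-window contrast of two conditions (B - A) with bootstrap CIs."""

    diff: np.ndarray
    ratio: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_bootstrap: int
    seed: int


def place_windows(
    t: TranscriptModel,
    cfg: PipelineConfig,
    side: str = "downstream",
    chrom_length: Optional[int] = None,
) -> Optional[list[GenomicInterval]]:
    """Genomic windows anchored at the transcript's 3' end.

    ``side="downstream"``: K contiguous W-nt windows starting at the TES,
    ordered by increasing distance from it, on the transcript's strand
    (increasing coordinates on +, decreasing on -).
    ``side="terminal"``: the single W-nt window immediately inside the
    transcript span, adjacent to the 3' end.

    Returns ``None`` when a window would extend beyond position 0, past the
    chromosome end (when known), or — for the terminal window — when the
    transcript span is shorter than W; callers flag the transcript invalid.
    """
    W, K = cfg.window_size, cfg.n_windows
    span = t.span
    if side == "terminal":
        if span.length < W:
            return None
        if t.strand == "+":
            return [GenomicInterval(t.chrom, span.end - W, span.end, "+")]
        return [GenomicInterval(t.chrom, span.start, span.start + W, "-")]
    if side != "downstream":
        raise ValueError(f"unknown side {side!r}")
    if t.strand == "+":
        lo, hi = t.tes, t.tes + K * W
    else:
        lo, hi = t.tes - K * W, t.tes
    if lo < 0 or (chrom_length is not None and hi > chrom_length):
        return None
    if t.strand == "+":
        return [
            GenomicInterval(t.chrom, t.tes + (k - 1) * W, t.tes + k * W, "+")
            for k in range(1, K + 1)
        ]
    return [
        GenomicInterval(t.chrom, t.tes - k * W, t.tes - (k - 1) * W, "-")
        for k in range(1, K + 1)
    ]


def transcript_profile(
    t: TranscriptModel,
    cov: StrandedCoverage,
    cfg: PipelineConfig,
    chrom_length: Optional[int] = None,
) -> TranscriptProfile:
    """Window signals downstream of the TES, normalized to the terminal window.

    Transcripts whose terminal signal falls below the floor are flagged
    invalid with reason ``terminal-floor`` (the ratio would be unstable);
    transcripts whose windows leave the chromosome get ``window-bounds``.
    """
    K = cfg.n_windows
    terminal = place_windows(t, cfg, side="terminal", chrom_length=chrom_length)
    downstream = place_windows(t, cfg, side="downstream", chrom_length=chrom_length)
    if terminal is None or downstream is None:
        return TranscriptProfile(
            transcript_id=t.transcript_id,
            terminal_signal=float("nan"),
            window_signals=np.full(K, np.nan),
            normalized=None,
            valid=False,
            reason="window-bounds",
        )
    terminal_signal = cov.interval_sum(terminal[0])
    window_signals = np.array([cov.interval_sum(iv) for iv in downstream])
    if terminal_signal < cfg.terminal_floor:
        return TranscriptProfile(
            transcript_id=t.transcript_id,
            terminal_signal=terminal_signal,
            window_signals=window_signals,
            normalized=None,
            valid=False,
            reason="terminal-floor",
        )
    return TranscriptProfile(
        transcript_id=t.transcript_id,
        terminal_signal=terminal_signal,
        window_signals=window_signals,
        normalized=window_signals / terminal_signal,
        valid=True,
    )


def _valid(profiles: Iterable[TranscriptProfile]) -> list[TranscriptProfile]:
    return [p for p in profiles if p.valid]


def metagene_profile(
    profiles: Sequence[TranscriptProfile],
    cfg: PipelineConfig,
    condition: str = "",
    replicate: str = "",
) -> MetaGeneProfile:
    """Aggregate per-transcript profiles into one meta-gene curve.

    ``mean_of_ratios``: per window, arithmetic mean and SD of the normalized
    values across valid transcripts. ``pooled_ratio``: per window, summed
    raw window signal divided by summed terminal signal (SD not defined,
    reported as 0).
    """
    valid = _valid(profiles)
    if not valid:
        raise ValueError("no analyzable transcripts")
    if cfg.aggregation == "mean_of_ratios":
        mat = np.vstack([p.normalized for p in valid])
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1) if len(valid) > 1 else np.zeros(mat.shape[1])
    else:
        windows = np.vstack([p.window_signals for p in valid]).sum(axis=0)
        terminal = sum(p.terminal_signal for p in valid)
        mean = windows / terminal
        sd = np.zeros_like(mean)
    return MetaGeneProfile(
        condition=condition,
        replicate=replicate,
        mean=mean,
        sd=sd,
        n_transcripts=len(valid),
        mode=cfg.aggregation,
        window_size=cfg.window_size,
    )


def compare_conditions(
    profiles_a: Sequence[TranscriptProfile],
    profiles_b: Sequence[TranscriptProfile],
    cfg: PipelineConfig,
) -> ConditionComparison:
    """Per-window mean difference (B - A) with a bootstrap 95% CI.

    Transcripts are resampled with replacement within each condition
    (n_bootstrap draws, seeded from ``cfg.seed``); the CI is the 2.5/97.5
    percentile of the resampled difference of mean-of-ratios means.
    """
    va, vb = _valid(profiles_a), _valid(profiles_b)
    if not va or not vb:
        raise ValueError("no analyzable transcripts in one of the conditions")
    mat_a = np.vstack([p.normalized for p in va])
    mat_b = np.vstack([p.normalized for p in vb])
    mean_a, mean_b = mat_a.mean(axis=0), mat_b.mean(axis=0)
    diff = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_a > 0, mean_b / mean_a, np.nan)
    rng = np.random.default_rng(cfg.seed)
    boot = np.empty((cfg.n_bootstrap, diff.size))
    for i in range(cfg.n_bootstrap):
        ia = rng.integers(0, len(va), size=len(va))
        ib = rng.integers(0, len(vb), size=len(vb))
        boot[i] = mat_b[ib].mean(axis=0) - mat_a[ia].mean(axis=0)
    ci_lo = np.percentile(boot, 2.5, axis=0)
    ci_hi = np.percentile(boot, 97.5, axis=0)
    return ConditionComparison(
        diff=diff,
        ratio=ratio,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        n_bootstrap=cfg.n_bootstrap,
        seed=cfg.seed,
    )
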
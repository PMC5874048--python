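"""Synthetic stranded annotations and coverage with known read-through.

The generative model mirrors the study design the pipeline targets:
spliced transcripts with strand-specific exonic coverage, sequenced in
replicate per condition, plus a condition-dependent read-through signal
decaying downstream of each transcript's 3' end. Expected per-base
coverage is

    c_t                       on exonic positions of transcript t,
    alpha * c_t * exp(-d/lambda)  at distance d in [0, D_max) downstream
                                  of t's TES on t's strand,
    beta                      elsewhere (background, both strands),

with per-transcript expression c_t drawn log-normally and realized values
Poisson-distributed around the expectation. ``alpha`` (the read-through
fraction) is the condition knob: near 0 for wild-type termination, large
when the torpedo nuclease is inactive. ``expected_metagene`` is the exact
closed form of the noiseless normalized window value under continuous
exponential decay, used as the analytic oracle for recovery tests.

Transcripts are packed left-to-right with same-strand downstream gaps at
least ``intergenic_min_gap``, so downstream windows never hit neighboring
transcription; margins of K*W are kept at both chromosome ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage
from .genome import AnnotationSet, GenomicInterval, TranscriptModel


@dataclass
class SimulationParams:
    """Generative parameters; defaults describe the emulated study design."""

    n_transcripts: int = 200
    chrom_length: int = 4_000_000
    chrom: str = "chrS"
    exon_count_range: tuple[int, int] = (1, 5)
    spliced_fraction: float = 0.8
    exon_length_range: tuple[int, int] = (300, 1200)
    intron_length_range: tuple[int, int] = (100, 500)
    expression_log_mean: float = 3.0  # log-scale mean of per-base coverage c_t
    expression_log_sd: float = 1.0
    readthrough_fraction: float = 0.05  # alpha; default mimics wild-type
    decay_length: float = 1000.0  # lambda, nt
    readthrough_extent: int = 5000  # D_max, nt
    background: float = 0.0  # beta, per-base
    intergenic_min_gap: int = 6000
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.readthrough_fraction <= 1.0:
            raise ValueError("readthrough_fraction must be in [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.intergenic_min_gap < 1:
            raise ValueError("intergenic_min_gap must be >= 1")

    @property
    def max_span(self) -> int:
        lo_n, hi_n = self.exon_count_range
        return hi_n * self.exon_length_range[1] + (hi_n - 1) * self.intron_length_range[1]


@dataclass
class SimulationTruth:
    """Ground truth for every generated transcript, for recovery tests."""

    table: pd.DataFrame  # transcript_id, c_t, strand, tes, alpha, lam
    seed: int
    params: SimulationParams

    def c_t(self, transcript_id: str) -> float:
        row = self.table.loc[self.table.transcript_id == transcript_id]
        return float(row.c_t.iloc[0])


def simulate_annotation(
    params: SimulationParams,
) -> tuple[AnnotationSet, SimulationTruth]:
    """Deterministically generate a packed, stranded toy annotation.

    Identical params+seed give identical output. Transcripts are placed
    left-to-right with inter-span gaps >= ``intergenic_min_gap`` (which also
    separates same-strand downstream windows from neighbors); strands are
    assigned randomly (seeded). Raises if the chromosome cannot hold the
    requested transcripts, naming the required minimum length.
    """
    rng = np.random.default_rng(params.seed)
    margin = max(params.intergenic_min_gap, params.readthrough_extent)
    required = (
        params.n_transcripts * (params.max_span + params.intergenic_min_gap)
        + 2 * margin
    )
    if required > params.chrom_length:
        raise ValueError(
            f"infeasible packing: chrom_length must be >= {required} nt "
            f"for {params.n_transcripts} transcripts"
        )
    transcripts = []
    truth_rows = []
    cursor = margin
    lo_n, hi_n = params.exon_count_range
    for i in range(params.n_transcripts):
        if rng.random() < params.spliced_fraction:
            n_exons = int(rng.integers(max(2, lo_n), hi_n + 1))
        else:
            n_exons = 1
        exon_lens = rng.integers(*params.exon_length_range, size=n_exons)
        intron_lens = (
            rng.integers(*params.intron_length_range, size=n_exons - 1)
            if n_exons > 1
            else np.empty(0, dtype=int)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append(
                GenomicInterval(params.chrom, pos, pos + int(exon_lens[j]), strand)
            )
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        tid = f"SIM{i:04d}"
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=f"GENE{i:04d}",
            chrom=params.chrom,
            strand=strand,
            exons=exons,
        )
        transcripts.append(t)
        c_t = float(
            np.exp(rng.normal(params.expression_log_mean, params.expression_log_sd))
        )
        truth_rows.append(
            {
                "transcript_id": tid,
                "c_t": c_t,
                "strand": strand,
                "tes": t.tes,
                "alpha": params.readthrough_fraction,
                "lam": params.decay_length,
            }
        )
        gap = int(rng.integers(params.intergenic_min_gap, params.intergenic_min_gap + 2000))
        cursor = pos + gap
    if cursor + margin > params.chrom_length:
        raise ValueError(
            f"infeasible packing: chrom_length must be >= {cursor + margin} nt "
            f"for {params.n_transcripts} transcripts"
        )
    ann = AnnotationSet(
        transcripts, chrom_sizes={params.chrom: params.chrom_length}
    )
    truth = SimulationTruth(
        table=pd.DataFrame(truth_rows), seed=params.seed, params=params
    )
    return ann, truth


def simulate_coverage(
    ann: AnnotationSet,
    truth: SimulationTruth,
    condition_alpha: Optional[float] = None,
    params: Optional[SimulationParams] = None,
    replicate_seed: int = 0,
    noiseless: bool = False,
) -> StrandedCoverage:
    """Realize one replicate of stranded coverage for the given annotation.

    Expected per-base values follow the generative model above;
    ``condition_alpha`` overrides the read-through fraction recorded in the
    truth table (conditions share an annotation and differ only in alpha).
    With ``noiseless=True`` the expectation itself is returned; otherwise
    each base is an independent Poisson draw seeded by ``replicate_seed``.
    """
    params = params if params is not None else truth.params
    L = params.chrom_length
    dense = {
        (params.chrom, "+"): np.zeros(L),
        (params.chrom, "-"): np.zeros(L),
    }
    decay = np.exp(-np.arange(params.readthrough_extent) / params.decay_length)
    c_by_tid = dict(zip(truth.table.transcript_id, truth.table.c_t))
    for t in ann:
        c_t = c_by_tid[t.transcript_id]
        alpha = (
            condition_alpha
            if condition_alpha is not None
            else float(
                truth.table.loc[
                    truth.table.transcript_id == t.transcript_id, "alpha"
                ].iloc[0]
            )
        )
        track = dense[(t.chrom, t.strand)]
        for ex in t.exons:
            track[ex.start : ex.end] += c_t
        D = params.readthrough_extent
        if t.strand == "+":
            hi = min(L, t.tes + D)
            track[t.tes : hi] += alpha * c_t * decay[: hi - t.tes]
        else:
            lo = max(0, t.tes - D)
            track[lo : t.tes] += alpha * c_t * decay[: t.tes - lo][::-1]
    if params.background > 0:
        for key in dense:
            dense[key] += params.background
    if not noiseless:
        rng = np.random.default_rng(replicate_seed)
        for key in dense:
            dense[key] = rng.poisson(dense[key]).astype(np.float64)
    return StrandedCoverage.from_dense(dense)


def expected_metagene(alpha: float, lam: float, W: int, k: int) -> float:
    """Noiseless normalized value of downstream window k (analytic oracle).

    With continuous exponential decay the expected window-k sum is
    alpha*c_t*lam*exp(-(k-1)W/lam)*(1-exp(-W/lam)) and the terminal window
    sum is c_t*W, giving

        alpha * (lam/W) * exp(-(k-1)W/lam) * (1 - exp(-W/lam)),

    independent of c_t. The discrete per-base sum differs from this
    continuous form by under 0.5% for lam >= 500 at W = 250.
    """
    if lam <= 0 or W < 1 or k < 1:
        raise ValueError("require lam > 0, W >= 1, k >= 1")
    return alpha * (lam / W) * math.exp(-(k - 1) * W / lam) * (1 - math.exp(-W / lam))


def estimate_alpha(window1_mean: float, lam: float, W: int) -> float:
    """Invert the window-1 oracle: alpha_hat from an observed meta-gene mean."""
    return window1_mean / ((lam / W) * (1 - math.exp(-W / lam)))


def write_bundle(
    out_dir: str,
    params: SimulationParams,
    condition_alphas: dict[str, float],
    noiseless: bool = False,
) -> dict[str, object]:
    """Write a complete simulated fixture bundle to ``out_dir``.

    Produces ``annotation.gtf``, per condition x replicate
    ``<cond>_<rep>.plus.bedgraph`` / ``.minus.bedgraph``, ``truth.tsv``,
    ``params.yaml`` and a ready-to-run pipeline ``config.yaml``.
    Replicate seeds are derived deterministically from ``params.seed``.
    """
    import os

    import yaml

    from .coverage import write_bedgraph_pair
    from .genome import write_gtf

    os.makedirs(out_dir, exist_ok=True)
    ann, truth = simulate_annotation(params)
    gtf_path = os.path.join(out_dir, "annotation.gtf")
    write_gtf(ann, gtf_path)
    truth.table.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)

    conditions: dict[str, dict[str, dict[str, str]]] = {}
    seed_stream = np.random.SeedSequence(params.seed)
    child_seeds = seed_stream.spawn(len(condition_alphas) * params.replicates)
    idx = 0
    for cond, alpha in condition_alphas.items():
        conditions[cond] = {}
        for r in range(1, params.replicates + 1):
            rep = f"rep{r}"
            rep_seed = int(child_seeds[idx].generate_state(1)[0] % (2**31))
            idx += 1
            cov = simulate_coverage(
                ann,
                truth,
                condition_alpha=alpha,
                params=params,
                replicate_seed=rep_seed,
                noiseless=noiseless,
            )
            plus_name = f"{cond}_{rep}.plus.bedgraph"
            minus_name = f"{cond}_{rep}.minus.bedgraph"
            write_bedgraph_pair(
                cov, os.path.join(out_dir, plus_name), os.path.join(out_dir, minus_name)
            )
            # paths relative to the bundle keep it relocatable and reproducible
            conditions[cond][rep] = {"plus": plus_name, "minus": minus_name}

    params_dict = {
        k: list(v) if isinstance(v, tuple) else v for k, v in asdict(params).items()
    }
    params_dict["condition_alphas"] = dict(condition_alphas)
    with open(os.path.join(out_dir, "params.yaml"), "w") as fh:
        yaml.safe_dump(params_dict, fh, sort_keys=True)

    config = {
        "annotation": "annotation.gtf",
        "conditions": conditions,
        "params": {"seed": params.seed},
    }
    conds = list(condition_alphas)
    if len(conds) >= 2:
        config["compare"] = conds[:2]
    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {"annotation": ann, "truth": truth, "config_path": config_path}
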
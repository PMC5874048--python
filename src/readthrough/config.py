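"""Pipeline parameters and the YAML run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Optional

import yaml


class ConfigError(ValueError):
    """Raised when a run configuration is missing or invalid."""


@dataclass
class PipelineConfig:
    """Tunable analysis parameters.

    window_size
        W, nt per window; the terminal reference and every downstream
        window have this genomic width (default 250 nt).
    n_windows
        K, number of contiguous downstream windows (default 20, i.e. 5 kb).
    tpm_threshold
        Transcripts must exceed this TPM strictly to be analyzed.
    require_spliced
        Keep only multi-exon transcripts.
    clearance
        nt downstream of the 3' end that must be free of other same-strand
        transcripts; ``None`` means K*W (the full windowed extent).
    terminal_floor
        Minimum signal in the terminal reference window; below it a
        transcript is excluded rather than producing unstable ratios.
    aggregation
        ``mean_of_ratios`` (average the per-transcript normalized profiles)
        or ``pooled_ratio`` (sum window signal across transcripts, divide by
        summed terminal signal).
    n_bootstrap
        Bootstrap resamples for the condition-contrast confidence interval.
    seed
        Single source of randomness for the run.
    """

    window_size: int = 250
    n_windows: int = 20
    tpm_threshold: float = 10.0
    require_spliced: bool = True
    clearance: Optional[int] = None
    terminal_floor: float = 1.0
    aggregation: str = "mean_of_ratios"
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ConfigError("window_size must be >= 1")
        if self.n_windows < 1:
            raise ConfigError("n_windows must be >= 1")
        if self.tpm_threshold < 0:
            raise ConfigError("tpm_threshold must be >= 0")
        if self.terminal_floor <= 0:
            raise ConfigError("terminal_floor must be > 0")
        if self.aggregation not in ("mean_of_ratios", "pooled_ratio"):
            raise ConfigError(f"unknown aggregation mode {self.aggregation!r}")
        if self.clearance is None:
            self.clearance = self.window_size * self.n_windows
        elif self.clearance < 1:
            raise ConfigError("clearance must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class RunConfig:
    """Full run configuration: inputs, conditions and parameters.

    YAML layout::

        annotation: annotation.gtf
        chrom_sizes: chrom.sizes        # optional
        conditions:
          WT:
            rep1: {plus: wt_rep1.plus.bedgraph, minus: wt_rep1.minus.bedgraph}
            rep2: {...}
          MUT:
            rep1: {...}
        compare: [WT, MUT]              # optional: [A, B]; reports B - A
        params:
          window_size: 250
          tpm_threshold: 10
          seed: 42
    """

    annotation: str
    conditions: dict[str, dict[str, dict[str, str]]]
    params: PipelineConfig = field(default_factory=PipelineConfig)
    compare: Optional[tuple[str, str]] = None
    chrom_sizes: Optional[str] = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        for key in ("annotation", "conditions"):
            if key not in raw:
                raise ConfigError(f"missing required config key: {key}")
        conditions = raw["conditions"]
        if not isinstance(conditions, dict) or not conditions:
            raise ConfigError("conditions must map condition -> replicates")
        for cond, reps in conditions.items():
            if not isinstance(reps, dict) or not reps:
                raise ConfigError(f"condition {cond!r} needs >= 1 replicate")
            for rep, files in reps.items():
                for side in ("plus", "minus"):
                    if side not in files:
                        raise ConfigError(
                            f"replicate {cond}/{rep} missing {side!r} bedGraph path"
                        )
        params = PipelineConfig(**raw.get("params", {}))
        compare = raw.get("compare")
        if compare is not None:
            if len(compare) != 2:
                raise ConfigError("compare must list exactly two conditions [A, B]")
            for cond in compare:
                if cond not in conditions:
                    raise ConfigError(f"compare names unknown condition {cond!r}")
            compare = (compare[0], compare[1])
        return cls(
            annotation=raw["annotation"],
            conditions=conditions,
            params=params,
            compare=compare,
            chrom_sizes=raw.get("chrom_sizes"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        """Load from YAML; relative file paths resolve against the config dir."""
        import os

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        try:
            run = cls.from_dict(raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        run.annotation = resolve(run.annotation)
        if run.chrom_sizes:
            run.chrom_sizes = resolve(run.chrom_sizes)
        for reps in run.conditions.values():
            for files in reps.values():
                for side in ("plus", "minus"):
                    files[side] = resolve(files[side])
        return run
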
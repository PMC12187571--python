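"""Pipeline configuration and run logging.

A single :class:`PipelineConfig` carries every threshold and parameter the
pipeline stages consume, so a run is reproducible from one YAML artifact.
CLI flags override individual keys.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

__all__ = ["Thresholds", "Paths", "PipelineConfig", "RunLog"]


@dataclass
class Thresholds:
    """Gate thresholds for the differential-omics stages (log2 units / FDR)."""

    deg_lfc: float = 2.5
    deg_padj: float = 0.01
    dep_lfc: float = 1.0
    dep_padj: float = 0.01


@dataclass
class Paths:
    input_dir: str = "."
    output_dir: str = "results"


@dataclass
class PipelineConfig:
    """All tunable parameters of the nomination / validation pipeline.

    Attributes
    ----------
    thresholds
        Differential expression/protein gates. Defaults: overexpression gate
        log2FC > 2.5 at Padj < 0.01; knockdown-proteomics gate |log2FC| > 1.0
        at Padj < 0.01.
    max_tss_distance
        Peak-to-gene assignment window in bp (distance from a peak edge to a
        gene TSS). Default 100 kb.
    stitching_distance
        Maximum gap in bp for transitive enhancer stitching (canonical ROSE
        constant, 12.5 kb).
    tss_exclusion
        Optional promoter-exclusion half-window in bp applied before
        stitching; 0 disables it.
    ssgsea_alpha
        Rank-weight exponent for single-sample enrichment scoring.
    gsea_permutations
        Gene-sampling permutations for the preranked enrichment null.
    irs_positive_cutoff
        Immunoreactive-score positivity rule: a sample is called compatible
        with the target entity iff IRS > cutoff. Integer in [0, 12].
    random_seed
        Seed for every stochastic stage (simulation, permutation nulls).
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    max_tss_distance: int = 100_000
    stitching_distance: int = 12_500
    tss_exclusion: int = 0
    ssgsea_alpha: float = 0.25
    gsea_permutations: int = 1000
    irs_positive_cutoff: int = 1
    random_seed: int = 42
    paths: Paths = field(default_factory=Paths)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.thresholds
        for name in ("deg_lfc", "deg_padj", "dep_lfc", "dep_padj"):
            if getattr(t, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")
        for name in ("max_tss_distance", "stitching_distance", "ssgsea_alpha",
                     "gsea_permutations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_tss_distance <= 0:
            raise ValueError("max_tss_distance must be > 0")
        if not (0 <= self.irs_positive_cutoff <= 12):
            raise ValueError("irs_positive_cutoff must lie in [0, 12]")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "paths" in d:
            d["paths"] = Paths(**d["paths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def override(self, **updates: Any) -> "PipelineConfig":
        """Return a copy with flat keys replaced (CLI-flag semantics).

        Threshold keys (``deg_lfc`` ...) address into ``thresholds``.
        ``None`` values are ignored so unset CLI flags pass through.
        """
        d = self.to_dict()
        for key, value in updates.items():
            if value is None:
                continue
            if key in d:
                d[key] = value
            elif key in d["thresholds"]:
                d["thresholds"][key] = value
            elif key in d["paths"]:
                d["paths"][key] = value
            else:
                raise KeyError(f"unknown config key: {key}")
        return PipelineConfig.from_dict(d)


def _digest(obj: Any) -> str:
    """Stable sha256 digest of a small python object (for run logs)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class LogRecord:
    stage: str
    timestamp: str
    seed: int
    counts: dict[str, int]
    input_digest: str


class RunLog:
    """Ordered per-stage log: every pipeline stage appends exactly one record."""

    def __init__(self, seed: int) -> None:
        self.seed = seed
        self.records: list[LogRecord] = []

    def append(self, stage: str, counts: dict[str, int] | None = None,
               inputs: Any = None) -> LogRecord:
        if any(r.stage == stage for r in self.records):
            raise ValueError(f"stage {stage!r} already logged")
        rec = LogRecord(
            stage=stage,
            timestamp=datetime.now(timezone.utc).isoformat(),
            seed=self.seed,
            counts=dict(counts or {}),
            input_digest=_digest(inputs) if inputs is not None else "",
        )
        self.records.append(rec)
        return rec

    def counts(self) -> dict[str, dict[str, int]]:
        return {r.stage: r.counts for r in self.records}

    def write(self, path: str | Path) -> None:
        lines = [
            f"{r.timestamp}\tstage={r.stage}\tseed={r.seed}"
            f"\tinputs={r.input_digest}\t"
            + " ".join(f"{k}={v}" for k, v in sorted(r.counts.items()))
            for r in self.records
        ]
        Path(path).write_text("\n".join(lines) + "\n")
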
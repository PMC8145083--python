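"""Run configuration: validated tunables shared by the CLI pipelines."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .summarizer import SummarizerConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    window: max Q&A pairs per slice; d: TextRank damping; tau: semantic
    match threshold; K / min_len: candidate-path enumeration; alpha /
    iterations: retrofitting; log_floor: LM floor (log10); es_fraction:
    extractive prefilter share for AoES; seed: governs every stochastic
    component (fixtures, LDA) — the pipeline core itself is deterministic.
    """

    window: int = 7
    d: float = 0.78
    tau: float = 0.6
    K: int = 100
    min_len: int = 8
    context_radius: int = 1
    alpha: float = 1.0
    iterations: int = 10
    log_floor: float = -10.0
    es_fraction: float = 0.5
    seed: int = 0
    # resource paths (optional; commands may require them)
    transcript: str | None = None
    lexicon: str | None = None
    embeddings: str | None = None
    lm: str | None = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if not 0.0 < self.d < 1.0:
            raise ConfigError("damping factor d must be in (0, 1)")
        if not 0.0 < self.tau <= 1.0:
            raise ConfigError("tau must be in (0, 1]")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.min_len < 1:
            raise ConfigError("min_len must be >= 1")
        if self.context_radius < 0:
            raise ConfigError("context_radius must be >= 0")
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.log_floor >= 0:
            raise ConfigError("log_floor must be negative")
        if not 0.0 < self.es_fraction <= 1.0:
            raise ConfigError("es_fraction must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        ) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {unknown}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def summarizer_config(self, use_wss: bool = True) -> SummarizerConfig:
        return SummarizerConfig(
            window=self.window,
            d=self.d,
            tau=self.tau,
            context_radius=self.context_radius,
            K=self.K,
            min_len=self.min_len,
            use_wss=use_wss,
        )

    def write_manifest(self, out_dir: str | Path, inputs: dict[str, str] | None = None) -> Path:
        """Echo the effective config (plus input hashes) into the output
        directory so every run is reproducible from its manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"config": self.to_dict(), "inputs": {}}
        for name, p in (inputs or {}).items():
            try:
                digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
            except OSError:
                digest = None
            manifest["inputs"][name] = {"path": str(p), "sha256": digest}
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
        return path
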
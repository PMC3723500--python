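"""Run configuration shared by learning, validation and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable knobs for panel learning and validation runs.

    sensitivity_target : required training sensitivity of every node classifier
        (default 1.0 — a positive sample rejected at a node can never be
        recovered, so sensitivity is pushed as close to unity as attainable).
    max_pairs : hard cap on pairs per node panel (printed panels span 1-7 pairs).
    min_specificity_gain : a pair is only appended while it still buys at least
        this much training specificity once the sensitivity target is reachable.
    prefilter_f : candidate features kept by rank-variance pre-filter before
        all-pairs scoring; None scores every feature (used when <= 1000).
    """

    seed: int = 0
    folds: int = 10
    repeats: int = 10
    sensitivity_target: float = 1.0
    max_pairs: int = 7
    min_specificity_gain: float = 0.01
    prefilter_f: int | None = 1000
    allowlist: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity_target <= 1.0:
            raise ValueError("sensitivity_target must be in (0, 1]")
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")
        if self.min_specificity_gain < 0:
            raise ValueError("min_specificity_gain must be >= 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.prefilter_f is not None and self.prefilter_f < 2:
            raise ValueError("prefilter_f must be >= 2 or None")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
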
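"""Run configuration and deterministic seed derivation.

Experiments stack many thresholds (U-threshold 0.5, extent 100, |z| >
3.29, extents 500/200, damage fraction 0.2, deficit probability 0.9,
sparseness 0.045 ...), so a run is described by one JSON document that
every command logs verbatim; each stochastic stage receives a seed
derived deterministically from the global one.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("lesionparc")


def derive_seed(global_seed: int, *labels: str) -> int:
    """Deterministic per-stage seed (< 2**31) from a global seed and a
    stage label path."""
    key = zlib.crc32("/".join(labels).encode())
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Paths, nested module parameters and the global seed of one run."""

    lesion_dir: str | None = None
    mask_path: str | None = None
    behaviour_path: str | None = None
    atlas_path: str | None = None
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def validate_paths(self) -> None:
        for name in ("lesion_dir", "mask_path", "behaviour_path", "atlas_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def setup_logging(level: str = "INFO", logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
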
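"""Run manifests: enough metadata to regenerate every output bit-identically.

A manifest records the canonical configuration hash, the master seed and the
per-stage seeds derived from it, package versions, and the output paths.
Timestamps are recorded for provenance but excluded from the hash, so two
runs of the same configuration produce identical data files and identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

__all__ = ["RunManifest", "canonical_hash", "derive_stage_seeds"]


def canonical_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted, compact) JSON form of a config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def derive_stage_seeds(master_seed: int, stages: list[str]) -> dict[str, int]:
    """Independent per-stage integer seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    stage_seeds: dict
    outputs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        from . import __version__

        return {
            "config": self.config,
            "config_hash": canonical_hash(self.config),
            "master_seed": self.master_seed,
            "stage_seeds": self.stage_seeds,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "versions": {
                "audbattery": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
            },
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2) + "\n")
        return path
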
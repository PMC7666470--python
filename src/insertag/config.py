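"""Pipeline configuration: every tunable, with provenance tracking.

A flat key=value file format is used (one assignment per line, ``#``
comments); values keep their Python types through a round-trip. Each field
records whether it still holds its default or was set by the user, so a run
manifest can state exactly which knobs were turned.
"""

from __future__ import annotations

import ast
import hashlib
import json
from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    # alignment input
    min_mapq: int = 20
    # discovery
    min_support: int = 3
    k: int = 31
    min_kmer_count: int = 1
    prune_ratio: float = 0.2
    min_flank: int = 15
    min_ins_part: int = 10
    flank_tolerance: float = 0.02
    microhomology_slack: int = 20
    max_pair_gap: int = 100
    # tracing
    trace_flank_len: int = 500
    trace_unique_mapq: int = 20
    trace_min_identity: float = 0.90
    max_insertion: int = 100_000
    # genotyping
    gt_t_low: float = 0.2
    gt_t_high: float = 0.8
    gt_min_depth: int = 4
    gt_score_margin: int = 3
    gt_min_overlap: int = 10
    # mechanism
    mech_flank_w: int = 100
    vntr_min_coverage: float = 0.85
    nahr_min_homology: int = 50
    te_min_fraction: float = 0.80
    # simulation
    seed: int = 1

    _user_set: set = field(default_factory=set, repr=False, compare=False)

    def set(self, key: str, value) -> None:
        if key.startswith("_") or key not in {f.name for f in fields(self)}:
            raise KeyError(f"unknown configuration key: {key}")
        current = getattr(self, key)
        setattr(self, key, type(current)(value))
        self._user_set.add(key)

    def provenance(self) -> dict[str, str]:
        return {
            f.name: ("user" if f.name in self._user_set else "default")
            for f in fields(self)
            if not f.name.startswith("_")
        }

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if not f.name.startswith("_")
        }

    def to_file(self, path: str) -> str:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key} = {value!r}\n")
        return path

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        cfg = cls()
        defaults = cls().to_dict()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (part.strip() for part in line.split("=", 1))
                value = ast.literal_eval(raw)
                cfg.set(key, value)
                if value == defaults.get(key):
                    cfg._user_set.discard(key)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
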
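"""Time-series container for cupula displacement / volume traces."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace"]

_KINDS = ("displacement", "volume")


@dataclass
class Trace:
    """A sampled cupula response.

    ``kind`` fixes the units: "displacement" traces are in μm, "volume"
    traces in m³.  ``meta`` records generator provenance (model
    parameters, seed, noise level, stimulus description).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "displacement"
    condition_code: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")

    @property
    def units(self) -> str:
        return "um" if self.kind == "displacement" else "m3"

    def scaled(self, c: float) -> "Trace":
        return Trace(self.times, c * self.values, self.kind, self.condition_code, dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        """Write `time_s,value,kind` CSV; code and meta go into `#` header
        comments so a round trip preserves provenance."""
        lines = []
        if self.condition_code is not None:
            lines.append(f"# condition_code: {self.condition_code}")
        if self.meta:
            lines.append("# meta: " + json.dumps(self.meta, ensure_ascii=False))
        df = pd.DataFrame({"time_s": self.times, "value": self.values, "kind": self.kind})
        with open(path, "w", encoding="utf-8") as fh:
            for ln in lines:
                fh.write(ln + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        code = None
        meta: dict = {}
        with open(path, "r", encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("# condition_code:"):
                    code = line.split(":", 1)[1].strip()
                elif line.startswith("# meta:"):
                    meta = json.loads(line.split(":", 1)[1])
                else:
                    fh.seek(pos)
                    break
                pos = fh.tell()
            df = pd.read_csv(fh)
        kind = str(df["kind"].iloc[0]) if "kind" in df and len(df) else "displacement"
        return cls(
            times=df["time_s"].to_numpy(),
            values=df["value"].to_numpy(),
            kind=kind,
            condition_code=code,
            meta=meta,
        )
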
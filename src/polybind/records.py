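"""Spike records and raster file IO.

A :class:`SpikeRecord` is the universal analysis input: ordered
(trial, neuron, time) events.  Rasters persist as TSV with ``#``-prefixed
metadata header lines followed by columns trial, neuron_id, time_ms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeRecord"]


@dataclass
class SpikeRecord:
    """Ordered spike events; times are onset-relative, in ms."""

    trial: np.ndarray
    neuron: np.ndarray
    time_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trial = np.asarray(self.trial, dtype=np.int64)
        self.neuron = np.asarray(self.neuron, dtype=np.int64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if not (self.trial.shape == self.neuron.shape == self.time_ms.shape):
            raise ValueError("trial, neuron and time arrays must be congruent")
        for t in np.unique(self.trial):
            tt = self.time_ms[self.trial == t]
            if tt.size and np.any(np.diff(tt) < 0):
                raise ValueError(f"spike times not sorted within trial {t}")

    def __len__(self) -> int:
        return self.time_ms.size

    @classmethod
    def empty(cls, **meta) -> "SpikeRecord":
        return cls(np.empty(0, np.int64), np.empty(0, np.int64),
                   np.empty(0, np.float64), meta=dict(meta))

    @classmethod
    def single_trial(cls, neuron, time_ms, trial: int = 0, **meta) -> "SpikeRecord":
        neuron = np.asarray(neuron, dtype=np.int64)
        time_ms = np.asarray(time_ms, dtype=np.float64)
        order = np.argsort(time_ms, kind="stable")
        return cls(np.full(neuron.shape, trial, np.int64),
                   neuron[order], time_ms[order], meta=dict(meta))

    @classmethod
    def concatenate(cls, records: list["SpikeRecord"]) -> "SpikeRecord":
        if not records:
            return cls.empty()
        meta = dict(records[0].meta)
        return cls(
            np.concatenate([r.trial for r in records]),
            np.concatenate([r.neuron for r in records]),
            np.concatenate([r.time_ms for r in records]),
            meta=meta,
        )

    def for_trial(self, trial: int) -> "SpikeRecord":
        m = self.trial == trial
        return SpikeRecord(self.trial[m], self.neuron[m], self.time_ms[m],
                           meta=dict(self.meta))

    def trials(self) -> np.ndarray:
        return np.unique(self.trial)

    def restrict_neurons(self, neurons) -> "SpikeRecord":
        m = np.isin(self.neuron, np.asarray(neurons))
        return SpikeRecord(self.trial[m], self.neuron[m], self.time_ms[m],
                           meta=dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": self.trial, "neuron_id": self.neuron, "time_ms": self.time_ms}
        )

    def write_tsv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for key, value in self.meta.items():
                if key == "v_trace":
                    continue
                fh.write(f"# {key}={value}\n")
            # 17 significant digits: the raster round-trips losslessly
            self.to_frame().to_csv(fh, sep="\t", index=False,
                                   float_format="%.17g")

    @classmethod
    def read_tsv(cls, path) -> "SpikeRecord":
        path = Path(path)
        meta: dict = {}
        body = io.StringIO()
        with path.open() as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
                else:
                    body.write(line)
        body.seek(0)
        df = pd.read_csv(body, sep="\t", float_precision="round_trip")
        return cls(df["trial"].to_numpy(), df["neuron_id"].to_numpy(),
                   df["time_ms"].to_numpy(), meta=meta)
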
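"""Illumination protocols and switching-experiment containers.

A photoswitching experiment toggles a negative-switching RSFP between its
fluorescent (on) and dark (off) states: violet light switches the protein on,
while the cyan excitation light that produces fluorescence simultaneously
drives it off.  One *period* of illumination yields one recorded frame, so a
protocol is fully described by the number of cycles and the number of on/off
periods per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["SwitchingProtocol", "SwitchingExperiment"]


@dataclass(frozen=True)
class SwitchingProtocol:
    """An on/off illumination schedule.

    Each cycle consists of ``on_periods`` frames under violet (on-switching)
    light followed by ``off_periods`` frames under cyan (off-switching,
    fluorescence-reading) light.  ``trailing_on_periods`` appends a final
    violet block after the last cycle, as used in the single-cycle
    20 on / 40 off / 20 on colony scheme.

    Parameters
    ----------
    n_cycles : number of switching cycles (>= 1).
    on_periods, off_periods : frames per half-cycle (>= 1).
    period_duration : duration of one illumination period in seconds; frame
        times are ``frame_index * period_duration``.
    frame_exposure : camera exposure per frame in seconds (metadata only).
    trailing_on_periods : extra on-switching frames after the final cycle.
    """

    n_cycles: int
    on_periods: int
    off_periods: int
    period_duration: float
    frame_exposure: float | None = None
    trailing_on_periods: int = 0
    on_label: str = "violet"
    off_label: str = "cyan"

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.on_periods < 1 or self.off_periods < 1:
            raise ValueError("n_cycles, on_periods and off_periods must all be >= 1")
        if self.trailing_on_periods < 0:
            raise ValueError("trailing_on_periods must be >= 0")
        if not np.isfinite(self.period_duration) or self.period_duration <= 0:
            raise ValueError("period_duration must be a positive, finite duration")
        if self.frame_exposure is not None and self.frame_exposure <= 0:
            raise ValueError("frame_exposure must be positive")

    @property
    def frames_per_cycle(self) -> int:
        return self.on_periods + self.off_periods

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.frames_per_cycle + self.trailing_on_periods

    @property
    def normalization_frame_index(self) -> int:
        """Frame at the point of complete on-switching: the last frame of the
        initial on-illumination block."""
        return self.on_periods - 1

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.period_duration

    def frame_table(self) -> pd.DataFrame:
        """Tidy per-frame schedule: frame, time_s, cycle, half_cycle, illumination.

        Cycles are numbered from 1; ``half_cycle`` is ``"on"`` or ``"off"``.
        Trailing on-frames carry the last cycle's number and ``half_cycle="on"``.
        """
        frames = np.arange(self.n_frames)
        in_cycle = frames[: self.n_cycles * self.frames_per_cycle]
        cycle = in_cycle // self.frames_per_cycle + 1
        within = in_cycle % self.frames_per_cycle
        half = np.where(within < self.on_periods, "on", "off")
        if self.trailing_on_periods:
            cycle = np.concatenate([cycle, np.full(self.trailing_on_periods, self.n_cycles)])
            half = np.concatenate([half, np.full(self.trailing_on_periods, "on")])
        illum = np.where(half == "on", self.on_label, self.off_label)
        return pd.DataFrame(
            {
                "frame": frames,
                "time_s": self.frame_times(),
                "cycle": cycle.astype(int),
                "half_cycle": half,
                "illumination": illum,
            }
        )

    def off_frame_indices(self, cycle: int) -> np.ndarray:
        """Frame indices of the off half-cycle of 1-based ``cycle``."""
        if not 1 <= cycle <= self.n_cycles:
            raise ValueError(f"cycle must be in 1..{self.n_cycles}")
        start = (cycle - 1) * self.frames_per_cycle + self.on_periods
        return np.arange(start, start + self.off_periods)

    def on_frame_indices(self, cycle: int) -> np.ndarray:
        if not 1 <= cycle <= self.n_cycles:
            raise ValueError(f"cycle must be in 1..{self.n_cycles}")
        start = (cycle - 1) * self.frames_per_cycle
        return np.arange(start, start + self.on_periods)

    def off_local_times(self) -> np.ndarray:
        """Times since off-switching onset for the frames of one off half-cycle."""
        return np.arange(self.off_periods) * self.period_duration

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "on_periods": self.on_periods,
            "off_periods": self.off_periods,
            "period_duration": self.period_duration,
            "frame_exposure": self.frame_exposure,
            "trailing_on_periods": self.trailing_on_periods,
            "on_label": self.on_label,
            "off_label": self.off_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchingProtocol":
        return cls(**d)

    @classmethod
    def hela_default(cls, n_cycles: int = 500) -> "SwitchingProtocol":
        """25 on + 25 off periods of 100 ms, repeated over many cycles."""
        return cls(
            n_cycles=n_cycles,
            on_periods=25,
            off_periods=25,
            period_duration=0.1,
            frame_exposure=0.05,
        )

    @classmethod
    def colony_default(cls) -> "SwitchingProtocol":
        """Single colony cycle: 20 on, 40 off, 20 trailing on periods of 30 s."""
        return cls(
            n_cycles=1,
            on_periods=20,
            off_periods=40,
            period_duration=30.0,
            frame_exposure=0.5,
            trailing_on_periods=20,
        )

    def with_cycles(self, n_cycles: int) -> "SwitchingProtocol":
        return replace(self, n_cycles=n_cycles)


@dataclass
class SwitchingExperiment:
    """Per-object fluorescence traces organized by an illumination protocol.

    ``traces`` is an ``(n_objects, n_frames)`` array of raw intensities; the
    population mean trace and its normalized form (scaled to 1 at the point of
    complete on-switching) are derived properties.
    """

    protocol: SwitchingProtocol
    traces: np.ndarray
    object_ids: list[int] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != self.protocol.n_frames:
            raise ValueError(
                f"traces have {self.traces.shape[1]} frames but the protocol "
                f"defines {self.protocol.n_frames}"
            )
        if not self.object_ids:
            self.object_ids = list(range(1, self.traces.shape[0] + 1))
        if len(self.object_ids) != self.traces.shape[0]:
            raise ValueError("object_ids length must match the number of traces")

    @property
    def n_objects(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def normalization_frame_index(self) -> int:
        return self.protocol.normalization_frame_index

    @property
    def mean_trace(self) -> np.ndarray:
        return self.traces.mean(axis=0)

    @property
    def normalized_mean_trace(self) -> np.ndarray:
        m = self.mean_trace
        ref = m[self.normalization_frame_index]
        if ref == 0:
            raise ZeroDivisionError("normalization frame has zero intensity")
        return m / ref

    def iter_off_segments(
        self, trace: np.ndarray | None = None
    ) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield ``(cycle, t_local, values)`` for each off half-cycle.

        ``t_local`` is the time since the onset of off-switching illumination
        within that cycle.  Uses the population mean trace unless ``trace`` is
        given.
        """
        y = self.mean_trace if trace is None else np.asarray(trace, dtype=float)
        t_local = self.protocol.off_local_times()
        for cycle in range(1, self.protocol.n_cycles + 1):
            idx = self.protocol.off_frame_indices(cycle)
            yield cycle, t_local, y[idx]

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (object, frame)."""
        schedule = self.protocol.frame_table()
        parts = []
        for oid, tr in zip(self.object_ids, self.traces):
            part = schedule.copy()
            part.insert(0, "object_id", oid)
            part["intensity"] = tr
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_tidy(
        cls, table: pd.DataFrame, protocol: SwitchingProtocol, metadata: dict | None = None
    ) -> "SwitchingExperiment":
        object_ids = sorted(table["object_id"].unique())
        traces = np.vstack(
            [
                table.loc[table["object_id"] == oid].sort_values("frame")["intensity"].to_numpy()
                for oid in object_ids
            ]
        )
        return cls(
            protocol=protocol,
            traces=traces,
            object_ids=[int(o) for o in object_ids],
            metadata=metadata or {},
        )
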
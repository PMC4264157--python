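"""Recording container shared by the simulator and the detection pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .grid import ElectrodeGrid, Site

DEFAULT_FS_HZ = 3200.0
DEFAULT_BAND_HZ = (3.0, 1300.0)

#: Beat kinds understood by the detection pipeline.
BEAT_KINDS = ("intracardiac", "pacing", "vf")


@dataclass
class RecordingSession:
    """Multichannel bipolar electrogram recording plus acquisition metadata.

    ``signals`` is a ``(n_channels, n_samples)`` matrix in mV.  QRS onsets
    are user-supplied triggers (ms from the start of the recording); beat
    kinds select the detection window class per beat.
    """

    signals: np.ndarray
    grid: ElectrodeGrid
    channel_map: tuple[Site, ...]
    qrs_onsets_ms: tuple[float, ...]
    fs: float = DEFAULT_FS_HZ
    band: tuple[float, float] = DEFAULT_BAND_HZ
    pacing_onsets_ms: tuple[float, ...] | None = None
    beat_kinds: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise InvalidArgumentError("signals must be channels x samples")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if len(self.channel_map) != self.signals.shape[0]:
            raise InvalidArgumentError("every channel must be mapped to a site")
        self.qrs_onsets_ms = tuple(float(q) for q in self.qrs_onsets_ms)
        if any(b >= a for a, b in zip(self.qrs_onsets_ms[1:], self.qrs_onsets_ms)):
            raise InvalidArgumentError("qrs onsets must be strictly increasing")
        if self.beat_kinds is None:
            self.beat_kinds = tuple("intracardiac" for _ in self.qrs_onsets_ms)
        else:
            self.beat_kinds = tuple(self.beat_kinds)
            if len(self.beat_kinds) != len(self.qrs_onsets_ms):
                raise InvalidArgumentError("one beat kind per QRS onset")
            for k in self.beat_kinds:
                if k not in BEAT_KINDS:
                    raise InvalidArgumentError(f"unknown beat kind {k!r}")
        if self.pacing_onsets_ms is not None:
            self.pacing_onsets_ms = tuple(float(p) for p in self.pacing_onsets_ms)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    @property
    def n_beats(self) -> int:
        return len(self.qrs_onsets_ms)

    def ms_to_sample(self, t_ms: float) -> int:
        return int(round(t_ms * self.fs / 1000.0))

    def sample_to_ms(self, i: int) -> float:
        return i * 1000.0 / self.fs

    def channel_of(self, site: Site) -> int:
        return self.channel_map.index(site)
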
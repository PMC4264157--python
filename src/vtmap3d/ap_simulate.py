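"""Synthetic microelectrode action-potential traces with injected DADs and
triggered activity.

Paced APs are piecewise-linear: a brief stimulus artifact, a fast upstroke,
then a repolarization polyline that crosses 50% and 90% repolarization at
exactly the configured APD50/APD90.  DADs are Gaussian humps injected after
full repolarization of the last paced AP of a drive; triggered activity is
a full AP whose upstroke starts at a DAD peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

DEFAULT_AP_FS_HZ = 2000.0


@dataclass(frozen=True)
class APShape:
    """Generator parameters for one paced AP."""

    mdp_mv: float = -85.0
    peak_mv: float = 20.0
    apd50_ms: float = 165.0
    apd90_ms: float = 234.0
    upstroke_latency_ms: float = 2.0
    rise_ms: float = 1.5
    tail_ms: float = 30.0
    artifact_mv: float = 5.0

    def __post_init__(self) -> None:
        if self.apd90_ms <= self.apd50_ms or self.apd50_ms <= self.rise_ms:
            raise InvalidSpecError("need rise < apd50 < apd90")
        if self.peak_mv <= self.mdp_mv:
            raise InvalidSpecError("peak must exceed MDP")

    @property
    def apa_mv(self) -> float:
        return self.peak_mv - self.mdp_mv

    @property
    def full_repol_ms(self) -> float:
        """Time from upstroke start to return to MDP."""
        return self.apd90_ms + self.tail_ms


@dataclass
class APProtocol:
    """Pacing/DAD-injection protocol for one simulated impalement."""

    pacing_frequencies_hz: tuple[float, ...] = (1.5,)
    drive_duration_s: float = 30.0
    n_paced: int | None = None
    dad_spec: tuple[tuple[float, float], ...] = ()  # (latency ms, amplitude mV)
    ta_probability: float = 0.0
    seed: int = 0
    shape: APShape = field(default_factory=APShape)

    def __post_init__(self) -> None:
        for f in self.pacing_frequencies_hz:
            if not 1.0 <= f <= 4.0:
                raise InvalidSpecError("pacing frequencies must lie in 1-4 Hz")
        if not 0.0 <= self.ta_probability <= 1.0:
            raise InvalidSpecError("ta_probability must lie in [0, 1]")
        for latency, amp in self.dad_spec:
            if amp <= 0:
                raise InvalidSpecError("DAD amplitudes must be positive")
            if latency < self.shape.upstroke_latency_ms + self.shape.full_repol_ms:
                raise InvalidSpecError(
                    "DAD latency falls before full repolarization of the last AP"
                )

    def stimuli_per_drive(self, freq_hz: float) -> int:
        if self.n_paced is not None:
            return self.n_paced
        return max(1, int(round(self.drive_duration_s * freq_hz)))


@dataclass
class DADEvent:
    time_ms: float
    amplitude_mv: float


@dataclass
class TAEvent:
    time_ms: float  # upstroke start (= peak of the carrying DAD)
    dad_index: int


@dataclass
class APTrace:
    samples: np.ndarray
    fs: float
    stimulus_times_ms: tuple[float, ...]
    pacing_frequency_hz: float
    drive_bounds_ms: tuple[tuple[float, float], ...] = ()


@dataclass
class SyntheticAPTrace(APTrace):
    truth_dads: tuple[DADEvent, ...] = ()
    truth_tas: tuple[TAEvent, ...] = ()


def _render_ap(
    x: np.ndarray, t_ms: np.ndarray, start_ms: float, shape: APShape, base_mv: float
) -> None:
    """Add one AP (upstroke beginning at ``start_ms``) on top of
    ``base_mv``; repolarization returns to the trace's MDP."""
    apa = shape.peak_mv - shape.mdp_mv
    v50 = shape.peak_mv - 0.5 * apa
    v90 = shape.peak_mv - 0.9 * apa
    pts_t = np.array(
        [
            0.0,
            shape.rise_ms,
            shape.apd50_ms,
            shape.apd90_ms,
            shape.apd90_ms + shape.tail_ms,
        ]
    )
    pts_v = np.array([base_mv, shape.peak_mv, v50, v90, shape.mdp_mv])
    rel = t_ms - start_ms
    sel = (rel >= 0) & (rel <= pts_t[-1])
    x[sel] = np.interp(rel[sel], pts_t, pts_v)


def _render_artifact(
    x: np.ndarray, t_ms: np.ndarray, at_ms: float, amp_mv: float
) -> None:
    rel = t_ms - at_ms
    sel = (rel >= 0) & (rel < 1.0)
    x[sel] += np.where(rel[sel] < 0.5, amp_mv, -amp_mv)


def simulate_ap_trace(
    protocol: APProtocol, fs: float = DEFAULT_AP_FS_HZ
) -> SyntheticAPTrace:
    """Simulate the full protocol: one drive per pacing frequency, DADs (and
    probabilistic TA) injected after the last paced AP of each drive."""
    rng = np.random.default_rng(protocol.seed)
    shape = protocol.shape
    post_ms = 500.0
    if protocol.dad_spec:
        post_ms = max(
            post_ms,
            max(l for l, _ in protocol.dad_spec) + shape.full_repol_ms + 300.0,
        )
    gap_ms = 300.0

    segments: list[tuple[float, float, float]] = []  # (start, end, freq)
    stimuli: list[float] = []
    cursor = 200.0
    for f in protocol.pacing_frequencies_hz:
        n = protocol.stimuli_per_drive(f)
        interval = 1000.0 / f
        stims = [cursor + i * interval for i in range(n)]
        stimuli.extend(stims)
        end = stims[-1] + post_ms
        segments.append((cursor, end, f))
        cursor = end + gap_ms

    total_ms = cursor + 100.0
    n_samples = int(round(total_ms * fs / 1000.0))
    t_ms = np.arange(n_samples) * 1000.0 / fs
    x = np.full(n_samples, shape.mdp_mv)

    dads: list[DADEvent] = []
    tas: list[TAEvent] = []
    for start, end, f in segments:
        n = protocol.stimuli_per_drive(f)
        interval = 1000.0 / f
        stims = [start + i * interval for i in range(n)]
        for s in stims:
            _render_ap(x, t_ms, s + shape.upstroke_latency_ms, shape, shape.mdp_mv)
        for s in stims:
            _render_artifact(x, t_ms, s, shape.artifact_mv)
        last_up = stims[-1] + shape.upstroke_latency_ms
        for latency, amp in protocol.dad_spec:
            peak_ms = stims[-1] + latency
            sigma = 20.0
            rel = (t_ms - peak_ms) / sigma
            win = np.abs(rel) < 6.0
            x[win] += amp * np.exp(-0.5 * rel[win] ** 2)
            dads.append(DADEvent(time_ms=peak_ms, amplitude_mv=amp))
            if protocol.ta_probability > 0 and rng.random() < protocol.ta_probability:
                _render_ap(x, t_ms, peak_ms, shape, shape.mdp_mv + amp)
                tas.append(TAEvent(time_ms=peak_ms, dad_index=len(dads) - 1))
        del last_up

    return SyntheticAPTrace(
        samples=x,
        fs=fs,
        stimulus_times_ms=tuple(stimuli),
        pacing_frequency_hz=protocol.pacing_frequencies_hz[0],
        drive_bounds_ms=tuple((s, e) for s, e, _ in segments),
        truth_dads=tuple(dads),
        truth_tas=tuple(tas),
    )
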
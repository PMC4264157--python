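"""Intracardiac activation-onset detection.

Onsets are marked at the maximum absolute slope (max |dV/dt|) of the
bipolar electrogram.  "Good" channels — regularly spaced onsets with
consistently large peaks — and their neighbors are detected on the raw
signal in a window around the channel's peak amplitude; every other
channel is detected on a boxcar-smoothed copy within its class window
(intracardiac or pacing) and then refined back onto the raw signal.  A
final refractory pass guarantees >= 65 ms between successive onsets on a
channel, re-detecting violators in an 80 ms window starting 65 ms after
the previous signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .session import RecordingSession


@dataclass(frozen=True)
class DetectionConfig:
    smooth_window_samples: int = 50
    good_spacing_ms: float = 120.0
    good_amp_frac: float = 0.60
    good_peak_window_ms: float = 20.0
    intracardiac_window_ms: tuple[float, float] = (-40.0, 80.0)
    pacing_window_ms: tuple[float, float] = (15.0, 150.0)
    refine_ms: float = 8.0
    refractory_ms: float = 65.0
    recalc_window_ms: float = 80.0
    min_amplitude_mv: float = 0.05

    def __post_init__(self) -> None:
        if self.smooth_window_samples < 1:
            raise InvalidArgumentError("smoothing window must be >= 1 sample")
        for v in (
            self.good_spacing_ms,
            self.good_amp_frac,
            self.good_peak_window_ms,
            self.refine_ms,
            self.refractory_ms,
            self.recalc_window_ms,
        ):
            if v <= 0:
                raise InvalidArgumentError("config values must be positive")


@dataclass
class ActivationEvent:
    """One detected intracardiac onset."""

    channel: int
    beat: int
    time_ms: float  # relative to the surface QRS onset of the beat
    mode: str  # "raw_dvdt" | "smoothed_refined"
    is_good_channel: bool = False
    amplitude_mv: float = 0.0
    outlier: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_ms):
            raise InvalidArgumentError("event time must be finite")
        if self.amplitude_mv < 0:
            raise InvalidArgumentError("amplitude must be >= 0")


def smooth_signal(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use shrinking windows so the output
    has the same length as the input.  ``window=1`` is the identity."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("empty input")
    if window < 1 or window > x.size:
        raise InvalidArgumentError("window must be in [1, len(x)]")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )


def dvdt(x: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference derivative, mV/ms."""
    return np.gradient(np.asarray(x, dtype=float)) * fs / 1000.0


def _argmax_absslope(x: np.ndarray, fs: float, lo: int, hi: int) -> int | None:
    """Index of max |dV/dt| inside [lo, hi); ties break earliest."""
    lo = max(lo, 0)
    hi = min(hi, len(x))
    if hi - lo < 3:
        return None
    seg = np.abs(dvdt(x[lo:hi], fs))
    return lo + int(np.argmax(seg))


def flag_good_channels(events_per_beat: dict, config: DetectionConfig) -> dict:
    """Per-channel "good" flag.

    ``events_per_beat`` maps channel -> list of (onset_ms, peak_amplitude_mv)
    over all beats.  A channel is good iff every consecutive onset gap is
    <= ``good_spacing_ms`` and every peak amplitude exceeds
    ``good_amp_frac`` x the channel's average maximum amplitude.
    """
    flags: dict = {}
    for ch, events in events_per_beat.items():
        if not events:
            flags[ch] = False
            continue
        times = np.array([t for t, _ in events], dtype=float)
        amps = np.array([a for _, a in events], dtype=float)
        gaps_ok = times.size < 2 or float(np.diff(np.sort(times)).max()) <= config.good_spacing_ms
        avg_max = float(amps.mean())
        amps_ok = bool(np.all(amps > config.good_amp_frac * avg_max))
        flags[ch] = gaps_ok and amps_ok
    return flags


def _class_window_ms(
    session: RecordingSession, beat: int, config: DetectionConfig
) -> tuple[float, float]:
    """Absolute [start, end) of the class detection window for a beat."""
    kind = session.beat_kinds[beat]
    if kind == "pacing" and session.pacing_onsets_ms is not None:
        p = session.pacing_onsets_ms[beat]
        return p + config.pacing_window_ms[0], p + config.pacing_window_ms[1]
    q = session.qrs_onsets_ms[beat]
    return q + config.intracardiac_window_ms[0], q + config.intracardiac_window_ms[1]


def _peak_in_window(x: np.ndarray, fs: float, lo_ms: float, hi_ms: float):
    """(p2p amplitude, time of max |v|) inside an absolute ms window."""
    lo = max(int(round(lo_ms * fs / 1000.0)), 0)
    hi = min(int(round(hi_ms * fs / 1000.0)), len(x))
    if hi - lo < 2:
        return 0.0, None
    seg = x[lo:hi]
    p2p = float(seg.max() - seg.min())
    peak = lo + int(np.argmax(np.abs(seg)))
    return p2p, peak * 1000.0 / fs


def detect_all_onsets(
    session: RecordingSession,
    beat: int,
    config: DetectionConfig = DetectionConfig(),
    good_flags: dict | None = None,
) -> list[ActivationEvent]:
    """Detect one onset per channel for one beat.

    Good channels and their neighbors: raw max |dV/dt| within
    +/- ``good_peak_window_ms`` of the channel's peak amplitude.  Other
    channels: max |dV/dt| of the smoothed signal inside the class window,
    refined to the raw max |dV/dt| within +/- ``refine_ms``.  VF beats are
    always detected raw.  Channels whose window holds no deflection are
    silently skipped (missing-event, not failure).
    """
    if beat < 0 or beat >= session.n_beats:
        raise InvalidArgumentError("beat index out of range")
    if good_flags is None:
        good_flags = {ch: False for ch in range(session.n_channels)}
    fs = session.fs
    qrs = session.qrs_onsets_ms[beat]
    is_vf = session.beat_kinds[beat] == "vf"
    lo_ms, hi_ms = _class_window_ms(session, beat, config)

    # neighbors of good channels: same needle or grid-adjacent needle
    good_needles = {
        session.channel_map[ch].needle
        for ch, g in good_flags.items()
        if g and ch < session.n_channels
    }
    grid = session.grid

    def near_good(ch: int) -> bool:
        nd = session.channel_map[ch].needle
        return any(
            nd == gn or grid.needles_adjacent(nd, gn) for gn in good_needles
        )

    # reference for not-good intracardiac windows: median onset of good
    # channels on the same needle for this beat, else the surface QRS onset
    good_times_by_needle: dict[int, list[float]] = {}

    events: list[ActivationEvent] = []
    pending: list[tuple[int, bool]] = []
    for ch in range(session.n_channels):
        x = session.signals[ch]
        p2p, peak_ms = _peak_in_window(x, fs, lo_ms, hi_ms)
        if p2p < config.min_amplitude_mv or peak_ms is None:
            continue  # missing-event
        good = bool(good_flags.get(ch, False))
        if not is_vf and (good or near_good(ch)):
            w = config.good_peak_window_ms
            idx = _argmax_absslope(
                x,
                fs,
                int(round((peak_ms - w) * fs / 1000.0)),
                int(round((peak_ms + w) * fs / 1000.0)) + 1,
            )
            if idx is None:
                continue
            t_ms = idx * 1000.0 / fs
            events.append(
                ActivationEvent(ch, beat, t_ms - qrs, "raw_dvdt", good, p2p)
            )
            if good:
                good_times_by_needle.setdefault(
                    session.channel_map[ch].needle, []
                ).append(t_ms - qrs)
        else:
            pending.append((ch, good))

    for ch, good in pending:
        x = session.signals[ch]
        w_lo, w_hi = lo_ms, hi_ms
        if not is_vf and session.beat_kinds[beat] == "intracardiac":
            nd = session.channel_map[ch].needle
            ref_times = good_times_by_needle.get(nd)
            if ref_times:
                ref = qrs + float(np.median(ref_times))
                w_lo = ref + config.intracardiac_window_ms[0]
                w_hi = ref + config.intracardiac_window_ms[1]
        lo = int(round(w_lo * fs / 1000.0))
        hi = int(round(w_hi * fs / 1000.0))
        p2p, _ = _peak_in_window(x, fs, w_lo, w_hi)
        if p2p < config.min_amplitude_mv:
            continue
        if is_vf:
            idx = _argmax_absslope(x, fs, lo, hi)
            mode = "raw_dvdt"
        else:
            xs = smooth_signal(x, min(config.smooth_window_samples, x.size))
            idx_s = _argmax_absslope(xs, fs, lo, hi)
            if idx_s is None:
                continue
            r = int(round(config.refine_ms * fs / 1000.0))
            idx = _argmax_absslope(x, fs, idx_s - r, idx_s + r + 1)
            mode = "smoothed_refined"
        if idx is None:
            continue
        events.append(
            ActivationEvent(ch, beat, idx * 1000.0 / fs - qrs, mode, good, p2p)
        )
    return events


def enforce_refractory(
    events_by_channel: dict[int, list[float]],
    session: RecordingSession,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[dict[int, list[float]], list[tuple[int, float, str]]]:
    """Enforce the >= ``refractory_ms`` spacing per channel.

    ``events_by_channel`` maps channel -> sorted absolute onset times (ms).
    A violator is re-detected at max |dV/dt| inside the
    ``recalc_window_ms`` window starting ``refractory_ms`` after the
    previous signal; if no deflection lives there it is dropped.  Returns
    (corrected events, dropped (channel, time, reason) records).  The
    operation is idempotent.
    """
    fs = session.fs
    out: dict[int, list[float]] = {}
    dropped: list[tuple[int, float, str]] = []
    for ch, times in events_by_channel.items():
        x = session.signals[ch]
        kept: list[float] = []
        for t in sorted(times):
            if not kept or t - kept[-1] >= config.refractory_ms:
                kept.append(t)
                continue
            w_lo = kept[-1] + config.refractory_ms
            w_hi = w_lo + config.recalc_window_ms
            p2p, _ = _peak_in_window(x, fs, w_lo, w_hi)
            idx = _argmax_absslope(
                x, fs, int(round(w_lo * fs / 1000.0)), int(round(w_hi * fs / 1000.0))
            )
            if idx is None or p2p < config.min_amplitude_mv:
                dropped.append((ch, t, "no deflection in recalculation window"))
                continue
            t_new = idx * 1000.0 / fs
            if kept and t_new - kept[-1] < config.refractory_ms:
                dropped.append((ch, t, "recalculated onset still refractory"))
                continue
            kept.append(t_new)
        out[ch] = kept
    return out, dropped


def detect_events(
    session: RecordingSession, config: DetectionConfig = DetectionConfig()
) -> list[ActivationEvent]:
    """Full per-record pipeline: provisional raw detection on every beat,
    good-channel flagging, class-specific re-detection, refractory pass."""
    # pass 1: provisional raw onsets and peak amplitudes per beat
    provisional: dict[int, list[tuple[float, float]]] = {
        ch: [] for ch in range(session.n_channels)
    }
    fs = session.fs
    for beat in range(session.n_beats):
        lo_ms, hi_ms = _class_window_ms(session, beat, config)
        for ch in range(session.n_channels):
            x = session.signals[ch]
            p2p, _ = _peak_in_window(x, fs, lo_ms, hi_ms)
            if p2p < config.min_amplitude_mv:
                continue
            idx = _argmax_absslope(
                x,
                fs,
                int(round(lo_ms * fs / 1000.0)),
                int(round(hi_ms * fs / 1000.0)),
            )
            if idx is not None:
                provisional[ch].append((idx * 1000.0 / fs, p2p))

    good = flag_good_channels(provisional, config)

    # pass 2: class-specific detection
    events: list[ActivationEvent] = []
    for beat in range(session.n_beats):
        events.extend(detect_all_onsets(session, beat, config, good_flags=good))

    # pass 3: refractory check on absolute times
    by_channel: dict[int, list[tuple[float, ActivationEvent]]] = {}
    for ev in events:
        t_abs = session.qrs_onsets_ms[ev.beat] + ev.time_ms
        by_channel.setdefault(ev.channel, []).append((t_abs, ev))
    corrected, _dropped = enforce_refractory(
        {ch: [t for t, _ in sorted(v)] for ch, v in by_channel.items()},
        session,
        config,
    )
    final: list[ActivationEvent] = []
    for ch, pairs in by_channel.items():
        pairs = sorted(pairs)
        new_times = corrected[ch]
        # pair surviving corrected times back to their source events in order
        i = 0
        for t_abs, ev in pairs:
            if i >= len(new_times):
                break
            # a dropped event shifts the pairing; match greedily by order
            if len(new_times) < len(pairs) and abs(new_times[i] - t_abs) > (
                config.refractory_ms + config.recalc_window_ms
            ):
                continue
            t_new = new_times[i]
            i += 1
            final.append(
                replace(ev, time_ms=t_new - session.qrs_onsets_ms[ev.beat])
            )
    return sorted(final, key=lambda e: (e.beat, e.channel))
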
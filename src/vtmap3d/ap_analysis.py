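"""Action-potential feature extraction and DAD / triggered-activity
detection from microelectrode traces.

MDP is the mean diastolic voltage just before the stimulus artifact
averaged over paced complexes; APA is the excursion from MDP to the
phase-1 peak; APD50/APD90 run from the upstroke (max dV/dt) to 50%/90%
repolarization.  DADs are transient depolarizations after full
repolarization of the last paced AP; TA is a full AP taking off from a
DAD peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ap_simulate import APTrace, DADEvent, TAEvent
from .errors import InsufficientDataError, InvalidArgumentError

#: Diastolic window for MDP: 5 ms ending 1 ms before the stimulus.
MDP_WINDOW_MS = (6.0, 1.0)

#: Skip this long after the stimulus before searching for the upstroke,
#: to clear the stimulus artifact.
ARTIFACT_SKIP_MS = 1.2

#: DADs must exceed the diastolic baseline by this much (mV).
DAD_THRESHOLD_MV = 1.0

#: TA upstroke must reach this fraction of the paced APA ...
TA_APA_FRAC = 0.60
#: ... and cross this absolute voltage (mV).
TA_CROSS_MV = -40.0

#: Slope separating a TA upstroke from a DAD hump (mV/ms).
UPSTROKE_SLOPE_MV_PER_MS = 5.0

#: "Full repolarization" = within this fraction of the AP excursion of MDP.
REPOL_FRAC = 0.9


@dataclass
class APFeatures:
    mdp_mv: float  # also reported as RMP
    apa_mv: float
    apd50_ms: float
    apd90_ms: float

    def __post_init__(self) -> None:
        if self.apa_mv <= 0:
            raise InvalidArgumentError("APA must be positive")
        if not self.apd90_ms >= self.apd50_ms > 0:
            raise InvalidArgumentError("need APD90 >= APD50 > 0")


def _dvdt(x: np.ndarray, fs: float) -> np.ndarray:
    return np.gradient(x) * fs / 1000.0


def _crossing_after(
    x: np.ndarray, start: int, level: float, fs: float
) -> float | None:
    below = np.nonzero(x[start:] <= level)[0]
    if below.size == 0:
        return None
    return (start + int(below[0])) * 1000.0 / fs


def extract_ap_features(
    trace: APTrace,
    stimulus_times_ms=None,
    n_complexes: int = 10,
) -> APFeatures:
    """Average AP features over ``n_complexes`` paced complexes."""
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.fs
    stims = list(
        trace.stimulus_times_ms if stimulus_times_ms is None else stimulus_times_ms
    )
    # keep complexes fully inside the record
    stims = [s for s in stims if (s + 600.0) * fs / 1000.0 < x.size and s > 10.0]
    if len(stims) < n_complexes:
        raise InsufficientDataError(
            f"need >= {n_complexes} paced complexes, have {len(stims)}"
        )
    stims = stims[:n_complexes]
    slope = _dvdt(x, fs)

    mdps, apas, apd50s, apd90s = [], [], [], []
    for s in stims:
        i_s = int(round(s * fs / 1000.0))
        w0 = i_s - int(round(MDP_WINDOW_MS[0] * fs / 1000.0))
        w1 = i_s - int(round(MDP_WINDOW_MS[1] * fs / 1000.0))
        mdp = float(np.mean(x[w0:w1]))
        u0 = i_s + int(round(ARTIFACT_SKIP_MS * fs / 1000.0))
        u1 = i_s + int(round(30.0 * fs / 1000.0))
        up = u0 + int(np.argmax(slope[u0:u1]))
        p0, p1 = up, up + int(round(30.0 * fs / 1000.0))
        peak_idx = p0 + int(np.argmax(x[p0:p1]))
        peak = float(x[peak_idx])
        apa = peak - mdp
        t50 = _crossing_after(x, peak_idx, peak - 0.5 * apa, fs)
        t90 = _crossing_after(x, peak_idx, peak - 0.9 * apa, fs)
        if t50 is None or t90 is None:
            raise InsufficientDataError("repolarization not captured")
        t_up = up * 1000.0 / fs
        mdps.append(mdp)
        apas.append(apa)
        apd50s.append(t50 - t_up)
        apd90s.append(t90 - t_up)
    return APFeatures(
        mdp_mv=float(np.mean(mdps)),
        apa_mv=float(np.mean(apas)),
        apd50_ms=float(np.mean(apd50s)),
        apd90_ms=float(np.mean(apd90s)),
    )


def _diastolic_baseline(x: np.ndarray) -> float:
    """Robust post-drive diastolic level (DAD/TA humps are excursions above
    it, so a low percentile tracks the baseline under offset and gain)."""
    return float(np.percentile(x, 10.0))


def full_repolarization_ms(
    trace: APTrace, features: APFeatures | None = None
) -> float:
    """Time at which the last paced AP has fully repolarized (returned to
    within 10% of MDP)."""
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.fs
    last = max(trace.stimulus_times_ms)
    start = int(round((last + 30.0) * fs / 1000.0))
    tail = x[start:]
    base = _diastolic_baseline(tail)
    peak = float(tail.max()) if features is None else base + features.apa_mv
    level = base + (1.0 - REPOL_FRAC) * (peak - base)
    t = _crossing_after(x, start, level, fs)
    if t is None:
        return last + 30.0
    return t


def detect_dads(
    trace: APTrace,
    last_paced_end_ms: float | None = None,
    threshold_mv: float = DAD_THRESHOLD_MV,
    fs: float | None = None,
) -> list[DADEvent]:
    """Transient depolarizations above threshold after full repolarization
    of the last paced AP.  A TA-bearing DAD is reported at the point its
    upstroke takes off (the DAD peak)."""
    x = np.asarray(trace.samples, dtype=float)
    fs = fs or trace.fs
    if last_paced_end_ms is None:
        last_paced_end_ms = full_repolarization_ms(trace)
    start = int(round(last_paced_end_ms * fs / 1000.0)) + 1
    if start >= x.size:
        return []
    base = _diastolic_baseline(x[start:])
    # skip the residual tail of the last AP's repolarization
    while start < x.size and x[start] > base + threshold_mv:
        start += 1
    post = x[start:]
    if post.size == 0:
        return []
    above = post > base + threshold_mv
    slope = _dvdt(post, fs)

    events: list[DADEvent] = []
    i = 0
    n = post.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        region = slice(i, j)
        fast = np.nonzero(slope[region] > UPSTROKE_SLOPE_MV_PER_MS)[0]
        if fast.size:
            k = i + int(fast[0])  # TA upstroke start = DAD peak
        else:
            k = i + int(np.argmax(post[region]))
        events.append(
            DADEvent(
                time_ms=(start + k) * 1000.0 / fs,
                amplitude_mv=float(post[k] - base),
            )
        )
        i = j
    return events


def detect_ta(
    trace: APTrace,
    dads: list[DADEvent],
    apa_ref_mv: float,
    fs: float | None = None,
    apa_frac: float = TA_APA_FRAC,
    cross_mv: float = TA_CROSS_MV,
) -> list[TAEvent]:
    """Full APs taking off at DAD peaks: the excursion after the DAD must
    reach ``apa_frac`` of the paced APA and cross ``cross_mv``."""
    x = np.asarray(trace.samples, dtype=float)
    fs = fs or trace.fs
    base = _diastolic_baseline(x)
    out: list[TAEvent] = []
    for idx, dad in enumerate(dads):
        lo = int(round(dad.time_ms * fs / 1000.0))
        hi = min(x.size, lo + int(round(100.0 * fs / 1000.0)))
        if hi - lo < 2:
            continue
        peak = float(x[lo:hi].max())
        if peak - base >= apa_frac * apa_ref_mv and peak >= cross_mv:
            out.append(TAEvent(time_ms=dad.time_ms, dad_index=idx))
    return out


def ta_rate(ta_counts, n_trials: int) -> float:
    """Total TA across trials divided by the number of trials."""
    if n_trials < 1:
        raise InvalidArgumentError("need at least one trial")
    counts = [int(c) for c in ta_counts]
    if any(c < 0 for c in counts):
        raise InvalidArgumentError("counts must be >= 0")
    return float(sum(counts)) / float(n_trials)
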
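"""Tachycardia mechanism and episode classification.

A complex is *reentrant* when the site recording its earliest activity is
grid-adjacent to the site of the latest activation of the previous complex
(supported, when available, by diastolic bridging or conduction-block
voltage evidence).  It is *focal* when the earliest site is surrounded by
adjacent sites that activate progressively away from it with no return —
no adjacent activity later than 50% of the cycle length.  Episode typing
separates sustained VT, non-sustained VT, VF and non-episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import smooth_signal
from .errors import InvalidArgumentError
from .grid import ElectrodeGrid, Site
from .mapping import ActivationMap


@dataclass(frozen=True)
class LayerRefractoryConfig:
    """Assumed tachycardia refractory periods; cycle lengths below the
    layer's value flag candidate refractory block."""

    epi_ms: float = 80.0
    endo_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.epi_ms <= 0 or self.endo_ms <= 0:
            raise InvalidArgumentError("refractory periods must be positive")

    def for_layer(self, layer: str) -> float:
        return self.epi_ms if layer == "epi" else self.endo_ms


#: Voltage-reduction fraction marking refractory/unidirectional block.
BLOCK_VOLTAGE_DROP = 0.75

#: "No return" bound for the focal criterion, as a fraction of cycle length.
FOCAL_RETURN_FRAC = 0.5


@dataclass
class MechanismCall:
    kind: str  # "focal" | "reentry" | "indeterminate"
    layer: str | None = None
    purkinje_origin: bool = False
    earliest_site: Site | None = None
    latest_prior_site: Site | None = None
    adjacency_link: bool = False
    block_sites: tuple[Site, ...] = ()
    diastolic_bridge: bool = False


@dataclass
class EpisodeCall:
    type: str  # sustained_VT | nonsustained_VT | VF | not_an_episode
    duration_s: float
    n_complexes: int
    terminated_by: str = "none"
    analyzed_prefix: tuple[int, int] | None = None


def _block_sites(
    amplitudes: dict[Site, tuple[float, float]] | None,
) -> tuple[Site, ...]:
    """Sites showing a >75% voltage reduction followed by increased voltage
    on the next activation; ``amplitudes`` maps site -> (this beat's p2p,
    next beat's p2p) relative to the site's reference amplitude."""
    if not amplitudes:
        return ()
    out = []
    for site, (frac_now, frac_next) in amplitudes.items():
        if frac_now <= (1.0 - BLOCK_VOLTAGE_DROP) and frac_next > frac_now:
            out.append(site)
    return tuple(out)


def classify_beat_mechanism(
    prev_map: ActivationMap,
    cur_map: ActivationMap,
    grid: ElectrodeGrid,
    cycle_length_ms: float,
    amplitudes: dict[Site, tuple[float, float]] | None = None,
    refractory: LayerRefractoryConfig = LayerRefractoryConfig(),
) -> MechanismCall:
    """Classify one complex given it and its predecessor's maps."""
    if cycle_length_ms <= 0:
        raise InvalidArgumentError("cycle length must be positive")
    if not cur_map.times or not prev_map.times:
        return MechanismCall(kind="indeterminate")
    earliest = cur_map.earliest_site
    latest_prior = prev_map.latest_site
    t0 = cur_map.times[earliest]
    neighbors = [s for s in grid.neighbors(earliest) if s in cur_map.times]
    if len(neighbors) < 2:
        return MechanismCall(
            kind="indeterminate", earliest_site=earliest, latest_prior_site=latest_prior
        )

    adjacency_link = grid.sites_adjacent(earliest, latest_prior)
    blocks = _block_sites(amplitudes)
    span = max(cur_map.times.values()) - t0
    bridge = span >= 0.7 * cycle_length_ms  # near-continuous diastolic activity

    # reentry: earliest-adjacent-to-latest is the necessary criterion;
    # bridging/block only support it
    if adjacency_link:
        return MechanismCall(
            kind="reentry",
            layer=earliest.layer,
            earliest_site=earliest,
            latest_prior_site=latest_prior,
            adjacency_link=True,
            block_sites=blocks,
            diastolic_bridge=bridge,
        )

    # focal: all adjacent sites later, spreading away, no late return
    neigh_after = all(cur_map.times[s] > t0 for s in neighbors)
    no_return = all(
        cur_map.times[s] - t0 <= FOCAL_RETURN_FRAC * cycle_length_ms
        for s in neighbors
    )
    dists = np.array([grid.distance_mm(earliest, s) for s in cur_map.times])
    times = np.array([cur_map.times[s] for s in cur_map.times])
    if len(dists) > 2 and np.std(dists) > 0 and np.std(times) > 0:
        spread_away = float(np.corrcoef(dists, times)[0, 1]) > 0.0
    else:
        spread_away = True
    if neigh_after and no_return and spread_away:
        return MechanismCall(
            kind="focal",
            layer=earliest.layer,
            earliest_site=earliest,
            latest_prior_site=latest_prior,
            adjacency_link=False,
            block_sites=blocks,
            diastolic_bridge=bridge,
        )
    return MechanismCall(
        kind="indeterminate",
        layer=earliest.layer,
        earliest_site=earliest,
        latest_prior_site=latest_prior,
        block_sites=blocks,
        diastolic_bridge=bridge,
    )


def classify_episode_mechanism(
    maps: list[ActivationMap],
    grid: ElectrodeGrid,
    cycle_length_ms: float,
    amplitudes=None,
    refractory: LayerRefractoryConfig = LayerRefractoryConfig(),
) -> tuple[MechanismCall, list[MechanismCall]]:
    """Classify every complex (from the second onward) and return the
    majority call plus the per-complex calls."""
    if len(maps) < 2:
        raise InvalidArgumentError("need >= 2 consecutive mapped complexes")
    calls = [
        classify_beat_mechanism(
            maps[k - 1], maps[k], grid, cycle_length_ms, amplitudes, refractory
        )
        for k in range(1, len(maps))
    ]
    keyed = [(c.kind, c.layer) for c in calls if c.kind != "indeterminate"]
    if not keyed:
        return MechanismCall(kind="indeterminate"), calls
    kinds = sorted(set(keyed), key=keyed.count)
    kind, layer = kinds[-1]
    winner = next(c for c in calls if (c.kind, c.layer) == (kind, layer))
    return winner, calls


# ---------------------------------------------------------------------------
# Purkinje prepotential
# ---------------------------------------------------------------------------

#: Acceptable prepotential amplitude (mV), spike width (ms) and lead (ms).
PURKINJE_AMP_MV = (0.2, 1.5)
PURKINJE_WIDTH_MS = (0.5, 2.5)
PURKINJE_LEAD_MS = (1.0, 11.0)


def find_prepotential(
    x: np.ndarray, onset_ms: float, fs: float
) -> float | None:
    """Lead (ms) of a Purkinje-like spike ahead of an onset, or None.

    The slow muscle shoulder is removed with a short moving average; a
    candidate spike in the residual must match the amplitude, width and
    1-11 ms lead criteria.
    """
    smooth_w = max(3, int(round(4.0 * fs / 1000.0)))
    lo = int(round((onset_ms - PURKINJE_LEAD_MS[1] - 3.0) * fs / 1000.0))
    hi = int(round((onset_ms - PURKINJE_LEAD_MS[0] + 1.0) * fs / 1000.0))
    if lo < smooth_w or hi > len(x) or hi - lo < 4:
        return None
    resid = x - smooth_signal(x, smooth_w)
    seg = np.abs(resid[lo:hi])
    pk = lo + int(np.argmax(seg))
    amp = float(np.abs(resid[pk]))
    if not PURKINJE_AMP_MV[0] <= amp <= PURKINJE_AMP_MV[1]:
        return None
    # width at half max around the peak
    half = amp / 2.0
    left = pk
    while left > lo and np.abs(resid[left - 1]) >= half:
        left -= 1
    right = pk
    while right < hi - 1 and np.abs(resid[right + 1]) >= half:
        right += 1
    width_ms = (right - left + 1) * 1000.0 / fs
    if not PURKINJE_WIDTH_MS[0] <= width_ms <= PURKINJE_WIDTH_MS[1]:
        return None
    lead = onset_ms - pk * 1000.0 / fs
    if not PURKINJE_LEAD_MS[0] <= lead <= PURKINJE_LEAD_MS[1]:
        return None
    return lead


def _prepotential_channels(signals, onsets_ms: dict[int, float], fs: float):
    return {
        ch
        for ch, onset in onsets_ms.items()
        if find_prepotential(signals[ch], onset, fs) is not None
    }


def detect_purkinje_origin(
    vt_signals: np.ndarray,
    vt_onsets_ms: dict[int, float],
    ref_pre_signals: np.ndarray,
    ref_pre_onsets_ms: dict[int, float],
    ref_post_signals: np.ndarray,
    ref_post_onsets_ms: dict[int, float],
    fs: float,
    min_channels: int = 2,
) -> bool:
    """Purkinje origin: a 0.5 mV, 1-2 ms spike leading the endocardial
    muscle deflection by 1-11 ms on >= ``min_channels`` channels, present
    on the VT focus beat AND on atrial-paced beats recorded both before
    and after occlusion.  Raises if a reference recording is absent.
    """
    for ref in (ref_pre_signals, ref_post_signals):
        if ref is None:
            raise InvalidArgumentError(
                "pre- and post-occlusion atrial-paced references are required"
            )
    vt = _prepotential_channels(vt_signals, vt_onsets_ms, fs)
    pre = _prepotential_channels(ref_pre_signals, ref_pre_onsets_ms, fs)
    post = _prepotential_channels(ref_post_signals, ref_post_onsets_ms, fs)
    return (
        len(vt) >= min_channels
        and len(pre) >= min_channels
        and len(post) >= min_channels
    )


# ---------------------------------------------------------------------------
# Episode typing
# ---------------------------------------------------------------------------

SUSTAINED_S = 10.0
MIN_EPISODE_COMPLEXES = 3
VF_PREFIX = (8, 40)


def classify_episode(
    complex_times_ms,
    terminated_by: str = "none",
    qrs_variability: bool = False,
    pressure_collapse: bool = False,
) -> EpisodeCall:
    """Type one induced episode.  Total: every input yields exactly one
    type."""
    times = np.asarray(list(complex_times_ms), dtype=float)
    if times.size < 1:
        raise InvalidArgumentError("need at least one complex")
    if terminated_by not in ("spontaneous", "pacing", "shock", "none"):
        raise InvalidArgumentError(f"unknown termination {terminated_by!r}")
    n = int(times.size)
    duration_s = float(times.max() - times.min()) / 1000.0
    if qrs_variability and pressure_collapse:
        prefix = (0, min(n, VF_PREFIX[1]))
        return EpisodeCall("VF", duration_s, n, terminated_by, prefix)
    if duration_s >= SUSTAINED_S or terminated_by in ("pacing", "shock"):
        return EpisodeCall("sustained_VT", duration_s, n, terminated_by)
    if n >= MIN_EPISODE_COMPLEXES and duration_s < SUSTAINED_S:
        return EpisodeCall("nonsustained_VT", duration_s, n, terminated_by)
    return EpisodeCall("not_an_episode", duration_s, n, terminated_by)
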
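"""3-D activation maps: layer-consistency margins, onset sequencing and
isochrone banding.

The adjacency assessment checks whether the onsets detected on the layers
of one needle are mutually consistent: neighboring layers (endo-mid,
mid-epi) must agree within 20 ms and endo-epi within 30 ms at the first
onset, growing by 2 and 3 ms respectively for each following onset.  A
layer lying outside the margin of BOTH other layers is an outlier and is
re-detected inside the trend window spanned by the other two layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionConfig, _argmax_absslope, _peak_in_window
from .errors import InvalidArgumentError
from .grid import LAYERS, Site
from .session import RecordingSession

NEIGHBOR_MARGIN_MS = 20.0
ENDO_EPI_MARGIN_MS = 30.0
NEIGHBOR_GROWTH_MS = 2.0
ENDO_EPI_GROWTH_MS = 3.0

_PAIRS = (("endo", "mid"), ("mid", "epi"), ("endo", "epi"))


def pair_margin_ms(layer_a: str, layer_b: str, k: int) -> float:
    """Consistency margin for a layer pair at onset index ``k`` (0-based)."""
    if k < 0:
        raise InvalidArgumentError("onset index must be >= 0")
    pair = tuple(sorted((layer_a, layer_b), key=LAYERS.index))
    if pair == ("endo", "epi"):
        return ENDO_EPI_MARGIN_MS + ENDO_EPI_GROWTH_MS * k
    return NEIGHBOR_MARGIN_MS + NEIGHBOR_GROWTH_MS * k


@dataclass
class AdjacencyAssessment:
    needle: int
    onset_index: int
    flags: dict[tuple[str, str], bool | None]
    margins_ms: dict[tuple[str, str], float]


def build_adjacency(
    events: dict[int, dict[str, float]], k: int
) -> list[AdjacencyAssessment]:
    """Layer-pair consistency per needle for onset index ``k``.

    ``events`` maps needle -> {layer: onset time ms}.  Missing layers yield
    ``None`` flags.
    """
    out = []
    for needle, layer_times in events.items():
        flags: dict[tuple[str, str], bool | None] = {}
        margins: dict[tuple[str, str], float] = {}
        for a, b in _PAIRS:
            m = pair_margin_ms(a, b, k)
            margins[(a, b)] = m
            if a in layer_times and b in layer_times:
                flags[(a, b)] = abs(layer_times[a] - layer_times[b]) <= m
            else:
                flags[(a, b)] = None
        out.append(AdjacencyAssessment(needle, k, flags, margins))
    return out


def _find_outlier(layer_times: dict[str, float], k: int) -> str | None:
    """The single layer outside the margin of BOTH other layers, if any."""
    if len(layer_times) < 3:
        return None
    for layer in layer_times:
        others = [l for l in layer_times if l != layer]
        out_of_both = all(
            abs(layer_times[layer] - layer_times[o]) > pair_margin_ms(layer, o, k)
            for o in others
        )
        a, b = others
        others_agree = abs(layer_times[a] - layer_times[b]) <= pair_margin_ms(a, b, k)
        if out_of_both and others_agree:
            return layer
    return None


def sequence_onsets(
    events: dict[Site, float],
    session: RecordingSession,
    beat: int,
    k: int | None = None,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[dict[Site, float], set[Site]]:
    """Relocate per-needle layer outliers (times are ms relative to the
    beat's QRS onset).

    An outlier is re-detected at max |dV/dt| inside the trend window:
    the interval spanned by the two in-margin layers, padded by their pair
    margin.  VF and pacing beats pass through unchanged.  Returns the
    (possibly) adjusted events and the set of sites kept but flagged as
    unresolved outliers.
    """
    if k is None:
        k = beat
    if session.beat_kinds[beat] in ("vf", "pacing"):
        return dict(events), set()
    qrs = session.qrs_onsets_ms[beat]
    fs = session.fs
    adjusted = dict(events)
    flagged: set[Site] = set()
    by_needle: dict[int, dict[str, float]] = {}
    for site, t in events.items():
        by_needle.setdefault(site.needle, {})[site.layer] = t
    for needle, layer_times in by_needle.items():
        outlier = _find_outlier(layer_times, k)
        if outlier is None:
            continue
        others = sorted(
            (t for l, t in layer_times.items() if l != outlier)
        )
        a, b = [l for l in layer_times if l != outlier]
        pad = pair_margin_ms(a, b, k)
        w_lo = qrs + others[0] - pad
        w_hi = qrs + others[1] + pad
        site = Site(needle, outlier)
        ch = session.channel_of(site)
        x = session.signals[ch]
        p2p, _ = _peak_in_window(x, fs, w_lo, w_hi)
        idx = _argmax_absslope(
            x, fs, int(round(w_lo * fs / 1000.0)), int(round(w_hi * fs / 1000.0))
        )
        if idx is None or p2p < config.min_amplitude_mv:
            flagged.add(site)  # trend window empty: keep, flag
            continue
        adjusted[site] = idx * 1000.0 / fs - qrs
    return adjusted, flagged


@dataclass
class ActivationMap:
    """Per-site activation times for one tachycardia complex (ms relative
    to the surface QRS onset)."""

    times: dict[Site, float]
    complex_index: int = 0
    qrs_onset_ms: float = 0.0
    bands: dict[Site, int] = field(default_factory=dict)

    def layer_times(self, layer: str) -> dict[Site, float]:
        return {s: t for s, t in self.times.items() if s.layer == layer}

    @property
    def earliest_site(self) -> Site:
        return min(self.times, key=lambda s: (self.times[s], s))

    @property
    def latest_site(self) -> Site:
        return max(self.times, key=lambda s: (self.times[s], s))


#: Default isochrone edges: white < -25 <= yellow <= 15 < later bands.
DEFAULT_BAND_EDGES = (-25.0, 15.0)
BAND_STEP_MS = 40.0


def band_edges_for(times, edges=DEFAULT_BAND_EDGES, step_ms: float = BAND_STEP_MS):
    """Extend the printed early edges with uniform bands up to the latest
    mapped time."""
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise InvalidArgumentError("band edges must increase")
    t_max = max(times) if len(times) else edges[-1]
    while edges[-1] < t_max:
        edges.append(edges[-1] + step_ms)
    return tuple(edges)


def band_of(time_ms: float, edges) -> int:
    """Band index of one time: 0 = white (< first edge), 1 = yellow
    ([first edge, second edge]), later bands right-closed."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise InvalidArgumentError("band edges must increase")
    if time_ms < edges[0]:
        return 0
    return 1 + int(np.searchsorted(edges[1:], time_ms, side="left"))


def band_label(index: int, n_bands: int) -> str:
    if index == 0:
        return "white"
    if index == 1:
        return "yellow"
    if index >= n_bands - 1:
        return "green"
    return "red"


def compute_isochrones(amap: ActivationMap, band_edges=None) -> ActivationMap:
    """Assign each mapped site its isochrone band (in place; also returns
    the map)."""
    times = list(amap.times.values())
    edges = (
        band_edges_for(times)
        if band_edges is None
        else band_edges_for(times, band_edges)
    )
    amap.bands = {s: band_of(t, edges) for s, t in amap.times.items()}
    return amap


def maps_from_events(
    events_rel: list[dict[Site, float]], qrs_onsets_ms
) -> list[ActivationMap]:
    """Wrap per-complex relative event dicts as ActivationMaps."""
    return [
        ActivationMap(times=dict(ev), complex_index=k, qrs_onset_ms=q)
        for k, (ev, q) in enumerate(zip(events_rel, qrs_onsets_ms))
    ]
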
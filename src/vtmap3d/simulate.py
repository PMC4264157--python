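"""Synthetic plunge-needle electrogram episodes with known ground truth.

The generator is phenomenological, not biophysical: each activation is a
biphasic deflection (Gaussian-derivative template) whose steepest negative
slope marks the true onset, wavefronts travel at a fixed conduction
velocity over the site graph, and reentry is modelled by pinning an ordered
circuit of adjacent sites to phases of the cycle so that the earliest site
of every complex is grid-adjacent to the latest site of the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidArgumentError, InvalidSpecError
from .grid import ElectrodeGrid, Site
from .session import DEFAULT_BAND_HZ, DEFAULT_FS_HZ, RecordingSession

#: Minimum spacing between activations on one channel (ms).
REFRACTORY_MS = 65.0

#: Peak-to-peak of a unit-scale Gaussian-derivative template.
_TEMPLATE_P2P = 2.0 * np.exp(-0.5)

MECHANISM_KINDS = ("paced", "focal", "reentry", "vf_onset")


@dataclass(frozen=True)
class PurkinjeSpec:
    """Prepotential added ahead of the muscle deflection: a brief
    low-amplitude spike leading the onset by 1-11 ms."""

    lead_ms: float = 5.0
    amplitude_mv: float = 0.5
    width_ms: float = 1.5

    def __post_init__(self) -> None:
        if not 1.0 <= self.lead_ms <= 11.0:
            raise InvalidSpecError("purkinje lead must lie in [1, 11] ms")
        if not 0.5 <= self.width_ms <= 2.5:
            raise InvalidSpecError("purkinje spike width must be ~1-2 ms")


@dataclass
class MechanismSpec:
    """Ground-truth mechanism driving one simulated episode."""

    kind: str
    origin_site: Site | None = None
    circuit_sites: tuple[Site, ...] = ()
    layer: str = "endo"
    cycle_length_ms: float = 150.0
    conduction_velocity_mm_per_ms: float = 0.5
    block_site: Site | None = None
    purkinje: PurkinjeSpec | None = None
    n_complexes: int = 5
    circuit_phases_ms: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MECHANISM_KINDS:
            raise InvalidSpecError(f"unknown mechanism kind {self.kind!r}")
        if self.cycle_length_ms <= 0:
            raise InvalidSpecError("cycle length must be positive")
        if self.conduction_velocity_mm_per_ms <= 0:
            raise InvalidSpecError("conduction velocity must be positive")
        if self.n_complexes < 1:
            raise InvalidSpecError("need at least one complex")
        if self.kind == "reentry":
            if len(self.circuit_sites) < 3:
                raise InvalidSpecError("reentry requires >= 3 circuit sites")
            if self.circuit_phases_ms is not None and len(
                self.circuit_phases_ms
            ) != len(self.circuit_sites):
                raise InvalidSpecError("one phase per circuit site")
        elif self.kind == "vf_onset":
            if not 8 <= self.n_complexes <= 40:
                raise InvalidSpecError(
                    "vf analyzable prefix must span 8-40 complexes"
                )
            if self.origin_site is None:
                raise InvalidSpecError("vf_onset requires an origin site")
        elif self.origin_site is None:
            raise InvalidSpecError(f"{self.kind} requires an origin site")


@dataclass
class SyntheticRecording:
    """A simulated session bundled with its per-channel ground truth."""

    session: RecordingSession
    truth_onsets: dict[int, list[float]]
    truth_mechanism: MechanismSpec
    qrs_onsets_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        span = self.session.duration_ms
        for ch, onsets in self.truth_onsets.items():
            arr = np.asarray(onsets, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise InvalidSpecError("truth onsets must be finite")
            if arr.size and (arr.min() < 0 or arr.max() > span):
                raise InvalidSpecError("truth onset outside recorded span")
            if arr.size > 1 and np.diff(arr).min() < REFRACTORY_MS:
                raise InvalidSpecError(
                    f"channel {ch}: truth onsets closer than {REFRACTORY_MS} ms"
                )

    def truth_relative(self, beat: int) -> dict[int, float]:
        """Truth onset of each channel for one complex, ms relative to that
        complex's QRS onset.  Every simulated channel activates exactly once
        per complex, so onset ``beat`` is the one for that complex."""
        q = self.qrs_onsets_ms[beat]
        return {ch: onsets[beat] - q for ch, onsets in self.truth_onsets.items()}


def synthesize_waveform(
    truth_onsets_ms,
    amplitudes_mv,
    fs: float = DEFAULT_FS_HZ,
    n_samples: int | None = None,
    sigma_ms: float = 2.0,
    purkinje: PurkinjeSpec | None = None,
) -> np.ndarray:
    """Render a channel's sample vector from its true onsets.

    Each onset contributes a biphasic Gaussian-derivative deflection whose
    steepest negative slope lies at the onset time (within one sample after
    discretisation) and whose peak-to-peak amplitude is ``amplitudes_mv``.
    A Purkinje spec adds a narrow monophasic spike leading each deflection.
    """
    onsets = np.atleast_1d(np.asarray(truth_onsets_ms, dtype=float))
    amps = np.broadcast_to(
        np.asarray(amplitudes_mv, dtype=float), onsets.shape
    ).astype(float)
    if fs <= 2600.0:
        raise InvalidArgumentError("fs must exceed twice the 1300 Hz band edge")
    if np.any(np.diff(onsets) < 0):
        raise InvalidArgumentError("onsets must be sorted")
    if onsets.size > 1 and np.diff(onsets).min() < 6.0 * sigma_ms:
        raise InvalidSpecError("deflections overlap: onsets closer than template width")
    if n_samples is None:
        n_samples = int(round((onsets.max() + 50.0) * fs / 1000.0)) if onsets.size else 0
    t = np.arange(n_samples) * 1000.0 / fs
    x = np.zeros(n_samples)
    for t0, amp in zip(onsets, amps):
        u = (t - t0) / sigma_ms
        # support is ~6 sigma; render a window only, for speed
        lo = max(0, int((t0 - 8 * sigma_ms) * fs / 1000.0))
        hi = min(n_samples, int((t0 + 8 * sigma_ms) * fs / 1000.0) + 1)
        uw = u[lo:hi]
        x[lo:hi] += (amp / _TEMPLATE_P2P) * (-uw) * np.exp(-0.5 * uw * uw)
        if purkinje is not None:
            ts = t0 - purkinje.lead_ms
            sig_p = purkinje.width_ms / 2.355  # FWHM -> sigma
            plo = max(0, int((ts - 6 * sig_p) * fs / 1000.0))
            phi = min(n_samples, int((ts + 6 * sig_p) * fs / 1000.0) + 1)
            up = (t[plo:phi] - ts) / sig_p
            x[plo:phi] += purkinje.amplitude_mv * np.exp(-0.5 * up * up)
    return x


def band_limited_noise(
    n_samples: int,
    sd_mv: float,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise limited to the acquisition band, rescaled to sd_mv."""
    if sd_mv <= 0 or n_samples == 0:
        return np.zeros(n_samples)
    rng = rng if rng is not None else np.random.default_rng()
    white = rng.standard_normal(n_samples)
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd_mv / s) if s > 0 else shaped


def _relative_times(
    grid: ElectrodeGrid, spec: MechanismSpec, origin_lead_ms: float
) -> tuple[np.ndarray, Site, Site]:
    """Per-site activation time relative to the surface QRS onset for one
    complex, plus the (earliest, latest) ground-truth sites."""
    v = spec.conduction_velocity_mm_per_ms
    sites = grid.sites
    if spec.kind == "reentry":
        circuit = spec.circuit_sites
        for a, b in zip(circuit, circuit[1:] + circuit[:1]):
            if not grid.sites_adjacent(a, b):
                raise InvalidSpecError(
                    f"reentry circuit not closed on grid adjacency: {a} -> {b}"
                )
        m = len(circuit)
        if spec.circuit_phases_ms is not None:
            phases = np.asarray(spec.circuit_phases_ms, dtype=float)
            if np.any(np.diff(phases) <= 0) or phases[0] != 0:
                raise InvalidSpecError("circuit phases must start at 0 and increase")
        else:
            phases = np.arange(m) * spec.cycle_length_ms / m
        idx = {s: grid.site_index[s] for s in circuit}
        rel = np.empty(grid.n_sites)
        for j, s in enumerate(sites):
            if s in idx:
                rel[j] = phases[circuit.index(s)]
            else:
                d = grid.geodesic_mm[[idx[c] for c in circuit], j]
                rel[j] = float(np.min(phases + d / v))
        rel -= origin_lead_ms
        return rel, circuit[0], circuit[-1]
    origin = spec.origin_site
    if origin not in grid.site_index:
        raise InvalidSpecError(f"origin {origin} not on grid")
    d = grid.geodesic_mm[grid.site_index[origin]]
    rel = d / v - origin_lead_ms
    latest = sites[int(np.argmax(rel))]
    return rel, origin, latest


def simulate_episode(
    grid: ElectrodeGrid,
    spec: MechanismSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = DEFAULT_FS_HZ,
    origin_lead_ms: float = 35.0,
    amplitude_scale: dict[Site, float] | None = None,
    sigma_ms: float = 5.0,
    noise_band: tuple[float, float] = (3.0, 150.0),
) -> SyntheticRecording:
    """Simulate one tachycardia episode on ``grid`` with known truth.

    Identical ``(seed, arguments)`` give bit-identical output.  ``noise_sd``
    is additive band-limited Gaussian noise in mV; its default band rolls
    off well below the acquisition band edge, as baseline/motion noise
    dominates real recordings.  ``amplitude_scale`` attenuates chosen sites
    (e.g. ischemic attenuation).
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cl = spec.cycle_length_ms
    pre_ms = 150.0
    n_sites = grid.n_sites
    base_amp = rng.uniform(6.0, 12.0, size=n_sites)
    if amplitude_scale:
        for s, f in amplitude_scale.items():
            base_amp[grid.site_index[s]] *= f

    rel, _earliest, _latest = _relative_times(grid, spec, origin_lead_ms)

    if spec.kind == "vf_onset":
        # analyzable prefix with jittered cycle lengths, then unlabeled chaos
        cls = cl * (1.0 + 0.08 * rng.uniform(-1, 1, size=spec.n_complexes))
        cls = np.maximum(cls, REFRACTORY_MS + rel.max() - rel.min() + 10.0)
        qrs = pre_ms + origin_lead_ms + np.concatenate([[0.0], np.cumsum(cls[:-1])])
    else:
        qrs = pre_ms + origin_lead_ms + cl * np.arange(spec.n_complexes)

    truth: dict[int, list[float]] = {}
    amps: dict[int, list[float]] = {}
    pk_channels: set[int] = set()
    if spec.purkinje is not None and spec.origin_site is not None:
        oi = grid.site_index[spec.origin_site]
        endo = [
            grid.site_index[s]
            for s in grid.neighbors(spec.origin_site)
            if s.layer == spec.origin_site.layer
        ]
        order = np.argsort(grid.geodesic_mm[oi, endo]) if endo else []
        pk_channels = {oi} | {endo[i] for i in order[:2]}

    for j in range(n_sites):
        ts, aa = [], []
        for k, q in enumerate(qrs):
            t = q + rel[j]
            a = base_amp[j]
            if spec.block_site is not None and j == grid.site_index[spec.block_site]:
                if k == 0:
                    a *= 0.2  # >75% reduction on the blocked beat
                elif k == 1:
                    a *= 1.15  # increased voltage on the next activation
            ts.append(t)
            aa.append(a)
        truth[j] = ts
        amps[j] = aa

    end_ms = qrs[-1] + rel.max() + 120.0

    chaos: dict[int, list[tuple[float, float]]] = {}
    if spec.kind == "vf_onset":
        chaos_end = end_ms + 400.0
        for j in range(n_sites):
            t = truth[j][-1] + rng.uniform(70.0, 140.0)
            while t < chaos_end - 40.0:
                chaos.setdefault(j, []).append(
                    (t, base_amp[j] * rng.uniform(0.3, 0.7))
                )
                t += rng.uniform(REFRACTORY_MS + 5.0, 150.0)
        end_ms = chaos_end

    n_samples = int(round(end_ms * fs / 1000.0))
    signals = np.zeros((n_sites, n_samples))
    for j in range(n_sites):
        onsets = list(truth[j]) + [c[0] for c in chaos.get(j, [])]
        amplitudes = list(amps[j]) + [c[1] for c in chaos.get(j, [])]
        signals[j] = synthesize_waveform(
            onsets,
            amplitudes,
            fs=fs,
            n_samples=n_samples,
            sigma_ms=sigma_ms,
            purkinje=spec.purkinje if j in pk_channels else None,
        )
        if noise_sd > 0:
            signals[j] += band_limited_noise(
                n_samples, noise_sd, fs, band=noise_band, rng=rng
            )

    kind = {"paced": "pacing", "vf_onset": "vf"}.get(spec.kind, "intracardiac")
    pacing = None
    if spec.kind == "paced":
        pacing = tuple(q - origin_lead_ms - 20.0 for q in qrs)
    session = RecordingSession(
        signals=signals,
        grid=grid,
        channel_map=grid.sites,
        qrs_onsets_ms=tuple(qrs),
        fs=fs,
        pacing_onsets_ms=pacing,
        beat_kinds=tuple(kind for _ in qrs),
    )
    return SyntheticRecording(
        session=session,
        truth_onsets=truth,
        truth_mechanism=spec,
        qrs_onsets_ms=tuple(qrs),
    )


def square_circuit(grid: ElectrodeGrid, corner_needle: int, layer: str = "endo"):
    """Convenience: a closed 4-site circuit on a 2x2 needle square whose
    top-left needle is ``corner_needle`` (row-major rectangular layouts)."""
    import math

    width = int(round(math.sqrt(grid.n_needles)))
    if width * width < grid.n_needles:
        width += 1
    r, c = divmod(corner_needle, width)
    if c + 1 >= width:
        raise InvalidArgumentError("corner needle must not be on the right edge")
    quad = [corner_needle, corner_needle + 1, corner_needle + width + 1, corner_needle + width]
    if max(quad) >= grid.n_needles:
        raise InvalidArgumentError("2x2 square exceeds grid")
    return tuple(Site(n, layer) for n in quad)
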
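"""Site-level ischemia classification from pre- vs post-occlusion
electrograms.

The local electrogram interval is anchored at the max |dV/dt| inside a
window 30 ms before to 80 ms after the surface QRS onset, extended forward
to the isoelectric line and backward to where the local slope falls below
a configurable factor of the tracing's average slope.  Ischemia is at
least a 45% drop in the maximal total (peak positive minus peak negative)
voltage inside that interval; borderline drops are confirmed by a 45%
decrease of the maximum slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import dvdt
from .errors import NoDeflectionError, UndefinedSiteError

SEARCH_WINDOW_MS = (-30.0, 80.0)
DROP_THRESHOLD = 0.45
BORDERLINE_LOW = 0.40
DEFAULT_SLOPE_FACTOR = 0.1
ISO_NOISE_MULT = 3.0


@dataclass
class LocalInterval:
    start_ms: float
    end_ms: float
    anchor_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.anchor_ms < self.end_ms:
            raise ValueError("interval must bracket its anchor")


@dataclass
class IschemiaCall:
    site: object
    v_pre_mv: float
    v_post_mv: float
    drop_frac: float
    dvdt_drop_frac: float | None
    status: str  # ischemic | borderline-confirmed | non-ischemic

    @property
    def is_ischemic(self) -> bool:
        return self.status in ("ischemic", "borderline-confirmed")


def _noise_sd(x: np.ndarray, fs: float, qrs_onset_ms: float) -> float:
    """Baseline noise SD from the diastolic segment preceding the search
    window."""
    hi = int(round((qrs_onset_ms + SEARCH_WINDOW_MS[0]) * fs / 1000.0))
    seg = x[: max(hi, 0)]
    if seg.size < 8:
        seg = x
    return float(np.std(seg - np.median(seg)))


def local_interval(
    x: np.ndarray,
    fs: float,
    qrs_onset_ms: float,
    slope_factor: float = DEFAULT_SLOPE_FACTOR,
) -> LocalInterval:
    """Bracket the local electrogram deflection around its max |dV/dt|."""
    x = np.asarray(x, dtype=float)
    lo = int(round((qrs_onset_ms + SEARCH_WINDOW_MS[0]) * fs / 1000.0))
    hi = int(round((qrs_onset_ms + SEARCH_WINDOW_MS[1]) * fs / 1000.0))
    lo = max(lo, 0)
    hi = min(hi, x.size)
    if hi - lo < 4:
        raise NoDeflectionError("search window outside the record")
    slope = np.abs(dvdt(x, fs))
    noise = _noise_sd(x, fs, qrs_onset_ms)
    iso_band = max(ISO_NOISE_MULT * noise, 1e-9)
    seg = x[lo:hi]
    # noise alone spans ~6-7 SD peak-to-peak over this window; demand a
    # clearly larger excursion before calling it a deflection
    if float(seg.max() - seg.min()) <= 10.0 * max(noise, 1e-9):
        raise NoDeflectionError("no deflection above the isoelectric band")
    anchor = lo + int(np.argmax(slope[lo:hi]))
    baseline = float(np.median(x[:lo])) if lo >= 8 else float(np.median(x))

    # forward to the isoelectric line: the deflection ends where the signal
    # last leaves the isoelectric band before settling (100 ms horizon)
    limit = min(anchor + int(round(0.1 * fs)), x.size)
    beyond = np.nonzero(np.abs(x[anchor:limit] - baseline) >= iso_band)[0]
    end = anchor + (int(beyond[-1]) + 1 if beyond.size else 1)
    end = min(end, x.size - 1)

    # backward to where the local slope drops below factor x average slope
    mean_slope = float(np.mean(slope))
    start = anchor
    while start > 0 and slope[start] >= slope_factor * mean_slope:
        start -= 1
    if start == anchor:
        start = anchor - 1
    return LocalInterval(
        start_ms=start * 1000.0 / fs,
        end_ms=end * 1000.0 / fs,
        anchor_ms=anchor * 1000.0 / fs,
    )


def total_voltage(x: np.ndarray, interval: LocalInterval, fs: float) -> float:
    """Maximum positive minus maximum negative voltage inside the local
    interval."""
    lo = int(round(interval.start_ms * fs / 1000.0))
    hi = int(round(interval.end_ms * fs / 1000.0)) + 1
    seg = np.asarray(x, dtype=float)[lo:hi]
    return float(seg.max() - seg.min())


def max_slope(x: np.ndarray, interval: LocalInterval, fs: float) -> float:
    lo = int(round(interval.start_ms * fs / 1000.0))
    hi = int(round(interval.end_ms * fs / 1000.0)) + 1
    return float(np.max(np.abs(dvdt(np.asarray(x, dtype=float)[lo:hi], fs))))


def classify_ischemia(
    v_pre_mv: float,
    v_post_mv: float,
    dvdt_pre: float | None = None,
    dvdt_post: float | None = None,
    site=None,
    drop_threshold: float = DROP_THRESHOLD,
    borderline_low: float = BORDERLINE_LOW,
) -> IschemiaCall:
    """Apply the voltage-drop rule with optional dV/dt confirmation.

    drop >= 45% -> ischemic; drop in [40%, 45%) with a >= 45% dV/dt drop
    -> borderline-confirmed (counts as ischemic); otherwise non-ischemic.
    """
    if v_pre_mv < 0 or v_post_mv < 0:
        raise UndefinedSiteError("voltages must be >= 0")
    if v_pre_mv == 0:
        raise UndefinedSiteError("pre-occlusion voltage is zero")
    drop = 1.0 - v_post_mv / v_pre_mv
    dvdt_drop = None
    if dvdt_pre is not None and dvdt_post is not None and dvdt_pre > 0:
        dvdt_drop = 1.0 - dvdt_post / dvdt_pre
    eps = 1e-12  # a drop of exactly 45.0% counts as "at least 45%"
    if drop >= drop_threshold - eps:
        status = "ischemic"
    elif (
        borderline_low - eps <= drop < drop_threshold
        and dvdt_drop is not None
        and dvdt_drop >= drop_threshold - eps
    ):
        status = "borderline-confirmed"
    else:
        status = "non-ischemic"
    return IschemiaCall(site, v_pre_mv, v_post_mv, drop, dvdt_drop, status)


def assess_site(
    pre: np.ndarray,
    post: np.ndarray,
    fs: float,
    qrs_pre_ms: float,
    qrs_post_ms: float,
    site=None,
    slope_factor: float = DEFAULT_SLOPE_FACTOR,
) -> IschemiaCall:
    """Full signal-level assessment of one site."""
    iv_pre = local_interval(pre, fs, qrs_pre_ms, slope_factor)
    iv_post = local_interval(post, fs, qrs_post_ms, slope_factor)
    return classify_ischemia(
        total_voltage(pre, iv_pre, fs),
        total_voltage(post, iv_post, fs),
        max_slope(pre, iv_pre, fs),
        max_slope(post, iv_post, fs),
        site=site,
    )
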
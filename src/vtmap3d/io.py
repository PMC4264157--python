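"""Reading and writing recording bundles and tabular results.

A recording bundle is a directory with ``meta.json`` (grid geometry,
sampling metadata, channel table), ``signals.csv`` (channels x samples,
mV; one row per channel) and, for synthetic recordings, ``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import ActivationEvent
from .grid import ElectrodeGrid, Site
from .mapping import ActivationMap, band_label
from .session import RecordingSession
from .simulate import MechanismSpec, SyntheticRecording


def write_bundle(rec: SyntheticRecording | RecordingSession, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = rec.session if isinstance(rec, SyntheticRecording) else rec
    grid = session.grid
    meta = {
        "fs": session.fs,
        "band": list(session.band),
        "qrs_onsets_ms": list(session.qrs_onsets_ms),
        "pacing_onsets_ms": (
            list(session.pacing_onsets_ms) if session.pacing_onsets_ms else None
        ),
        "beat_kinds": list(session.beat_kinds),
        "grid": {
            "positions": grid.positions.tolist(),
            "layers": list(grid.layers),
            "spacing_mm": grid.spacing_mm,
            "layer_depth_mm": grid.layer_depth_mm,
        },
        "channels": [
            {"channel": i, "needle": s.needle, "layer": s.layer}
            for i, s in enumerate(session.channel_map)
        ],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    np.savetxt(out / "signals.csv", session.signals, delimiter=",", fmt="%.6g")
    if isinstance(rec, SyntheticRecording):
        truth = {
            "mechanism": {
                "kind": rec.truth_mechanism.kind,
                "layer": rec.truth_mechanism.layer,
                "cycle_length_ms": rec.truth_mechanism.cycle_length_ms,
            },
            "onsets_ms": {str(ch): ts for ch, ts in rec.truth_onsets.items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out


def read_bundle(in_dir) -> RecordingSession:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    signals = np.loadtxt(src / "signals.csv", delimiter=",", ndmin=2)
    g = meta["grid"]
    grid = ElectrodeGrid(
        positions=np.asarray(g["positions"], dtype=float),
        layers=tuple(g["layers"]),
        spacing_mm=g["spacing_mm"],
        layer_depth_mm=g["layer_depth_mm"],
    )
    channel_map = tuple(
        Site(c["needle"], c["layer"]) for c in meta["channels"]
    )
    return RecordingSession(
        signals=signals,
        grid=grid,
        channel_map=channel_map,
        qrs_onsets_ms=tuple(meta["qrs_onsets_ms"]),
        fs=meta["fs"],
        band=tuple(meta["band"]),
        pacing_onsets_ms=(
            tuple(meta["pacing_onsets_ms"]) if meta.get("pacing_onsets_ms") else None
        ),
        beat_kinds=tuple(meta["beat_kinds"]),
    )


def events_to_frame(
    events: list[ActivationEvent], session: RecordingSession
) -> pd.DataFrame:
    rows = []
    for ev in events:
        site = session.channel_map[ev.channel]
        rows.append(
            {
                "beat": ev.beat,
                "channel": ev.channel,
                "needle": site.needle,
                "layer": site.layer,
                "time_ms": ev.time_ms,
                "mode": ev.mode,
                "good_flag": ev.is_good_channel,
                "amplitude_mv": ev.amplitude_mv,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "beat",
            "channel",
            "needle",
            "layer",
            "time_ms",
            "mode",
            "good_flag",
            "amplitude_mv",
        ],
    )


def map_to_frame(maps: list[ActivationMap]) -> pd.DataFrame:
    rows = []
    for amap in maps:
        n_bands = (max(amap.bands.values()) + 1) if amap.bands else 0
        for site, t in sorted(amap.times.items()):
            band = amap.bands.get(site)
            rows.append(
                {
                    "complex": amap.complex_index,
                    "needle": site.needle,
                    "layer": site.layer,
                    "time_ms": t,
                    "band": band,
                    "band_label": (
                        band_label(band, n_bands) if band is not None else ""
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["complex", "needle", "layer", "time_ms", "band", "band_label"]
    )


def plot_isochrones(amap: ActivationMap, grid: ElectrodeGrid, path) -> None:
    """One panel per layer, sites colored by isochrone band (early yellow,
    intermediate red, late green, pre-early white)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"white": "#ffffff", "yellow": "#ffd700", "red": "#d62728", "green": "#2ca02c"}
    n_bands = (max(amap.bands.values()) + 1) if amap.bands else 1
    layers = grid.layers[::-1]  # epi on top, as conventional
    fig, axes = plt.subplots(len(layers), 1, figsize=(4, 3 * len(layers)))
    if len(layers) == 1:
        axes = [axes]
    for ax, layer in zip(axes, layers):
        for site, t in amap.layer_times(layer).items():
            band = amap.bands.get(site, 0)
            x, y = grid.positions[site.needle]
            ax.scatter(
                x, y, s=220, c=colors[band_label(band, n_bands)],
                edgecolors="k", zorder=2,
            )
            ax.annotate(f"{t:.0f}", (x, y), ha="center", va="center", fontsize=7)
        ax.set_title(layer)
        ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
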
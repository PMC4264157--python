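import numpy as np
import pytest

from vtmap3d import MechanismSpec, make_grid, simulate_episode, square_circuit
from vtmap3d.grid import Site
from vtmap3d.mapping import ActivationMap

#: Needle corners of the default 23-needle layout that admit a 2x2 square.
SQUARE_CORNERS = (0, 1, 2, 3, 5, 6, 7, 8, 10, 11, 12, 13, 15, 16)

SAMPLE_MS = 1000.0 / 3200.0


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(4, 8.0, ("endo", "epi"))


def random_episode_spec(grid, rng, kind=None):
    """Draw a random focal or reentrant episode spec whose activity fits
    the default detection windows."""
    if kind is None:
        kind = rng.choice(["focal", "reentry"])
    if kind == "reentry":
        corner = int(rng.choice(SQUARE_CORNERS))
        layer = str(rng.choice(["endo", "epi"]))
        return MechanismSpec(
            kind="reentry",
            circuit_sites=square_circuit(grid, corner, layer),
            cycle_length_ms=float(rng.uniform(140.0, 152.0)),
            n_complexes=3,
        )
    site = Site(int(rng.integers(0, grid.n_needles)), str(rng.choice(grid.layers)))
    return MechanismSpec(
        kind="focal",
        origin_site=site,
        cycle_length_ms=float(rng.uniform(140.0, 300.0)),
        n_complexes=3,
    )


def truth_of(spec):
    if spec.kind == "reentry":
        return "reentry", spec.circuit_sites[0].layer
    return "focal", spec.origin_site.layer


def detected_maps(rec, events):
    """Group detected events into per-complex ActivationMaps."""
    session = rec.session
    maps = []
    for k in range(session.n_beats):
        times = {
            session.channel_map[e.channel]: e.time_ms for e in events if e.beat == k
        }
        maps.append(ActivationMap(times=times, complex_index=k))
    return maps


def truth_maps(rec):
    maps = []
    for k in range(len(rec.qrs_onsets_ms)):
        rel = rec.truth_relative(k)
        times = {rec.session.channel_map[ch]: t for ch, t in rel.items()}
        maps.append(ActivationMap(times=times, complex_index=k))
    return maps
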
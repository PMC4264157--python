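import numpy as np
import pytest

from vtmap3d import (
    LayerRefractoryConfig,
    MechanismSpec,
    PurkinjeSpec,
    classify_beat_mechanism,
    classify_episode,
    classify_episode_mechanism,
    detect_events,
    detect_purkinje_origin,
    simulate_episode,
    square_circuit,
    synthesize_waveform,
)
from vtmap3d.errors import InvalidArgumentError
from vtmap3d.grid import Site
from vtmap3d.mapping import ActivationMap, band_edges_for, band_of
from vtmap3d.mechanism import find_prepotential

from conftest import detected_maps, random_episode_spec, truth_maps, truth_of

FS = 3200.0


class TestWorkedMaps:
    """Activation maps patterned on the published worked example: one
    episode carrying an endocardial focal complex (earliest -53), an
    endocardial reentrant complex (-69 -> -11 -> 39 -> 60), a second
    endocardial reentry (-38 -> 21 -> 105) and an epicardial focal
    complex."""

    def test_focal_endo_complex(self, grid):
        spec = MechanismSpec(
            kind="focal", origin_site=Site(12, "endo"), cycle_length_ms=220.0,
            n_complexes=2,
        )
        rec = simulate_episode(grid, spec, seed=0, origin_lead_ms=53.0)
        maps = truth_maps(rec)
        assert maps[1].times[Site(12, "endo")] == pytest.approx(-53.0)
        call = classify_beat_mechanism(maps[0], maps[1], grid, 220.0)
        assert (call.kind, call.layer) == ("focal", "endo")

    def test_focal_epi_complex(self, grid):
        spec = MechanismSpec(
            kind="focal", origin_site=Site(6, "epi"), cycle_length_ms=200.0,
            n_complexes=2,
        )
        rec = simulate_episode(grid, spec, seed=0, origin_lead_ms=30.0)
        call = classify_beat_mechanism(*truth_maps(rec)[:2], grid, 200.0)
        assert (call.kind, call.layer) == ("focal", "epi")

    def test_reentry_endo_printed_progression(self, grid):
        spec = MechanismSpec(
            kind="reentry",
            circuit_sites=square_circuit(grid, 6, "endo"),
            circuit_phases_ms=(0.0, 58.0, 108.0, 129.0),
            cycle_length_ms=150.0,
            n_complexes=2,
        )
        rec = simulate_episode(grid, spec, seed=0, origin_lead_ms=69.0)
        maps = truth_maps(rec)
        call = classify_beat_mechanism(maps[0], maps[1], grid, 150.0)
        assert (call.kind, call.layer) == ("reentry", "endo")
        assert call.adjacency_link

    def test_second_reentry_three_site_circuit(self, grid):
        circuit = (Site(6, "endo"), Site(7, "endo"), Site(11, "endo"))
        spec = MechanismSpec(
            kind="reentry",
            circuit_sites=circuit,
            circuit_phases_ms=(0.0, 59.0, 143.0),
            cycle_length_ms=160.0,
            n_complexes=2,
        )
        rec = simulate_episode(grid, spec, seed=0, origin_lead_ms=38.0)
        maps = truth_maps(rec)
        assert maps[1].times[circuit[0]] == pytest.approx(-38.0)
        call = classify_beat_mechanism(maps[0], maps[1], grid, 160.0)
        assert (call.kind, call.layer) == ("reentry", "endo")

    def test_printed_isochrone_band_examples(self):
        edges = band_edges_for([-69.0, 105.0])
        assert band_of(-53.0, edges) == 0  # white
        assert band_of(0.0, edges) == 1  # yellow


class TestGroundTruthRecovery:
    def test_noiseless_recovery_mixed_episodes(self, grid):
        rng = np.random.default_rng(21)
        for i in range(10):
            spec = random_episode_spec(grid, rng)
            rec = simulate_episode(grid, spec, seed=500 + i)
            maps = detected_maps(rec, detect_events(rec.session))
            call, _ = classify_episode_mechanism(maps, grid, spec.cycle_length_ms)
            assert (call.kind, call.layer) == truth_of(spec)

    def test_mutual_exclusivity_per_complex(self, grid):
        rng = np.random.default_rng(3)
        for i in range(4):
            spec = random_episode_spec(grid, rng)
            rec = simulate_episode(grid, spec, seed=700 + i)
            maps = truth_maps(rec)
            _, calls = classify_episode_mechanism(maps, grid, spec.cycle_length_ms)
            for c in calls:
                assert c.kind in ("focal", "reentry", "indeterminate")

    def test_insufficient_sites_indeterminate(self, grid):
        prev = ActivationMap(times={Site(0, "endo"): 10.0})
        cur = ActivationMap(times={Site(20, "endo"): 5.0})
        call = classify_beat_mechanism(prev, cur, grid, 200.0)
        assert call.kind == "indeterminate"

    def test_invalid_cycle_length(self, grid):
        m = ActivationMap(times={Site(0, "endo"): 0.0})
        with pytest.raises(InvalidArgumentError):
            classify_beat_mechanism(m, m, grid, 0.0)


class TestPurkinje:
    @staticmethod
    def _traces(n_spiked, lead=5.0, n_channels=3, onset=100.0):
        pk = PurkinjeSpec(lead_ms=lead) if n_spiked else None
        sig = []
        for ch in range(n_channels):
            sig.append(
                synthesize_waveform(
                    [onset], [8.0], fs=FS, n_samples=800,
                    purkinje=PurkinjeSpec(lead_ms=lead) if ch < n_spiked else None,
                    sigma_ms=5.0,
                )
            )
        onsets = {ch: onset for ch in range(n_channels)}
        return np.stack(sig), onsets

    def test_positive_case(self):
        vt, onsets = self._traces(2)
        pre, _ = self._traces(2)
        post, _ = self._traces(2)
        assert detect_purkinje_origin(vt, onsets, pre, onsets, post, onsets, FS)

    def test_no_prepotential_false(self):
        vt, onsets = self._traces(0)
        ref, _ = self._traces(2)
        assert not detect_purkinje_origin(vt, onsets, ref, onsets, ref, onsets, FS)

    def test_single_channel_insufficient(self):
        vt, onsets = self._traces(1)
        ref, _ = self._traces(2)
        assert not detect_purkinje_origin(vt, onsets, ref, onsets, ref, onsets, FS)

    def test_missing_reference_rejected(self):
        vt, onsets = self._traces(2)
        with pytest.raises(InvalidArgumentError):
            detect_purkinje_origin(vt, onsets, None, onsets, vt, onsets, FS)

    def test_lead_outside_band_rejected(self):
        # spike 15 ms ahead of the muscle deflection: outside 1-11 ms
        x = synthesize_waveform([100.0], [8.0], fs=FS, n_samples=800, sigma_ms=5.0)
        t = np.arange(x.size) / FS * 1000.0
        x = x + 0.5 * np.exp(-0.5 * ((t - 85.0) / 0.64) ** 2)
        assert find_prepotential(x, 100.0, FS) is None

    def test_monotone_in_prepotential_presence(self):
        # removing the spike from a positive case always yields False
        vt, onsets = self._traces(2)
        bare, _ = self._traces(0)
        ref, _ = self._traces(2)
        assert detect_purkinje_origin(vt, onsets, ref, onsets, ref, onsets, FS)
        assert not detect_purkinje_origin(bare, onsets, ref, onsets, ref, onsets, FS)


class TestEpisodeTyping:
    def test_sustained_by_pace_termination(self):
        times = np.arange(0, 12_000.0, 250.0)
        call = classify_episode(times, terminated_by="pacing")
        assert call.type == "sustained_VT"

    def test_sustained_by_duration(self):
        times = np.arange(0, 10_500.0, 300.0)
        call = classify_episode(times, terminated_by="spontaneous")
        assert call.type == "sustained_VT"
        assert call.duration_s >= 10.0

    def test_nonsustained(self):
        call = classify_episode([0.0, 300.0, 600.0], terminated_by="spontaneous")
        assert call.type == "nonsustained_VT"
        assert call.n_complexes == 3

    def test_two_complexes_not_an_episode(self):
        assert classify_episode([0.0, 400.0]).type == "not_an_episode"

    def test_vf_requires_both_flags(self):
        times = np.arange(0, 3000.0, 120.0)
        vf = classify_episode(times, "shock", qrs_variability=True, pressure_collapse=True)
        assert vf.type == "VF"
        assert vf.analyzed_prefix == (0, min(len(times), 40))
        not_vf = classify_episode(times, "shock", qrs_variability=True)
        assert not_vf.type == "sustained_VT"

    def test_totality(self):
        rng = np.random.default_rng(0)
        kinds = set()
        for _ in range(50):
            n = int(rng.integers(1, 45))
            times = np.cumsum(rng.uniform(100.0, 600.0, size=n))
            call = classify_episode(
                times,
                terminated_by=str(rng.choice(["spontaneous", "pacing", "shock", "none"])),
                qrs_variability=bool(rng.integers(2)),
                pressure_collapse=bool(rng.integers(2)),
            )
            kinds.add(call.type)
        assert kinds <= {"sustained_VT", "nonsustained_VT", "VF", "not_an_episode"}

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_episode([])

    def test_refractory_config_validation(self):
        with pytest.raises(InvalidArgumentError):
            LayerRefractoryConfig(epi_ms=0.0)
        assert LayerRefractoryConfig().for_layer("epi") == 80.0
        assert LayerRefractoryConfig().for_layer("endo") == 100.0
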
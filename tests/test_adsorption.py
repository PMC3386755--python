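"""RSA monolayer formation and SEM-like coated-tube measurements."""

import numpy as np
import pytest

from nanocyp import (
    AdsorbedProtein,
    AdsorptionState,
    Nanotube,
    ProteinPrism,
    SurfaceRect,
    layer_thickness_stats,
    make_orientation_set,
    projected_diameter_profile,
    rects_overlap,
    run_rsa,
    simulate_ensemble,
)
from nanocyp.adsorption import EnsembleConfig
from nanocyp.errors import EmptyStateError, InvalidParameterError


def assert_no_overlap(state):
    """O(n^2) oracle replay of the no-overlap invariant."""
    period = state.tube.circumference
    prots = state.proteins
    for i in range(len(prots)):
        for j in range(i + 1, len(prots)):
            assert not rects_overlap(prots[i].footprint, prots[j].footprint, period)


def lateral_only(protein, tube):
    ors = make_orientation_set(protein, tube)
    return [o for o in ors if o.mode_id == "lateral"]


class TestRunRsa:
    def test_tube_with_room_for_one_footprint(self, protein):
        # 6 nm long, 2 nm diameter: a second lateral footprint fits neither
        # axially (2 x 5.75 > 6) nor azimuthally (2 x 4.75 > pi x 2)
        tube = Nanotube(2.0, 6.0)
        state = run_rsa(tube, protein, lateral_only(protein, tube), seed=0,
                        stop_after_failures=200)
        assert len(state.proteins) <= 1

    def test_identical_seed_identical_state(self, protein):
        tube = Nanotube(10.0, 80.0)
        s1 = run_rsa(tube, protein, seed=7, stop_after_failures=500)
        s2 = run_rsa(tube, protein, seed=7, stop_after_failures=500)
        assert s1.proteins == s2.proteins
        assert s1.consecutive_failures == s2.consecutive_failures

    def test_no_overlap_invariant(self, protein):
        tube = Nanotube(10.0, 100.0)
        state = run_rsa(tube, protein, lateral_only(protein, tube), seed=1,
                        stop_after_failures=5000)
        assert len(state.proteins) > 10
        assert_no_overlap(state)
        assert 0.0 < state.coverage_fraction < 1.0

    def test_jittered_dimensions_no_overlap(self):
        tube = Nanotube(10.0, 100.0)
        state = run_rsa(tube, seed=3, stop_after_failures=2000,
                        dimension_ranges=((4.5, 5.0), (5.0, 6.5), (3.5, 4.5)))
        assert_no_overlap(state)
        modes = {p.orientation_id for p in state.proteins}
        assert "lateral" in modes  # dominant mode must appear

    def test_aligned_square_jamming_coverage(self):
        # lateral-only square footprints: RSA jamming coverage of aligned
        # squares is ~0.56 on the infinite plane; allow edge effects
        p = ProteinPrism(5.0, 5.0, 4.0)
        tube = Nanotube(10.0, 150.0)
        state = run_rsa(tube, p, lateral_only(p, tube), seed=11,
                        stop_after_failures=5000)
        assert 0.4 <= state.coverage_fraction <= 0.6

    def test_footprint_larger_than_tube_rejected(self, protein):
        tube = Nanotube(10.0, 3.0)  # shorter than any footprint
        with pytest.raises(InvalidParameterError):
            run_rsa(tube, protein, seed=0, stop_after_failures=10)

    def test_footprints_inside_tube(self, protein):
        tube = Nanotube(10.0, 60.0)
        state = run_rsa(tube, protein, seed=2, stop_after_failures=1000)
        for p in state.proteins:
            assert p.footprint.z_min >= 0.0
            assert p.footprint.z_max <= tube.length


def manual_state(extents, tube=None, sides=None):
    tube = tube or Nanotube(10.0, 50.0)
    period = tube.circumference
    sides = sides or [0.25] * len(extents)  # arc fraction -> top half by default
    prots = []
    for k, (ext, frac) in enumerate(zip(extents, sides)):
        s = frac * period
        z = 10.0 + 6.0 * k
        prots.append(
            AdsorbedProtein(z, s, "lateral", ext,
                            SurfaceRect(z - 2.5, z + 2.5, s - 2.0, s + 2.0))
        )
    return AdsorptionState(tube=tube, proteins=prots)


class TestMeasurements:
    def test_thickness_of_uniform_layer(self):
        state = manual_state([4.5, 4.5, 4.5])
        mean, sd = layer_thickness_stats(state)
        assert mean == pytest.approx(4.5)
        assert sd == 0.0

    def test_thickness_mean_of_two(self):
        mean, _ = layer_thickness_stats(manual_state([4.0, 6.0]))
        assert mean == pytest.approx(5.0)

    def test_thickness_empty_state_rejected(self, tube):
        with pytest.raises(EmptyStateError):
            layer_thickness_stats(AdsorptionState(tube=tube))

    def test_bare_tube_profile(self, tube):
        d = projected_diameter_profile(AdsorptionState(tube=tube), 10)
        assert np.all(d == tube.diameter)

    def test_single_sided_protein_adds_its_extent(self):
        state = manual_state([4.0])  # one protein on the top half at z=10
        d = projected_diameter_profile(state, 500)
        z = (np.arange(500) + 0.5) * state.tube.length / 500
        covered = (z >= 7.5) & (z <= 12.5)
        assert np.all(d[covered] == pytest.approx(14.0))
        assert np.all(d[~covered] == pytest.approx(10.0))

    def test_both_sides_add(self):
        state = manual_state([4.0, 5.0], sides=[0.25, 0.75])
        # overlap the two axially
        state.proteins[1] = AdsorbedProtein(
            10.0, state.proteins[1].s, "lateral", 5.0,
            SurfaceRect(7.5, 12.5, state.proteins[1].s - 2, state.proteins[1].s + 2),
        )
        d = projected_diameter_profile(state, 100)
        assert d.max() == pytest.approx(19.0)


class TestEnsemble:
    def test_mean_diameter_monotone_in_protein_thickness(self):
        means = []
        for t in (3.5, 4.0, 4.5):
            p = ProteinPrism(4.75, 5.75, t)
            tube = Nanotube(10.0, 120.0)
            state = run_rsa(tube, p, lateral_only(p, tube), seed=21,
                            stop_after_failures=3000)
            means.append(projected_diameter_profile(state, 100).mean())
        assert means[0] <= means[1] <= means[2]

    def test_small_ensemble_statistics(self):
        cfg = EnsembleConfig(tube_length=120.0, stop_after_failures=3000)
        stats = simulate_ensemble(n_tubes=4, config=cfg, seed=5)
        assert stats.n_tubes == 4
        assert stats.mean_diameter >= 10.0
        assert 0.0 < stats.coverage_fraction < 1.0
        assert 3.0 <= stats.mean_thickness <= 6.0

    def test_shrinking_protein_approaches_bare_diameter(self):
        small = EnsembleConfig(
            tube_length=15.0,
            dimension_ranges=((1.0, 1.0), (1.0, 1.0), (1.0, 1.0)),
            stop_after_failures=2000,
        )
        stats_small = simulate_ensemble(n_tubes=1, config=small, seed=9)
        default = simulate_ensemble(
            n_tubes=1, config=EnsembleConfig(tube_length=60.0,
                                             stop_after_failures=2000), seed=9
        )
        assert 10.0 < stats_small.mean_diameter <= 12.0
        assert stats_small.mean_diameter < default.mean_diameter

    def test_seed_stability_of_mean_diameter(self):
        cfg = EnsembleConfig(tube_length=150.0, stop_after_failures=4000)
        a = simulate_ensemble(n_tubes=8, config=cfg, seed=100)
        b = simulate_ensemble(n_tubes=8, config=cfg, seed=900)
        assert abs(a.mean_diameter - b.mean_diameter) < 1.0
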
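"""Actin measurements: lattice geometry, repeats, crosslinks, branches."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from gcmorph.core import GcMorphError, InsufficientDataError, ValidationError
from gcmorph import actin
from gcmorph.actin import CrossSection
from gcmorph.synth import (
    DEFAULT_NOISE_SD,
    BundleSpec,
    MissingWedge,
    ScenePlan,
    make_branch,
    make_filament,
    render_scene,
)

from helpers import hex_points, render_one_filament, render_pair_bundle

A = 12.1


class TestInterfilamentDistances:
    def test_ideal_lattice_means(self):
        cs = CrossSection(hex_points(5, 3, A))
        short, long_ = actin.interfilament_distances(cs)
        assert np.mean(short) == pytest.approx(12.1, abs=0.01)
        assert np.mean(long_) == pytest.approx(20.96, abs=0.01)

    def test_two_points(self):
        short, long_ = actin.interfilament_distances(CrossSection([[0, 0], [10, 0]]))
        assert short == [pytest.approx(10.0)]
        assert long_ == []

    def test_single_point_and_coincident(self):
        assert actin.interfilament_distances(CrossSection([[1, 2]])) == ([], [])
        with pytest.raises(ValidationError):
            actin.interfilament_distances(CrossSection([[0, 0], [0, 0], [5, 5]]))

    def test_jittered_lattice_against_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pts = hex_points(5, 3, A, jitter=1.2, rng=rng)
        short, long_ = actin.interfilament_distances(CrossSection(pts))
        # oracle: exhaustive pair enumeration with the same shell windows
        d = pdist(pts)
        a_hat = np.median(np.sort(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=2) +
            np.eye(len(pts)) * 1e9, axis=1)[:, 0])
        oracle_short = d[d < 1.3 * a_hat]
        oracle_long = d[(d >= 1.50 * a_hat) & (d <= 1.95 * a_hat)]
        assert np.allclose(sorted(short), sorted(oracle_short))
        assert np.allclose(sorted(long_), sorted(oracle_long))
        # means within 3 s.e.m. of the generator truth
        assert np.mean(short) == pytest.approx(
            12.1, abs=3 * np.std(short) / math.sqrt(len(short)) + 3 * 1.2 / math.sqrt(len(short)))
        assert np.mean(long_) == pytest.approx(
            20.96, abs=3 * np.std(long_) / math.sqrt(len(long_)) + 3 * 1.2 / math.sqrt(len(long_)))


class TestHexagonalOrder:
    def test_perfect_lattice_scores_high(self):
        score, flag = actin.hexagonal_order(CrossSection(hex_points(5, 4, A)))
        assert score > 0.95 and flag

    def test_random_points_score_low(self):
        # simulation oracle: uniform random points are never called hexagonal
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cs = CrossSection(rng.uniform(0, 60, (50, 2)))
            score, flag = actin.hexagonal_order(cs)
            scores.append(score)
            assert not flag
        assert np.mean(scores) < 0.5

    def test_square_lattice_rejected(self):
        xy = np.array([(x, y) for x in range(5) for y in range(4)], float) * A
        score, flag = actin.hexagonal_order(CrossSection(xy))
        assert not flag

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            actin.hexagonal_order(CrossSection(hex_points(3, 2, A)))


class TestBundleDimensions:
    def test_ideal_12_by_6(self):
        assert actin.bundle_dimensions(CrossSection(hex_points(12, 6, A))) == (12, 6)

    def test_single_row(self):
        assert actin.bundle_dimensions(CrossSection(hex_points(5, 1, A))) == (5, 1)

    def test_jittered_8_by_4(self):
        rng = np.random.default_rng(1)
        pts = hex_points(8, 4, A, jitter=1.0, rng=rng)
        assert actin.bundle_dimensions(CrossSection(pts)) == (8, 4)

    def test_non_lattice_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValidationError):
            actin.bundle_dimensions(CrossSection(rng.uniform(0, 60, (30, 2))))


class TestHalfRepeat:
    @pytest.mark.parametrize("cls,true", [("long", 37.106), ("short", 27.303)])
    def test_recovery_with_wedge_and_noise(self, cls, true):
        vol, f = render_one_filament(cls, seed=4)
        s, profs = actin.crossover_profiles(vol, f.centerline)
        m = actin.half_repeat(s, profs, "f")
        assert m.half_repeat == pytest.approx(true, abs=0.8)
        assert m.repeat_class == cls

    def test_orientation_invariance(self):
        vol, f = render_one_filament("long", seed=5)
        s, p_fwd = actin.crossover_profiles(vol, f.centerline)
        s, p_rev = actin.crossover_profiles(vol, f.centerline.reversed())
        fwd = actin.half_repeat(s, p_fwd, "f").half_repeat
        rev = actin.half_repeat(s, p_rev, "r").half_repeat
        assert fwd == pytest.approx(rev, abs=0.3)

    def test_constant_profile_unclassified(self):
        s = np.arange(0, 200.0)
        m = actin.half_repeat(s, np.full((4, len(s)), 0.7), "flat")
        assert m.repeat_class == "unclassified"
        assert not np.isfinite(m.half_repeat)

    def test_short_trace_and_coarse_sampling_rejected(self):
        with pytest.raises(InsufficientDataError):
            actin.half_repeat(np.arange(0, 50.0), np.zeros(50), "x")
        with pytest.raises(ValidationError):
            actin.half_repeat(np.arange(0, 300.0, 3.0), np.zeros(100), "x")


class TestRepeatPopulation:
    def test_mixed_population_two_classes_no_intermediates(self):
        ms = []
        for seed in range(3):
            for cls in ("long", "short"):
                vol, f = render_one_filament(cls, seed=seed)
                s, profs = actin.crossover_profiles(vol, f.centerline)
                ms.append(actin.half_repeat(s, profs, f"{cls}{seed}"))
        pop = actin.classify_repeat_population(ms)
        assert pop.n_long == 3 and pop.n_short == 3 and pop.n_intermediate == 0
        assert pop.long_mean == pytest.approx(37.1, abs=1.0)
        assert pop.short_mean == pytest.approx(27.3, abs=1.0)

    def test_single_class_leaves_other_empty(self):
        ms = [actin.RepeatMeasurement("a", 37.0, "long", 5)]
        pop = actin.classify_repeat_population(ms)
        assert pop.n_short == 0 and np.isnan(pop.short_mean)

    def test_class_transition_detected_in_windows(self):
        # one filament switching repeat class mid-length: windowed analysis
        # classifies the two halves separately
        long_f = make_filament((20, 20, 20), (1, 0, 0), 220, "long")
        short_f = make_filament((240, 20, 20), (1, 0, 0), 220, "short")
        plan = ScenePlan(shape=(500, 40, 40), voxel_size=1.0,
                         filaments=[long_f, short_f],
                         wedge=MissingWedge(), noise_sd=DEFAULT_NOISE_SD, seed=9)
        vol, _ = render_scene(plan)
        from gcmorph.core import Centerline

        whole = Centerline([[20, 20, 20], [460, 20, 20]], "transition")
        s, profs = actin.crossover_profiles(vol, whole)
        windows = actin.half_repeat_windowed(s, profs, "t", window=180.0, step=220.0)
        classes = [w.repeat_class for w in windows]
        assert classes[0] == "long" and classes[-1] == "short"


class TestCrosslinkSpacing:
    def test_default_bundle_period_recovered(self):
        vol, b = render_pair_bundle(seed=1)
        sp = actin.crosslink_spacing(vol, b.filaments[0].centerline,
                                     b.filaments[1].centerline)
        assert np.mean(sp) == pytest.approx(37.1, abs=1.0)

    def test_no_crosslinks_gives_empty_list(self):
        from helpers import WEDGE

        fils = [make_filament((20, 28.95, 35), (1, 0, 0), 400, "long", label="a"),
                make_filament((20, 41.05, 35), (1, 0, 0), 400, "long", label="b")]
        b = BundleSpec(fils, crosslink_pairs="none")
        plan = ScenePlan(shape=(440, 70, 70), voxel_size=1.0, bundles=[b],
                         wedge=WEDGE, noise_sd=DEFAULT_NOISE_SD, seed=0)
        vol, _ = render_scene(plan)
        assert actin.crosslink_spacing(vol, fils[0].centerline, fils[1].centerline) == []

    def test_every_other_occupancy_doubles_spacing(self):
        vol, b = render_pair_bundle(seed=0, period=74.2)
        sp = actin.crosslink_spacing(vol, b.filaments[0].centerline,
                                     b.filaments[1].centerline)
        assert np.mean(sp) == pytest.approx(74.2, abs=2.0)

    def test_distant_filaments_rejected(self):
        vol, b = render_pair_bundle(seed=0)
        far = make_filament((20, 15, 60), (1, 0, 0), 400, "long")
        with pytest.raises(ValidationError):
            actin.crosslink_spacing(vol, b.filaments[0].centerline, far.centerline)

    def test_rotation_invariance_of_mean_spacing(self):
        # same bundle laid out along a rotated in-plane direction
        d = np.array([math.cos(math.radians(30)), math.sin(math.radians(30)), 0.0])
        from gcmorph.synth import make_bundle

        b = make_bundle((30, 30, 45), d, 400, n_wide=2, n_high=1)
        plan = ScenePlan(shape=(440, 290, 90), voxel_size=1.0, bundles=[b],
                         wedge=MissingWedge(), noise_sd=DEFAULT_NOISE_SD, seed=1)
        vol, _ = render_scene(plan)
        sp = actin.crosslink_spacing(vol, b.filaments[0].centerline,
                                     b.filaments[1].centerline)
        assert np.mean(sp) == pytest.approx(37.1, rel=0.02)


class TestSubunitOffset:
    @pytest.mark.parametrize("true_offset", [0, 1, 2])
    def test_integer_offsets_recovered(self, true_offset):
        f1 = make_filament((20, 20, 20), (1, 0, 0), 300, "long", phase_offset=0)
        f2 = make_filament((20, 32, 20), (1, 0, 0), 300, "long",
                           phase_offset=true_offset, label="f2")
        plan = ScenePlan(shape=(340, 52, 40), voxel_size=1.0, filaments=[f1, f2],
                         wedge=MissingWedge(), noise_sd=DEFAULT_NOISE_SD,
                         seed=7 + true_offset)
        vol, _ = render_scene(plan)
        off, res = actin.subunit_offset(vol, f1.centerline, f2.centerline)
        assert off == true_offset
        assert abs(res) <= 2.75

    def test_flat_profile_unmeasurable(self):
        from gcmorph.core import Volume3D, Centerline

        v = Volume3D(np.zeros((100, 40, 40), dtype=np.float32), 1.0)
        a = Centerline([[10, 20, 20], [90, 20, 20]], "a")
        b = Centerline([[10, 28, 20], [90, 28, 20]], "b")
        with pytest.raises(ValidationError):
            actin.subunit_offset(v, a, b)


class TestBranchAngle:
    def test_seventy_degree_junction(self):
        par = make_filament((20, 50, 30), (1, 0, 0), 300, "long", label="par")
        br = make_branch(par, 150.0, 120.0, branch_angle=70.1)
        ang = actin.branch_angle(par.centerline, br.child.centerline, [170, 50, 30])
        assert ang == pytest.approx(70.1, abs=0.5)

    def test_collinear_and_perpendicular(self):
        par = make_filament((0, 0, 0), (1, 0, 0), 200, "long")
        straight = make_filament((100, 0, 0), (1, 0, 0), 100, "long")
        perp = make_filament((100, 0, 0), (0, 1, 0), 100, "long")
        j = [100, 0, 0]
        assert actin.branch_angle(par.centerline, straight.centerline, j) == \
            pytest.approx(0.0, abs=1e-6)
        assert actin.branch_angle(par.centerline, perp.centerline, j) == \
            pytest.approx(90.0, abs=1e-6)

    def test_symmetric_in_arguments(self):
        par = make_filament((20, 50, 30), (1, 0, 0), 300, "long")
        br = make_branch(par, 150.0, 120.0, branch_angle=70.1)
        j = [170, 50, 30]
        a1 = actin.branch_angle(par.centerline, br.child.centerline, j)
        a2 = actin.branch_angle(br.child.centerline, par.centerline, j)
        assert a1 == pytest.approx(a2, abs=0.5)

    def test_far_junction_rejected(self):
        par = make_filament((0, 0, 0), (1, 0, 0), 200, "long")
        child = make_filament((100, 0, 0), (0, 1, 0), 100, "long")
        with pytest.raises(ValidationError):
            actin.branch_angle(par.centerline, child.centerline, [100, 50, 0])
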
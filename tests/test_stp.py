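"""Spatial tuning patterns: grid structure, source merging priority,
mirroring, per-direction normalization and directional interpolation."""

import numpy as np
import pytest

from omnineck.stp import (
    CoverageGapError,
    DegenerateDirectionError,
    MuscleGroup,
    MuscleRegistry,
    SourceRecord,
    SpatialTuningPattern,
    StpDirection,
    StpSet,
    build_direction_grid,
    combine_sources,
    default_registry,
    direction_from_axis,
    lookup_weights,
    mirror_right_to_left,
    normalize_per_direction,
    read_source_csv,
    read_stp_csv,
    write_source_csv,
    write_stp_csv,
)


class TestDirectionGrid:
    def test_has_26_entries(self):
        assert len(build_direction_grid()) == 26

    def test_eight_pure_bend_directions(self):
        grid = build_direction_grid()
        none_level = [d for d in grid if d.axial_level == "none" and not d.pure_axial]
        assert len(none_level) == 8

    def test_two_pure_axial_entries(self):
        grid = build_direction_grid()
        pure = [d for d in grid if d.pure_axial]
        assert len(pure) == 2
        assert {d.axial_level for d in pure} == {"left", "right"}

    def test_deterministic_ordering(self):
        assert build_direction_grid() == build_direction_grid()
        assert build_direction_grid()[-2:] == [
            StpDirection(None, "left", True),
            StpDirection(None, "right", True),
        ]

    def test_pure_axial_requires_signed_level(self):
        with pytest.raises(ValueError):
            StpDirection(None, "none", True)


class TestRegistry:
    def test_default_has_eleven_groups(self, registry):
        assert len(registry) == 11

    def test_substitutes_resolve(self, registry):
        for name in registry.names:
            chain = registry.substitute_chain(name)
            assert all(sub in registry.names for sub in chain)

    def test_cycle_detection(self):
        a = MuscleGroup("a", "b", 1.0, 0.0, 0, (0, 0, 0), (0, 0, 0))
        b = MuscleGroup("b", "a", 1.0, 0.0, 0, (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError, match="cycle"):
            MuscleRegistry([a, b])


def _record(muscle, direction, activity, exp="e1", condition="dynamic", norm="MVIC"):
    return SourceRecord(exp, condition, norm, muscle, "right", direction, activity)


class TestCombineSources:
    def test_dynamic_mvic_preferred_over_isometric(self, registry):
        grid = build_direction_grid()
        records = []
        for name in registry.names:
            for d in grid:
                records.append(_record(name, d, 0.3, "iso", "isometric", "peak"))
                records.append(_record(name, d, 0.7, "dyn", "dynamic", "MVIC"))
        merged = combine_sources(records, registry)
        stp = merged[registry.names[0]]
        assert all(np.isclose(w, 0.7) for w in stp.weights.values())
        assert all(p.startswith("dyn") for p in stp.provenance.values())

    def test_substitute_fills_missing_group(self, registry):
        grid = build_direction_grid()
        records = []
        for name in registry.names:
            if name == "trapezius":  # has semispinalis_capitis as substitute
                continue
            for d in grid:
                records.append(_record(name, d, 0.5))
        merged = combine_sources(records, registry)
        trap = merged["trapezius"]
        assert all(p.startswith("substituted:") for p in trap.provenance.values())
        assert all(np.isclose(w, 0.5) for w in trap.weights.values())

    def test_single_source_identity(self, registry):
        grid = build_direction_grid()
        rng = np.random.default_rng(0)
        values = {d: float(rng.uniform(0.1, 1.0)) for d in grid}
        records = [
            _record(name, d, values[d]) for name in registry.names for d in grid
        ]
        merged = combine_sources(records, registry)
        for stp in merged.values():
            assert all(np.isclose(stp.weights[d], values[d]) for d in grid)

    def test_coverage_gap_reported_with_holes(self, registry):
        grid = build_direction_grid()
        records = [
            _record(name, d, 0.5)
            for name in registry.names
            for d in grid
            if not d.pure_axial  # nobody covers the pure-axial entries
        ]
        with pytest.raises(CoverageGapError) as err:
            combine_sources(records, registry)
        assert len(err.value.holes) == 2 * len(registry.names)


class TestMirroring:
    def test_direction_mirror_is_involution(self):
        for d in build_direction_grid():
            assert d.mirrored().mirrored() == d

    def test_right_lateral_bend_maps_to_left(self):
        # azimuth +90 deg (right lateral bend) reflects to 270 deg
        d = StpDirection(2, "none")
        assert d.mirrored() == StpDirection(6, "none")

    def test_flexion_right_axial_maps_to_flexion_left_axial(self):
        d = StpDirection(0, "right")
        assert d.mirrored() == StpDirection(0, "left")

    def test_mirror_weights_relocated(self):
        grid = build_direction_grid()
        weights = {d: 0.1 for d in grid}
        weights[StpDirection(2, "none")] = 0.9
        stp = SpatialTuningPattern("scm", "right", weights)
        left = mirror_right_to_left(stp)
        assert left.side == "left"
        assert left.weights[StpDirection(6, "none")] == 0.9

    def test_rejects_left_side_input(self):
        stp = SpatialTuningPattern(
            "scm", "left", {d: 0.5 for d in build_direction_grid()}
        )
        with pytest.raises(ValueError):
            mirror_right_to_left(stp)


def _uniform_set(value=0.5) -> StpSet:
    grid = build_direction_grid()
    right = {
        name: SpatialTuningPattern(name, "right", {d: value for d in grid})
        for name in ("a", "b")
    }
    return StpSet.from_right_patterns(right)


class TestNormalization:
    def test_two_group_arithmetic(self):
        grid = build_direction_grid()
        right = {
            "a": SpatialTuningPattern("a", "right", {d: 0.2 for d in grid}),
            "b": SpatialTuningPattern("b", "right", {d: 0.4 for d in grid}),
        }
        out = normalize_per_direction(StpSet.from_right_patterns(right))
        assert all(np.isclose(w, 0.5) for w in out.patterns[("a", "right")].weights.values())
        assert all(np.isclose(w, 1.0) for w in out.patterns[("b", "right")].weights.values())

    def test_idempotent(self, stps):
        again = normalize_per_direction(stps)
        _, _, w1 = stps.weight_matrix()
        _, _, w2 = again.weight_matrix()
        assert np.allclose(w1, w2)

    def test_max_is_one_at_every_direction(self, stps):
        _, _, w = stps.weight_matrix()
        assert np.allclose(w.max(axis=0), 1.0)
        assert w.min() >= 0.0 and w.max() <= 1.0 + 1e-12

    def test_scale_invariance(self, source_records, registry):
        right = combine_sources(source_records, registry)
        scaled = {
            name: SpatialTuningPattern(
                name, "right", {d: 3.7 * w for d, w in stp.weights.items()}
            )
            for name, stp in right.items()
        }
        a = normalize_per_direction(StpSet.from_right_patterns(right))
        b = normalize_per_direction(StpSet.from_right_patterns(scaled))
        _, _, wa = a.weight_matrix()
        _, _, wb = b.weight_matrix()
        assert np.allclose(wa, wb)

    def test_commutes_with_mirroring(self, stps):
        # the left pattern of the normalized set equals the mirror of the
        # normalized right pattern
        for (group, side), pattern in stps.patterns.items():
            if side != "right":
                continue
            mirrored = mirror_right_to_left(pattern)
            left = stps.patterns[(group, "left")]
            for d in build_direction_grid():
                assert np.isclose(mirrored.weights[d], left.weights[d])

    def test_all_zero_direction_rejected(self):
        grid = build_direction_grid()
        weights = {d: 0.5 for d in grid}
        # zero a direction and its mirror so neither side covers it
        weights[StpDirection(1, "left")] = 0.0
        weights[StpDirection(1, "left").mirrored()] = 0.0
        right = {"a": SpatialTuningPattern("a", "right", weights)}
        with pytest.raises(DegenerateDirectionError):
            normalize_per_direction(StpSet.from_right_patterns(right))


class TestLookup:
    def test_grid_point_identity(self, stps):
        d = StpDirection(3, "none")
        channels, w = lookup_weights(stps, d.bend_azimuth, 0.0)
        for i, c in enumerate(channels):
            assert np.isclose(w[i], stps.patterns[c].weights[d])

    def test_midpoint_is_arithmetic_mean(self, stps):
        az = (StpDirection(1, "none").bend_azimuth + StpDirection(2, "none").bend_azimuth) / 2
        channels, w = lookup_weights(stps, az, 0.0)
        for i, c in enumerate(channels):
            expected = 0.5 * (
                stps.patterns[c].weights[StpDirection(1, "none")]
                + stps.patterns[c].weights[StpDirection(2, "none")]
            )
            assert np.isclose(w[i], expected)

    def test_zero_axial_uses_none_level_only(self, stps):
        d = StpDirection(5, "none")
        _, w = lookup_weights(stps, d.bend_azimuth, 0.0)
        _, w_signed = lookup_weights(stps, d.bend_azimuth, 0.5)  # at the knot
        channels = stps.channels
        for i, c in enumerate(channels):
            assert np.isclose(w[i], stps.patterns[c].weights[d])
            assert np.isclose(
                w_signed[i], stps.patterns[c].weights[StpDirection(5, "right")]
            )

    def test_pure_axial_limit(self, stps):
        _, w = lookup_weights(stps, 0.3, -1.0)
        for i, c in enumerate(stps.channels):
            assert np.isclose(
                w[i], stps.patterns[c].weights[StpDirection(None, "left", True)]
            )

    def test_periodic_continuity_in_azimuth(self, stps):
        eps = 1e-6
        _, w_lo = lookup_weights(stps, -eps, 0.2)
        _, w_hi = lookup_weights(stps, eps, 0.2)
        assert np.allclose(w_lo, w_hi, atol=1e-4)

    def test_continuity_across_axial_knot(self, stps):
        eps = 1e-7
        _, w_lo = lookup_weights(stps, 1.0, 0.5 - eps)
        _, w_hi = lookup_weights(stps, 1.0, 0.5 + eps)
        assert np.allclose(w_lo, w_hi, atol=1e-5)

    def test_outputs_bounded(self, stps, rng):
        for _ in range(200):
            _, w = lookup_weights(
                stps, rng.uniform(-10, 10), rng.uniform(-1, 1)
            )
            assert np.all(w >= 0.0) and np.all(w <= 1.0 + 1e-12)

    def test_nonfinite_query_rejected(self, stps):
        with pytest.raises(ValueError):
            lookup_weights(stps, np.nan, 0.0)


class TestAxisMapping:
    def test_flexion_axis_maps_to_zero_azimuth(self):
        az, ax = direction_from_axis(np.array([0.0, -1.0, 0.0]))
        assert np.isclose(az, 0.0) and np.isclose(ax, 0.0)

    def test_right_lateral_bend_axis(self):
        az, ax = direction_from_axis(np.array([1.0, 0.0, 0.0]))
        assert np.isclose(az, np.pi / 2)

    def test_pure_axial_axis(self):
        az, ax = direction_from_axis(np.array([0.0, 0.0, 1.0]))
        assert ax == 1.0


class TestSerialization:
    def test_source_csv_round_trip(self, source_records, tmp_path):
        path = tmp_path / "sources.csv"
        write_source_csv(source_records, path)
        back = read_source_csv(path)
        assert len(back) == len(source_records)
        assert set(back) == set(source_records) or all(
            np.isclose(a.activity, b.activity) and a.direction == b.direction
            for a, b in zip(back, source_records)
        )

    def test_stp_csv_round_trip(self, stps, tmp_path):
        path = tmp_path / "stp.csv"
        write_stp_csv(stps, path)
        back = read_stp_csv(path)
        assert set(back.patterns) == set(stps.patterns)
        for key, pattern in stps.patterns.items():
            for d, w in pattern.weights.items():
                assert np.isclose(back.patterns[key].weights[d], w)
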
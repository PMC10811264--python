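"""Spatial tuning patterns: direction grid, source merging, mirroring,
per-direction normalization and directional lookup.

A spatial tuning pattern (STP) maps a movement direction to the normalized
activity of one neck muscle group, and is the mechanism that turns the
controller's single common drive into intermuscular load sharing.  The grid
has 26 directions: eight flexion/extension and lateral-bending combinations
(45 degree azimuth spacing) at three axial-rotation levels (left, none,
right) plus two pure axial rotations.

Azimuth convention (see :mod:`omnineck.kinematics` for the frame): azimuth 0
is the flexion direction (head deviated forward), +90 degrees is right
lateral bending, 180 degrees extension.  All STPs describe the activity of
muscles *returning* the head from the named deviation direction, so a
forward head deviation queries azimuth 0 and loads the extensors.

Mapping of the rotational controller's rotation axis ``v`` onto the grid:

======================  =============================
quantity                expression
======================  =============================
bend azimuth            ``atan2(v_x, -v_y)``
axial component         ``v_z`` (+ = right axial)
======================  =============================

(a pure flexion deviation has axis ``(0, -1, 0)`` -> azimuth 0; right
lateral bending has axis ``(1, 0, 0)`` -> azimuth +pi/2; right axial
rotation has axis ``(0, 0, 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StpDirection",
    "SourceRecord",
    "SpatialTuningPattern",
    "StpSet",
    "MuscleGroup",
    "MuscleRegistry",
    "CoverageGapError",
    "DegenerateDirectionError",
    "build_direction_grid",
    "combine_sources",
    "mirror_right_to_left",
    "normalize_per_direction",
    "lookup_weights",
    "direction_from_axis",
    "default_registry",
    "write_stp_csv",
    "read_stp_csv",
    "write_source_csv",
    "read_source_csv",
]

N_BEND_AZIMUTHS = 8
AXIAL_LEVELS = ("left", "none", "right")

#: Source-selection priority: smaller is preferred.
_PRIORITY = {
    ("dynamic", "MVIC"): 1,
    ("dynamic", "peak"): 2,
    ("isometric", "MVIC"): 3,
    ("isometric", "peak"): 3,
}


class CoverageGapError(ValueError):
    """Raised when source tables leave (group, direction) holes that no
    substitute can fill; carries the list of holes."""

    def __init__(self, holes: list[tuple[str, "StpDirection"]]):
        self.holes = holes
        listing = ", ".join(f"{g}@{d}" for g, d in holes[:8])
        more = "" if len(holes) <= 8 else f" (+{len(holes) - 8} more)"
        super().__init__(f"no source covers: {listing}{more}")


class DegenerateDirectionError(ValueError):
    """Raised when a direction has zero activity across all groups and sides."""


@dataclass(frozen=True)
class StpDirection:
    """One of the 26 grid directions.

    ``bend_index`` indexes the eight 45-degree azimuth steps (0 = flexion);
    it is ``None`` for the two pure axial rotation entries, whose bend
    azimuth is undefined.
    """

    bend_index: int | None
    axial_level: str
    pure_axial: bool = False

    def __post_init__(self) -> None:
        if self.axial_level not in AXIAL_LEVELS:
            raise ValueError(f"unknown axial level {self.axial_level!r}")
        if self.pure_axial:
            if self.bend_index is not None:
                raise ValueError("pure axial entries carry no bend azimuth")
            if self.axial_level == "none":
                raise ValueError("pure axial entries must be left or right")
        else:
            if self.bend_index is None or not 0 <= self.bend_index < N_BEND_AZIMUTHS:
                raise ValueError("bend_index must be in 0..7")

    @property
    def bend_azimuth(self) -> float:
        """Bend azimuth in radians; NaN for pure axial entries."""
        if self.pure_axial:
            return float("nan")
        return self.bend_index * 2.0 * np.pi / N_BEND_AZIMUTHS

    def mirrored(self) -> "StpDirection":
        """Reflection about the sagittal plane: azimuth negated, axial
        left and right swapped."""
        swap = {"left": "right", "right": "left", "none": "none"}
        if self.pure_axial:
            return StpDirection(None, swap[self.axial_level], True)
        return StpDirection(
            (-self.bend_index) % N_BEND_AZIMUTHS, swap[self.axial_level], False
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        if self.pure_axial:
            return f"pure-axial-{self.axial_level}"
        return f"az{self.bend_index * 45}-ax-{self.axial_level}"


def build_direction_grid() -> list[StpDirection]:
    """The fixed 26-direction grid, deterministically ordered: bend azimuth
    ascending within each axial level (left, none, right), pure-axial last."""
    grid = [
        StpDirection(k, level)
        for level in AXIAL_LEVELS
        for k in range(N_BEND_AZIMUTHS)
    ]
    grid += [StpDirection(None, "left", True), StpDirection(None, "right", True)]
    return grid


@dataclass(frozen=True)
class SourceRecord:
    """One experimental observation: the normalized activity of one muscle
    on one side for one grid direction in one experiment."""

    experiment_id: str
    condition: str  # "dynamic" | "isometric"
    normalization: str  # "MVIC" | "peak" (within-experiment peak)
    muscle: str
    side: str  # "left" | "right"
    direction: StpDirection
    activity: float

    def __post_init__(self) -> None:
        if self.condition not in ("dynamic", "isometric"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.normalization not in ("MVIC", "peak"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if not np.isfinite(self.activity) or self.activity < 0.0:
            raise ValueError("activity must be finite and non-negative")

    @property
    def priority(self) -> int:
        return _PRIORITY[(self.condition, self.normalization)]


@dataclass(frozen=True)
class SpatialTuningPattern:
    """Direction -> weight map for one muscle group on one side."""

    muscle_group: str
    side: str
    weights: Mapping[StpDirection, float]
    provenance: Mapping[StpDirection, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        for d, w in self.weights.items():
            if not np.isfinite(w) or w < 0.0:
                raise ValueError(f"weight at {d} must be finite and >= 0")


@dataclass(frozen=True)
class MuscleGroup:
    """Registry entry for one of the 11 muscle groups (right-side geometry).

    ``corrects_azimuth`` is the deviation direction (rad, right-side
    convention) the group is anatomically best placed to correct and is used
    by the fixture generator; ``axial_sign`` is +1 if the group corrects
    right axial deviations, -1 for left, 0 for none.  ``attachment`` is the
    skull attachment point in the head frame relative to the head centre of
    gravity; ``origin`` the caudal anchor in the T1 frame relative to T1.
    Both are metres in the library frame (x forward, y right, z down).
    """

    name: str
    substitute: str | None
    max_force: float  # N, per side
    corrects_azimuth: float  # rad
    axial_sign: int
    attachment: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def moment_arm(self) -> np.ndarray:
        """Attachment point relative to the head CoG (T1/head frame, m)."""
        return np.asarray(self.attachment)

    @property
    def line_of_action(self) -> np.ndarray:
        """Unit vector from skull attachment toward the caudal origin at the
        reference posture (T1 frame)."""
        # T1 sits 0.15 m below (+z) the head CoG at reference.
        origin_cog = np.asarray(self.origin) + np.array([0.0, 0.0, 0.15])
        v = origin_cog - np.asarray(self.attachment)
        return v / np.linalg.norm(v)

    def mirrored(self) -> "MuscleGroup":
        ax, ay, az = self.attachment
        ox, oy, oz = self.origin
        return replace(
            self,
            corrects_azimuth=-self.corrects_azimuth,
            axial_sign=-self.axial_sign,
            attachment=(ax, -ay, az),
            origin=(ox, -oy, oz),
        )


def _make_group(
    name: str,
    substitute: str | None,
    max_force: float,
    azimuth_deg: float,
    axial_sign: int,
) -> MuscleGroup:
    """Construct plant-facing geometry from a corrective azimuth.

    The skull attachment sits on a 5 cm ring opposite the corrected
    deviation direction, slightly below the head CoG; the caudal origin sits
    on a matching ring at T1 level, offset tangentially for axial
    correctors.  Pulling along attachment -> origin then produces both a
    restoring force and a restoring torque for deviations toward
    ``corrects_azimuth`` (and about z for ``axial_sign != 0``).
    """
    phi = np.deg2rad(azimuth_deg)
    d = np.array([np.cos(phi), np.sin(phi), 0.0])
    tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
    attachment = -0.05 * d + np.array([0.0, 0.0, 0.02])
    origin = -0.05 * d + axial_sign * 0.05 * tangent  # T1 frame, at T1 level
    return MuscleGroup(
        name=name,
        substitute=substitute,
        max_force=max_force,
        corrects_azimuth=phi,
        axial_sign=axial_sign,
        attachment=tuple(attachment),
        origin=tuple(origin),
    )


def default_registry() -> "MuscleRegistry":
    """Default 11-group registry.

    Group membership, substitutes, forces and geometry are this library's
    own anatomically motivated choices (documented in the methods note), not
    experimental data.  Azimuths follow the right-side convention (0 =
    corrects forward/flexion deviation, i.e. an extensor).
    """
    groups = [
        _make_group("semispinalis_capitis", None, 150.0, 0.0, 0),
        _make_group("semispinalis_cervicis", "semispinalis_capitis", 100.0, 20.0, 0),
        _make_group("splenius_capitis", None, 120.0, 45.0, -1),
        _make_group("trapezius", "semispinalis_capitis", 250.0, 60.0, 0),
        _make_group("levator_scapulae", "splenius_capitis", 80.0, 90.0, 0),
        _make_group("scalenus_medius", "scalenus_anterior", 90.0, 110.0, 0),
        _make_group("scalenus_anterior", None, 100.0, 135.0, 0),
        _make_group("sternocleidomastoid", None, 200.0, 160.0, 1),
        _make_group("sternohyoid", None, 30.0, 175.0, 0),
        _make_group("longus_capitis", None, 60.0, 180.0, 0),
        _make_group("longus_colli", "longus_capitis", 50.0, -170.0, 0),
    ]
    return MuscleRegistry(groups)


class MuscleRegistry:
    """The muscle groups the controller distributes drive across."""

    def __init__(self, groups: Iterable[MuscleGroup]):
        self.groups: dict[str, MuscleGroup] = {}
        for g in groups:
            if g.name in self.groups:
                raise ValueError(f"duplicate group {g.name!r}")
            self.groups[g.name] = g
        for g in self.groups.values():
            seen = {g.name}
            sub = g.substitute
            while sub is not None:
                if sub not in self.groups:
                    raise ValueError(f"substitute {sub!r} of {g.name!r} unknown")
                if sub in seen:
                    raise ValueError(f"substitute cycle through {g.name!r}")
                seen.add(sub)
                sub = self.groups[sub].substitute

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def substitute_chain(self, name: str) -> list[str]:
        """Substitutes of ``name`` in resolution order (nearest first)."""
        chain = []
        sub = self.groups[name].substitute
        while sub is not None:
            chain.append(sub)
            sub = self.groups[sub].substitute
        return chain


def combine_sources(
    records: Iterable[SourceRecord], registry: MuscleRegistry
) -> dict[str, SpatialTuningPattern]:
    """Merge source tables into one raw right-side pattern per muscle group.

    For each (group, direction) the single best source is selected by
    priority: dynamic+MVIC first, then dynamic with within-experiment-peak
    normalization, then isometric; ties break on experiment id for
    determinism.  A group absent from every source for a direction borrows
    the value of its substitute group (provenance marked ``substituted``).
    Only right-side records participate; left patterns are obtained by
    mirroring afterwards.
    """
    grid = build_direction_grid()
    by_key: dict[tuple[str, StpDirection], SourceRecord] = {}
    for rec in records:
        if rec.side != "right":
            continue
        key = (rec.muscle, rec.direction)
        best = by_key.get(key)
        if best is None or (rec.priority, rec.experiment_id) < (
            best.priority,
            best.experiment_id,
        ):
            by_key[key] = rec

    holes: list[tuple[str, StpDirection]] = []
    patterns: dict[str, SpatialTuningPattern] = {}
    for name in registry.names:
        weights: dict[StpDirection, float] = {}
        provenance: dict[StpDirection, str] = {}
        for d in grid:
            rec = by_key.get((name, d))
            if rec is not None:
                weights[d] = rec.activity
                provenance[d] = f"{rec.experiment_id}:{rec.condition}:{rec.normalization}"
                continue
            for sub in registry.substitute_chain(name):
                rec = by_key.get((sub, d))
                if rec is not None:
                    weights[d] = rec.activity
                    provenance[d] = f"substituted:{sub}:{rec.experiment_id}"
                    break
            else:
                holes.append((name, d))
        patterns[name] = SpatialTuningPattern(name, "right", weights, provenance)
    if holes:
        raise CoverageGapError(holes)
    return patterns


def mirror_right_to_left(stp: SpatialTuningPattern) -> SpatialTuningPattern:
    """Mirror a right-side pattern about the sagittal plane: the bend azimuth
    is reflected and the axial level swapped left<->right."""
    if stp.side != "right":
        raise ValueError("mirroring is defined from right-side patterns only")
    weights = {d.mirrored(): w for d, w in stp.weights.items()}
    provenance = {d.mirrored(): p for d, p in stp.provenance.items()}
    return SpatialTuningPattern(stp.muscle_group, "left", weights, provenance)


@dataclass(frozen=True)
class StpSet:
    """All patterns, both sides, sharing the 26-direction grid."""

    patterns: Mapping[tuple[str, str], SpatialTuningPattern]

    @classmethod
    def from_right_patterns(
        cls, right: Mapping[str, SpatialTuningPattern]
    ) -> "StpSet":
        patterns: dict[tuple[str, str], SpatialTuningPattern] = {}
        for name, stp in right.items():
            patterns[(name, "right")] = stp
            patterns[(name, "left")] = mirror_right_to_left(stp)
        return cls(patterns)

    @property
    def channels(self) -> list[tuple[str, str]]:
        """Deterministic (group, side) channel order."""
        return sorted(self.patterns)

    def weight_matrix(self) -> tuple[list[tuple[str, str]], list[StpDirection], np.ndarray]:
        channels = self.channels
        grid = build_direction_grid()
        w = np.array(
            [[self.patterns[c].weights[d] for d in grid] for c in channels]
        )
        return channels, grid, w


def normalize_per_direction(stps: StpSet) -> StpSet:
    """Normalize every direction by the maximum activity across all groups
    and both sides at that direction, so the per-direction maximum is 1."""
    channels, grid, w = stps.weight_matrix()
    maxima = w.max(axis=0)
    zero = [grid[j] for j in range(len(grid)) if maxima[j] <= 0.0]
    if zero:
        raise DegenerateDirectionError(
            f"all-zero activity at direction(s): {', '.join(map(str, zero))}"
        )
    w = w / maxima[np.newaxis, :]
    patterns = {}
    for i, c in enumerate(channels):
        old = stps.patterns[c]
        patterns[c] = SpatialTuningPattern(
            old.muscle_group,
            old.side,
            {d: float(w[i, j]) for j, d in enumerate(grid)},
            old.provenance,
        )
    return StpSet(patterns)


class StpInterpolator:
    """Precomputed weight arrays for fast directional queries.

    Bilinear scheme: periodic-linear in azimuth between the two adjacent
    45-degree grid azimuths, and piecewise linear in ``|axial_component|``
    — from the no-axial level at 0 to the signed axial level at
    ``axial_knot``, then blending toward the signed pure-axial entry at
    ``|axial_component| = 1``.  The sign of the axial component selects the
    left or right axial level.  Outputs are convex combinations of stored
    weights, hence stay in [0, 1] for normalized patterns.
    """

    def __init__(self, stps: StpSet):
        self.channels = stps.channels
        self._levels = {
            level: np.array(
                [
                    [stps.patterns[c].weights[StpDirection(k, level)] for k in range(N_BEND_AZIMUTHS)]
                    for c in self.channels
                ]
            )
            for level in AXIAL_LEVELS
        }
        self._pure = {
            level: np.array(
                [stps.patterns[c].weights[StpDirection(None, level, True)] for c in self.channels]
            )
            for level in ("left", "right")
        }

    def query(
        self, bend_azimuth: float, axial_component: float, axial_knot: float = 0.5
    ) -> np.ndarray:
        if not (np.isfinite(bend_azimuth) and np.isfinite(axial_component)):
            raise ValueError("direction query must be finite")
        if not 0.0 < axial_knot < 1.0:
            raise ValueError("axial_knot must lie in (0, 1)")
        axial_component = float(np.clip(axial_component, -1.0, 1.0))

        pos = (bend_azimuth % (2.0 * np.pi)) / (2.0 * np.pi / N_BEND_AZIMUTHS)
        k0 = int(np.floor(pos)) % N_BEND_AZIMUTHS
        k1 = (k0 + 1) % N_BEND_AZIMUTHS
        frac = pos - np.floor(pos)

        def bend(level: str) -> np.ndarray:
            w = self._levels[level]
            return (1.0 - frac) * w[:, k0] + frac * w[:, k1]

        t = abs(axial_component)
        level = "right" if axial_component > 0 else "left"
        if t == 0.0:
            return bend("none")
        if t <= axial_knot:
            alpha = t / axial_knot
            return (1.0 - alpha) * bend("none") + alpha * bend(level)
        beta = (t - axial_knot) / (1.0 - axial_knot)
        return (1.0 - beta) * bend(level) + beta * self._pure[level]


def lookup_weights(
    stps: StpSet,
    bend_azimuth: float,
    axial_component: float,
    *,
    axial_knot: float = 0.5,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Interpolate the per-channel weights at an arbitrary direction.

    Convenience wrapper around :class:`StpInterpolator`; see its docstring
    for the interpolation scheme.
    """
    interp = StpInterpolator(stps)
    return interp.channels, interp.query(bend_azimuth, axial_component, axial_knot)


def direction_from_axis(axis: np.ndarray) -> tuple[float, float]:
    """Map a rotation axis (unit 3-vector) to (bend_azimuth, axial_component)
    for the STP query; see the module docstring table."""
    v = np.asarray(axis, dtype=float)
    azimuth = float(np.arctan2(v[0], -v[1])) if np.hypot(v[0], v[1]) > 0 else 0.0
    return azimuth, float(np.clip(v[2], -1.0, 1.0))


# ---------------------------------------------------------------------------
# CSV serialization (header row mandatory; degrees at the I/O boundary)
# ---------------------------------------------------------------------------


def _direction_to_fields(d: StpDirection) -> tuple[float, str, bool]:
    az = float("nan") if d.pure_axial else np.rad2deg(d.bend_azimuth)
    return az, d.axial_level, d.pure_axial


def _direction_from_fields(az_deg: float, level: str, pure: bool) -> StpDirection:
    if pure:
        return StpDirection(None, level, True)
    k = int(round(float(az_deg) / 45.0)) % N_BEND_AZIMUTHS
    return StpDirection(k, level)


def write_source_csv(records: Iterable[SourceRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        az, level, pure = _direction_to_fields(r.direction)
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "condition": r.condition,
                "normalization": r.normalization,
                "muscle": r.muscle,
                "side": r.side,
                "bend_azimuth_deg": az,
                "axial_level": level,
                "pure_axial": pure,
                "activity": r.activity,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_source_csv(path: str | Path) -> list[SourceRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SourceRecord(
                experiment_id=str(row.experiment_id),
                condition=row.condition,
                normalization=row.normalization,
                muscle=row.muscle,
                side=row.side,
                direction=_direction_from_fields(
                    row.bend_azimuth_deg, row.axial_level, bool(row.pure_axial)
                ),
                activity=float(row.activity),
            )
        )
    return records


def write_stp_csv(stps: StpSet, path: str | Path) -> None:
    rows = []
    grid = build_direction_grid()
    for (group, side) in stps.channels:
        stp = stps.patterns[(group, side)]
        for d in grid:
            az, level, pure = _direction_to_fields(d)
            rows.append(
                {
                    "group": group,
                    "side": side,
                    "bend_azimuth_deg": az,
                    "axial_level": level,
                    "pure_axial": pure,
                    "weight": stp.weights[d],
                    "provenance": stp.provenance.get(d, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stp_csv(path: str | Path) -> StpSet:
    df = pd.read_csv(path)
    patterns: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        key = (str(row.group), str(row.side))
        entry = patterns.setdefault(key, {"weights": {}, "provenance": {}})
        d = _direction_from_fields(
            row.bend_azimuth_deg, row.axial_level, bool(row.pure_axial)
        )
        entry["weights"][d] = float(row.weight)
        prov = row.provenance if isinstance(row.provenance, str) else ""
        entry["provenance"][d] = prov
    return StpSet(
        {
            (g, s): SpatialTuningPattern(g, s, e["weights"], e["provenance"])
            for (g, s), e in patterns.items()
        }
    )
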
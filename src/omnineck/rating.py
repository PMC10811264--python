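"""Objective bio-fidelity rating of simulated channels against reference
corridors.

The score for one channel combines a corridor sub-score (containment
between inner and outer bands around the reference mean) with
cross-correlation sub-scores for shape, size and phase, in the structure
of the published CORA rating scheme.  Scores are comparable in structure,
not numerically, to the proprietary CORAplus implementation; every
constant lives in :class:`CoraSettings`.  Channel scores aggregate into
translation and rotation composites weighted by the reference peak
magnitude, and the overall score is the mean of the two composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceCorridor",
    "CoraSettings",
    "BioFidelityReport",
    "InvalidIntervalError",
    "UndefinedWeightingError",
    "RATING_LABELS",
    "cora_score",
    "classify_rating",
    "overall_score",
    "activity_similarity",
    "write_corridor_csv",
    "read_corridor_csv",
]

RATING_LABELS = ("excellent", "good", "fair", "poor")

#: Default rating ladder (score at or above a cut earns the higher label).
DEFAULT_THRESHOLDS = (0.94, 0.80, 0.58)


class InvalidIntervalError(ValueError):
    """Raised when an evaluation or averaging window is empty."""


class UndefinedWeightingError(ValueError):
    """Raised when every peak in a channel family is zero, leaving the
    magnitude weighting undefined."""


@dataclass(frozen=True)
class ReferenceCorridor:
    """Reference mean +/- SD time history for one channel."""

    channel: str
    time: np.ndarray  # s, uniform
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if not (t.shape == m.shape == s.shape) or t.ndim != 1 or len(t) < 2:
            raise ValueError("corridor arrays must be aligned 1-D series")
        if np.any(s < 0.0):
            raise ValueError("sd must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)

    @property
    def peak(self) -> float:
        """Peak magnitude of the reference mean (used for weighting)."""
        return float(np.max(np.abs(self.mean)))


@dataclass(frozen=True)
class CoraSettings:
    """All rating constants.

    ``corridor_mode`` selects how corridor half-widths are built: ``"sd"``
    uses multiples of the per-sample reference SD, ``"peak_fraction"``
    fractions of the reference peak.  Top-level and correlation sub-weights
    must each sum to 1.
    """

    corridor_mode: str = "sd"
    inner_width: float = 1.0  # x SD, or x peak
    outer_width: float = 2.0
    corridor_weight: float = 0.5
    correlation_weight: float = 0.5
    shape_weight: float = 0.5
    size_weight: float = 0.25
    phase_weight: float = 0.25
    max_shift_fraction: float = 0.2
    eval_interval: tuple[float, float] | None = None
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.corridor_mode not in ("sd", "peak_fraction"):
            raise ValueError("corridor_mode must be 'sd' or 'peak_fraction'")
        if self.outer_width <= self.inner_width:
            raise ValueError("outer corridor must be wider than inner")
        if abs(self.corridor_weight + self.correlation_weight - 1.0) > 1e-9:
            raise ValueError("method weights must sum to 1")
        if abs(self.shape_weight + self.size_weight + self.phase_weight - 1.0) > 1e-9:
            raise ValueError("correlation sub-weights must sum to 1")
        if not (
            1.0 >= self.thresholds[0] > self.thresholds[1] > self.thresholds[2] >= 0.0
        ):
            raise ValueError("thresholds must be strictly decreasing in [0, 1]")


def cora_score(
    sim: np.ndarray,
    corridor: ReferenceCorridor,
    settings: CoraSettings | None = None,
    *,
    return_subscores: bool = False,
) -> float | tuple[float, dict[str, float]]:
    """Score one simulated channel against its reference corridor, in [0, 1].

    Corridor sub-score: per sample, 1 inside the inner band, 0 outside the
    outer band, linear between; time-averaged.  Correlation sub-scores:
    shape is the peak normalized cross-correlation over the allowed shift,
    size the ratio of absolute areas, phase maps the best-correlation shift
    to [0, 1].  The total is the weighted sum per the settings.
    """
    settings = settings or CoraSettings()
    sim = np.asarray(sim, dtype=float)
    if sim.shape != corridor.time.shape:
        raise ValueError("sim must be resampled onto the corridor time base")

    mask = np.ones_like(corridor.time, dtype=bool)
    if settings.eval_interval is not None:
        t0, t1 = settings.eval_interval
        mask = (corridor.time >= t0) & (corridor.time <= t1)
        if not mask.any():
            raise InvalidIntervalError(f"evaluation interval ({t0}, {t1}) is empty")
    t = corridor.time[mask]
    y = sim[mask]
    m = corridor.mean[mask]
    s = corridor.sd[mask]

    if settings.corridor_mode == "sd":
        inner = settings.inner_width * s
        outer = settings.outer_width * s
    else:
        peak = np.max(np.abs(m))
        inner = np.full_like(m, settings.inner_width * peak)
        outer = np.full_like(m, settings.outer_width * peak)

    dev = np.abs(y - m)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(
            dev <= inner,
            1.0,
            np.where(dev >= outer, 0.0, (outer - dev) / np.maximum(outer - inner, 1e-300)),
        )
    corridor_sub = float(np.mean(frac))

    n = len(y)
    max_shift = max(int(round(settings.max_shift_fraction * n)), 1)
    norm_y = np.linalg.norm(y)
    norm_m = np.linalg.norm(m)
    if norm_y <= 0.0 or norm_m <= 0.0:
        shape_sub = size_sub = phase_sub = 0.0
    else:
        best_corr, best_shift = -np.inf, 0
        for shift in range(-max_shift, max_shift + 1):
            if shift >= 0:
                a, b = y[shift:], m[: n - shift]
            else:
                a, b = y[: n + shift], m[-shift:]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            corr = float(a @ b / denom) if denom > 0 else 0.0
            if corr > best_corr:
                best_corr, best_shift = corr, shift
        shape_sub = max(best_corr, 0.0)
        area_y = float(np.trapezoid(np.abs(y), t))
        area_m = float(np.trapezoid(np.abs(m), t))
        size_sub = min(area_y, area_m) / max(area_y, area_m) if max(area_y, area_m) > 0 else 0.0
        phase_sub = 1.0 - abs(best_shift) / max_shift

    correlation_sub = (
        settings.shape_weight * shape_sub
        + settings.size_weight * size_sub
        + settings.phase_weight * phase_sub
    )
    score = (
        settings.corridor_weight * corridor_sub
        + settings.correlation_weight * correlation_sub
    )
    score = float(np.clip(score, 0.0, 1.0))
    if return_subscores:
        return score, {
            "corridor": corridor_sub,
            "shape": shape_sub,
            "size": size_sub,
            "phase": phase_sub,
        }
    return score


def classify_rating(
    score: float, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Bin a score into excellent/good/fair/poor; a boundary score earns
    the higher label."""
    if not (1.0 >= thresholds[0] > thresholds[1] > thresholds[2] >= 0.0):
        raise ValueError("thresholds must be strictly decreasing in [0, 1]")
    for cut, label in zip(thresholds, RATING_LABELS[:3]):
        if score >= cut:
            return label
    return "poor"


@dataclass(frozen=True)
class BioFidelityReport:
    """Per-channel scores and ratings plus magnitude-weighted composites."""

    channel_scores: Mapping[str, float]
    channel_ratings: Mapping[str, str]
    translation_composite: float
    rotation_composite: float
    overall: float
    overall_rating: str
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    meta: Mapping[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": c, "score": self.channel_scores[c], "rating": self.channel_ratings[c]}
            for c in sorted(self.channel_scores)
        ]
        rows.append(
            {"channel": "_translation", "score": self.translation_composite, "rating": ""}
        )
        rows.append({"channel": "_rotation", "score": self.rotation_composite, "rating": ""})
        rows.append({"channel": "_overall", "score": self.overall, "rating": self.overall_rating})
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    ) -> "BioFidelityReport":
        df = pd.read_csv(path).fillna({"rating": ""})
        scores, ratings = {}, {}
        composites = {}
        overall_rating = ""
        for row in df.itertuples(index=False):
            if str(row.channel).startswith("_"):
                composites[row.channel] = float(row.score)
                if row.channel == "_overall":
                    overall_rating = str(row.rating)
            else:
                scores[str(row.channel)] = float(row.score)
                ratings[str(row.channel)] = str(row.rating)
        return cls(
            channel_scores=scores,
            channel_ratings=ratings,
            translation_composite=composites["_translation"],
            rotation_composite=composites["_rotation"],
            overall=composites["_overall"],
            overall_rating=overall_rating,
            thresholds=thresholds,
        )


def overall_score(
    channel_scores: Mapping[str, float],
    peaks: Mapping[str, float],
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> BioFidelityReport:
    """Aggregate channel scores into a bio-fidelity report.

    Translation channels (``head_t*``) and rotation channels (``head_r*``)
    form separate composites, each a mean weighted by the reference peak
    magnitude, so small-magnitude channels matter less; the overall score
    gives the two families equal value.
    """
    missing = set(channel_scores) - set(peaks)
    if missing:
        raise ValueError(f"missing reference peaks for: {sorted(missing)}")

    def composite(prefix: str) -> float:
        names = [c for c in channel_scores if c.startswith(prefix)]
        if not names:
            raise UndefinedWeightingError(f"no channels with prefix {prefix!r}")
        w = np.array([abs(peaks[c]) for c in names])
        if w.sum() <= 0.0:
            raise UndefinedWeightingError(
                f"all reference peaks are zero for family {prefix!r}"
            )
        s = np.array([channel_scores[c] for c in names])
        return float((s * w).sum() / w.sum())

    trans = composite("head_t")
    rot = composite("head_r")
    overall = 0.5 * (trans + rot)
    return BioFidelityReport(
        channel_scores=dict(channel_scores),
        channel_ratings={
            c: classify_rating(v, thresholds) for c, v in channel_scores.items()
        },
        translation_composite=trans,
        rotation_composite=rot,
        overall=overall,
        overall_rating=classify_rating(overall, thresholds),
        thresholds=thresholds,
    )


def activity_similarity(
    time: np.ndarray,
    activation: np.ndarray,
    window: tuple[float, float],
    ref_mean: float,
    ref_sd: float,
) -> str:
    """Classify a muscle's time-averaged activity over a window as
    ``"similar"`` if it falls within the reference mean +/- 1 SD
    (bounds inclusive), else ``"dissimilar"``."""
    time = np.asarray(time, dtype=float)
    activation = np.asarray(activation, dtype=float)
    t0, t1 = window
    mask = (time >= t0) & (time <= t1)
    if not mask.any():
        raise InvalidIntervalError(f"averaging window ({t0}, {t1}) is empty")
    avg = float(np.mean(activation[mask]))
    # inclusive bounds, with a relative epsilon so float accumulation noise
    # cannot flip a boundary case
    eps = 1e-9 * max(abs(ref_mean) + ref_sd, 1.0)
    lo, hi = ref_mean - ref_sd - eps, ref_mean + ref_sd + eps
    return "similar" if lo <= avg <= hi else "dissimilar"


def write_corridor_csv(corridors: Mapping[str, ReferenceCorridor], path: str | Path) -> None:
    """One CSV per corridor set: (channel, time, mean, sd) long format."""
    rows = []
    for name in sorted(corridors):
        c = corridors[name]
        for t, m, s in zip(c.time, c.mean, c.sd):
            rows.append({"channel": name, "time": t, "mean": m, "sd": s})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_corridor_csv(path: str | Path) -> dict[str, ReferenceCorridor]:
    df = pd.read_csv(path)
    out = {}
    for name, grp in df.groupby("channel", sort=True):
        out[str(name)] = ReferenceCorridor(
            channel=str(name),
            time=grp["time"].to_numpy(),
            mean=grp["mean"].to_numpy(),
            sd=grp["sd"].to_numpy(),
        )
    return out
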
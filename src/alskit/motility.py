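"""Cone-section classification of axonal mitochondrial motility.

Directions are binned with cone sections of a sphere around a per-recording
axis (the unit vector pointing away from the neurosphere/soma, i.e. the
anterograde direction).  With cos(half-angle) = 1/3 the internal cone angle
is 2·acos(1/3) ≈ 141° and the two polar caps and the equatorial band each
cover exactly one third of the sphere's surface ((1 − 1/3)/2 per cap).  That
equal trisection is a 3D property; the same rule is applied unchanged to 2D
data (where the sectors are not equal-measure), matching how planar
epifluorescence recordings are analysed.

A branch is *stationary* when it never exceeds a low step speed
(max step speed < 0.05 µm/s) or covers little ground over the time-lapse
(summed step distance < 2 µm).  Otherwise its net start→end displacement is
classified with the cone rule; branches moving orthogonally overall are
excluded from the motility proportions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from alskit.track_io import Branch

__all__ = [
    "MotilityClass",
    "MotilityParams",
    "RecordingSummary",
    "AssociationResult",
    "classify_direction",
    "classify_branch",
    "summarize_recording",
    "association_test",
    "estimate_axis",
    "CONE_COS_HALF_ANGLE",
    "SPEED_THRESHOLD_UM_S",
    "DISTANCE_THRESHOLD_UM",
]

#: cos of the cone half-angle that trisects the sphere
CONE_COS_HALF_ANGLE = 1.0 / 3.0
#: µm/s — a branch never exceeding this step speed is stationary
SPEED_THRESHOLD_UM_S = 0.05
#: µm — a branch whose summed step length stays below this is stationary
DISTANCE_THRESHOLD_UM = 2.0


class MotilityClass(enum.Enum):
    STATIONARY = "stationary"
    ANTEROGRADE = "anterograde"
    RETROGRADE = "retrograde"
    ORTHOGONAL_EXCLUDED = "orthogonal_excluded"


#: classes entering the motility proportions (orthogonal movement excluded)
INCLUDED_CLASSES = (
    MotilityClass.STATIONARY,
    MotilityClass.ANTEROGRADE,
    MotilityClass.RETROGRADE,
)


@dataclass(frozen=True)
class MotilityParams:
    """Classification constants plus the per-recording anterograde axis."""

    axis: tuple[float, ...] = (1.0, 0.0)
    cos_half_angle: float = CONE_COS_HALF_ANGLE
    speed_threshold: float = SPEED_THRESHOLD_UM_S
    distance_threshold: float = DISTANCE_THRESHOLD_UM
    per_step_vote: bool = False  # sensitivity alternative to net displacement

    def __post_init__(self) -> None:
        if not 0.0 < self.cos_half_angle < 1.0:
            raise ValueError("cos_half_angle must be in (0, 1)")
        if self.speed_threshold <= 0 or self.distance_threshold <= 0:
            raise ValueError("thresholds must be positive")
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"axis must be a unit vector (norm {norm})")


def classify_direction(
    step: Sequence[float], axis: Sequence[float], cos_half_angle: float = CONE_COS_HALF_ANGLE
) -> str | None:
    """Classify one displacement vector against the anterograde axis.

    Returns ``"anterograde"``, ``"retrograde"``, ``"orthogonal"`` or ``None``
    for a zero-length step (no movement; callers skip those).  The boundary
    c = ±cos_half_angle is inclusive to the motile classes.
    """
    step = np.asarray(step, dtype=float)
    norm = np.linalg.norm(step)
    if norm == 0.0:
        return None
    c = float(np.dot(step, axis)) / norm
    if c >= cos_half_angle:
        return "anterograde"
    if c <= -cos_half_angle:
        return "retrograde"
    return "orthogonal"


def classify_branch(branch: Branch, params: MotilityParams) -> MotilityClass:
    """Classify one branch as stationary / anterograde / retrograde / excluded.

    Stationary wins if either low-motility rule holds; a non-stationary
    branch with exactly zero net displacement is a degenerate case also
    labelled stationary.
    """
    if branch.max_step_speed < params.speed_threshold:
        return MotilityClass.STATIONARY
    if branch.path_length < params.distance_threshold:
        return MotilityClass.STATIONARY
    if params.per_step_vote:
        votes = [
            classify_direction(v, params.axis, params.cos_half_angle)
            for v in branch.step_vectors
        ]
        counts = {k: sum(v == k for v in votes) for k in ("anterograde", "retrograde", "orthogonal")}
        direction = max(counts, key=lambda k: (counts[k], k == "anterograde"))
        if all(v is None for v in votes):
            direction = None
    else:
        direction = classify_direction(
            branch.net_displacement, params.axis, params.cos_half_angle
        )
    if direction is None:
        return MotilityClass.STATIONARY
    if direction == "orthogonal":
        return MotilityClass.ORTHOGONAL_EXCLUDED
    return MotilityClass(direction)


@dataclass
class RecordingSummary:
    """Per-recording class counts, proportions and ternary coordinates.

    Proportions are over stationary + anterograde + retrograde only; the
    ternary embedding is the standard 2-simplex
    (x, y) = (p_antero + p_retro/2, p_retro·√3/2).
    """

    recording_id: str
    line_id: str
    counts: dict[MotilityClass, int]
    proportions: dict[MotilityClass, float] | None
    ternary_xy: tuple[float, float] | None

    @property
    def n_included(self) -> int:
        return sum(self.counts[c] for c in INCLUDED_CLASSES)


def summarize_recording(
    branches: Iterable[Branch],
    params: MotilityParams,
    recording_id: str = "",
    line_id: str = "",
) -> RecordingSummary:
    """Classify all branches of one recording and summarize the composition."""
    counts = {c: 0 for c in MotilityClass}
    for b in branches:
        counts[classify_branch(b, params)] += 1
    total = sum(counts[c] for c in INCLUDED_CLASSES)
    if total == 0:
        return RecordingSummary(recording_id, line_id, counts, None, None)
    props = {c: counts[c] / total for c in INCLUDED_CLASSES}
    p_a = props[MotilityClass.ANTEROGRADE]
    p_r = props[MotilityClass.RETROGRADE]
    ternary = (p_a + 0.5 * p_r, p_r * math.sqrt(3.0) / 2.0)
    return RecordingSummary(recording_id, line_id, counts, props, ternary)


@dataclass
class AssociationResult:
    """Pearson χ² association between cell line and motility class.

    ``pearson_residuals`` are (O − E)/√E; positive residuals mark attraction
    (observed above expected), negative mark repulsion.  ``contributions``
    are residual²/χ² and sum to 1 whenever χ² > 0.
    """

    chi2: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    pearson_residuals: pd.DataFrame
    contributions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "pearson_residuals": self.pearson_residuals.to_dict(),
            "contributions": self.contributions.to_dict(),
        }


def association_test(contingency: pd.DataFrame | np.ndarray) -> AssociationResult:
    """Pearson χ² test (no continuity correction) on a line × class table.

    Expected counts come from the margins; the p-value is the upper tail of
    χ² with (r−1)(c−1) degrees of freedom.
    """
    obs = pd.DataFrame(contingency)
    arr = obs.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if np.any(arr < 0):
        raise ValueError("negative counts in contingency table")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if np.any(row_sums == 0):
        bad = obs.index[np.where(row_sums == 0)[0][0]]
        raise ValueError(f"zero margin in row {bad!r}")
    if np.any(col_sums == 0):
        bad = obs.columns[np.where(col_sums == 0)[0][0]]
        raise ValueError(f"zero margin in column {bad!r}")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    resid = (arr - expected) / np.sqrt(expected)
    contrib = resid**2 / chi2 if chi2 > 0 else np.zeros_like(resid)
    wrap = lambda a: pd.DataFrame(a, index=obs.index, columns=obs.columns)
    return AssociationResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        observed=obs,
        expected=wrap(expected),
        pearson_residuals=wrap(resid),
        contributions=wrap(contrib),
    )


def estimate_axis(first_frame_positions: np.ndarray, sign: int = 1) -> np.ndarray:
    """Estimate the anterograde axis as the first principal axis of first-frame
    spot positions, oriented by a user-supplied sign.

    The principal axis fixes the line of the axon, not which end is the soma;
    ``sign`` (+1/−1) selects the outward direction and must come from the
    experimenter's knowledge of the recording geometry.
    """
    pos = np.asarray(first_frame_positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise ValueError("need at least two positions to estimate an axis")
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    return sign * axis / np.linalg.norm(axis)


def plot_ternary(summaries: Iterable[RecordingSummary], ax=None):
    """Scatter recordings in the stationary/anterograde/retrograde simplex.

    Each recording is one point at its ternary coordinates, colored by line.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    summaries = list(summaries)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    h = math.sqrt(3.0) / 2.0
    ax.plot([0, 1, 0.5, 0], [0, 0, h, 0], color="0.4", lw=1)
    lines = sorted({s.line_id for s in summaries if s.ternary_xy is not None})
    cmap = plt.get_cmap("tab10")
    for i, line in enumerate(lines):
        pts = [s.ternary_xy for s in summaries if s.line_id == line and s.ternary_xy]
        if pts:
            xs, ys = zip(*pts)
            ax.scatter(xs, ys, s=25, color=cmap(i % 10), label=line or None)
    for label, xy in [("stationary", (0, 0)), ("anterograde", (1, 0)), ("retrograde", (0.5, h))]:
        ax.annotate(label, xy, textcoords="offset points", xytext=(0, -12 if xy[1] == 0 else 6),
                    ha="center", fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    if lines and any(lines):
        ax.legend(frameon=False, fontsize=8)
    return ax


def classification_table(
    branches: Iterable[Branch], params: MotilityParams
) -> pd.DataFrame:
    """Per-branch classification as a tidy table (for TSV export)."""
    rows = []
    for b in branches:
        rows.append(
            {
                "branch_id": b.branch_id,
                "track_id": b.track_id,
                "n_spots": b.n_spots,
                "path_length_um": b.path_length,
                "net_distance_um": b.net_distance,
                "max_step_speed_um_s": b.max_step_speed,
                "duration_s": b.duration,
                "motility_class": classify_branch(b, params).value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "branch_id",
            "track_id",
            "n_spots",
            "path_length_um",
            "net_distance_um",
            "max_step_speed_um_s",
            "duration_s",
            "motility_class",
        ],
    )
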
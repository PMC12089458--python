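"""First-frame axial nearest-neighbour spacing of mitochondria.

For every mitochondrion present in the first frame of a recording, its
nearest neighbour in the anterograde and in the retrograde direction is
found among the mitochondria whose relative position vector falls in the
same cone section used for motility classification; the nearest candidate is
taken by Euclidean distance.  When both neighbours exist, the distance
across the three mitochondria (sum of the two) and the absolute difference
between the pair of opposing distances are recorded.

Group comparisons use recording-level means as the experimental unit: a
one-way ANOVA across lines followed by pairwise two-sided Wilcoxon rank-sum
tests of each mutant line against the reference line, with unadjusted
p-values and conventional significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from alskit.motility import CONE_COS_HALF_ANGLE, classify_direction
from alskit.track_io import Branch

__all__ = ["SpacingRecord", "neighbor_distances", "records_from_branches", "compare_groups"]


@dataclass
class SpacingRecord:
    """Nearest-neighbour distances (µm) for one mitochondrion."""

    mito_id: int
    position: tuple[float, ...]
    antero_neighbor_dist: float | None
    retro_neighbor_dist: float | None

    @property
    def across_dist(self) -> float | None:
        if self.antero_neighbor_dist is None or self.retro_neighbor_dist is None:
            return None
        return self.antero_neighbor_dist + self.retro_neighbor_dist

    @property
    def abs_diff(self) -> float | None:
        if self.antero_neighbor_dist is None or self.retro_neighbor_dist is None:
            return None
        return abs(self.antero_neighbor_dist - self.retro_neighbor_dist)


def neighbor_distances(
    positions: Sequence[Sequence[float]] | np.ndarray,
    axis: Sequence[float],
    cos_half_angle: float = CONE_COS_HALF_ANGLE,
    mito_ids: Sequence[int] | None = None,
) -> list[SpacingRecord]:
    """Axial nearest-neighbour distances for a set of first-frame positions.

    For each mitochondrion, neighbours are the others whose relative
    position vector classifies anterograde (resp. retrograde) under the cone
    rule; the nearest per side by Euclidean distance is kept.  Ties are
    broken by the smallest ``mito_id``.  A side with no candidate stays
    missing.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise ValueError("need at least two positions")
    ids = list(mito_ids) if mito_ids is not None else list(range(len(pos)))
    records = []
    for i in range(len(pos)):
        best: dict[str, tuple[float, int]] = {}
        for j in range(len(pos)):
            if i == j:
                continue
            rel = pos[j] - pos[i]
            side = classify_direction(rel, axis, cos_half_angle)
            if side not in ("anterograde", "retrograde"):
                continue
            d = float(np.linalg.norm(rel))
            if side not in best or (d, ids[j]) < best[side]:
                best[side] = (d, ids[j])
        records.append(
            SpacingRecord(
                mito_id=ids[i],
                position=tuple(pos[i]),
                antero_neighbor_dist=best["anterograde"][0] if "anterograde" in best else None,
                retro_neighbor_dist=best["retrograde"][0] if "retrograde" in best else None,
            )
        )
    return records


def records_from_branches(
    branches: Iterable[Branch],
    axis: Sequence[float],
    cos_half_angle: float = CONE_COS_HALF_ANGLE,
    first_frame_only: bool = True,
) -> list[SpacingRecord]:
    """Spacing records from a recording's branches.

    By default only mitochondria already present in frame 0 enter (one
    position per branch, its frame-0 spot); with ``first_frame_only=False``
    every branch contributes the position of its first spot regardless of
    when it appears.
    """
    positions, ids = [], []
    for b in branches:
        s = b.first_spot
        if first_frame_only and s.frame != 0:
            continue
        positions.append(s.position)
        ids.append(b.branch_id)
    if len(positions) < 2:
        return []
    return neighbor_distances(positions, axis, cos_half_angle, mito_ids=ids)


def spacing_table(records: Iterable[SpacingRecord]) -> pd.DataFrame:
    """Tidy per-mitochondrion table of spacing distances."""
    return pd.DataFrame(
        [
            {
                "mito_id": r.mito_id,
                "antero_neighbor_dist_um": r.antero_neighbor_dist,
                "retro_neighbor_dist_um": r.retro_neighbor_dist,
                "across_dist_um": r.across_dist,
                "abs_diff_um": r.abs_diff,
            }
            for r in records
        ],
        columns=[
            "mito_id",
            "antero_neighbor_dist_um",
            "retro_neighbor_dist_um",
            "across_dist_um",
            "abs_diff_um",
        ],
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    recording_means: Mapping[str, Sequence[float]], reference_line: str
) -> dict:
    """One-way ANOVA across lines, then pairwise Wilcoxon vs the reference.

    ``recording_means`` maps line id → per-recording mean distances (one
    value per recording).  The Wilcoxon rank-sum test is two-sided and exact
    (no tie/normal approximation) for the small per-line recording counts
    typical here; p-values are reported unadjusted, with significance stars
    at 0.05 / 0.01 / 0.001.  Lines with fewer than two recordings are
    excluded from the pairwise tests and listed in the report.
    """
    if reference_line not in recording_means:
        raise ValueError(f"reference line {reference_line!r} missing")
    groups = {k: np.asarray(v, dtype=float) for k, v in recording_means.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    anova_groups = [v for v in groups.values() if len(v) >= 2]
    if len(anova_groups) >= 2:
        f_stat, anova_p = stats.f_oneway(*anova_groups)
    else:
        f_stat, anova_p = float("nan"), float("nan")
    ref = groups[reference_line]
    pairwise = {}
    excluded = []
    for line, vals in groups.items():
        if line == reference_line:
            continue
        if len(vals) < 2 or len(ref) < 2:
            excluded.append(line)
            continue
        method = "exact" if (len(vals) <= 25 and len(ref) <= 25) else "auto"
        res = stats.mannwhitneyu(vals, ref, alternative="two-sided", method=method)
        pairwise[line] = {
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "stars": _stars(float(res.pvalue)),
            "n": len(vals),
            "n_reference": len(ref),
        }
    return {
        "anova": {"f_statistic": float(f_stat), "p_value": float(anova_p)},
        "reference_line": reference_line,
        "pairwise_wilcoxon": pairwise,
        "excluded_lines": excluded,
    }
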
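"""Reading and branching of particle-tracking output.

Tracking software (e.g. TrackMate with a StarDist detector and LAP linker)
emits a graph per track: spots (detections at one frame) joined by edges.
Because mitochondria fuse and divide, a track is in general a tree rather
than a chain.  For motility analysis each track graph is split into maximal
*linear* branches — the longest runs of spots in which every internal spot
has exactly one predecessor and one successor.  One branch is treated as one
mitochondrion discernible over the time-lapse.

Junction membership policy (fixed, so that spots partition disjointly):

* a *split* spot (out-degree > 1) belongs to the parent branch only; each
  child branch starts at its first post-junction spot;
* a *merge* spot (in-degree > 1) belongs to the downstream branch only; each
  incoming branch ends at its last pre-junction spot.

Coordinates are physical micrometres throughout, frames 0-based, times in
seconds taken from the file (never recomputed from the frame index), so that
gap-closed links keep their true duration and step speeds stay meaningful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Spot",
    "TrackGraph",
    "Branch",
    "BranchCollection",
    "read_trackmate_xml",
    "read_spots_csv",
    "split_branches",
    "SPOTS_COLUMN_ALIASES",
]


@dataclass(frozen=True)
class Spot:
    """A single detection: one particle in one frame."""

    spot_id: int
    track_id: int
    frame: int
    t: float
    position: tuple[float, ...]  # µm, 2 or 3 components
    quality: float | None = None

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"spot {self.spot_id}: non-finite position {self.position}")


@dataclass
class TrackGraph:
    """Spots plus directed (source → target) edges, grouped into tracks."""

    spots: dict[int, Spot]
    edges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for src, dst in self.edges:
            for sid in (src, dst):
                if sid not in self.spots:
                    raise ValueError(f"edge references unknown spot id {sid}")
            if self.spots[src].track_id != self.spots[dst].track_id:
                raise ValueError(
                    f"edge {src}->{dst} joins spots of different tracks "
                    f"({self.spots[src].track_id} vs {self.spots[dst].track_id})"
                )

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class Branch:
    """A time-ordered linear run of spots: one discernible mitochondrion.

    Derived kinematics (step vectors, speeds, path length, net displacement)
    are computed once from the spot sequence.
    """

    def __init__(self, branch_id: int, track_id: int, spots: Sequence[Spot]):
        if len(spots) < 2:
            raise ValueError("a branch needs at least 2 spots")
        frames = [s.frame for s in spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(f"branch {branch_id}: frames not strictly increasing")
        self.branch_id = branch_id
        self.track_id = track_id
        self.spots = list(spots)
        pos = np.asarray([s.position for s in spots], dtype=float)
        t = np.asarray([s.t for s in spots], dtype=float)
        self.positions = pos
        self.times = t
        self.step_vectors = np.diff(pos, axis=0)
        self.step_durations = np.diff(t)
        if np.any(self.step_durations <= 0):
            raise ValueError(f"branch {branch_id}: non-increasing times")
        step_lengths = np.linalg.norm(self.step_vectors, axis=1)
        self.step_lengths = step_lengths
        self.step_speeds = step_lengths / self.step_durations
        self.path_length = float(step_lengths.sum())
        self.net_displacement = pos[-1] - pos[0]
        self.duration = float(t[-1] - t[0])

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def net_distance(self) -> float:
        return float(np.linalg.norm(self.net_displacement))

    @property
    def max_step_speed(self) -> float:
        return float(self.step_speeds.max())

    @property
    def first_spot(self) -> Spot:
        return self.spots[0]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Branch(id={self.branch_id}, track={self.track_id}, "
            f"n_spots={self.n_spots}, path={self.path_length:.2f}um)"
        )


@dataclass
class BranchCollection:
    """Branches surviving the minimum-length filter plus a discard report."""

    branches: list[Branch]
    n_discarded: int = 0
    discarded_track_ids: list[int] = field(default_factory=list)

    def __iter__(self) -> Iterator[Branch]:
        return iter(self.branches)

    def __len__(self) -> int:
        return len(self.branches)

    def __getitem__(self, i):
        return self.branches[i]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

#: accepted header variants for the spots CSV, mapped to canonical names
SPOTS_COLUMN_ALIASES: Mapping[str, str] = {
    "TRACK_ID": "track_id",
    "track_id": "track_id",
    "track": "track_id",
    "SPOT_ID": "spot_id",
    "ID": "spot_id",
    "spot_id": "spot_id",
    "FRAME": "frame",
    "frame": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
    "POSITION_Z": "z",
    "x": "x",
    "y": "y",
    "z": "z",
    "X": "x",
    "Y": "y",
    "Z": "z",
    "POSITION_T": "t",
    "t": "t",
    "QUALITY": "quality",
    "quality": "quality",
}

_SPATIAL_FACTORS = {"micron": 1.0, "µm": 1.0, "um": 1.0, "micrometer": 1.0}
_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "second": 1.0, "seconds": 1.0, "ms": 1e-3, "min": 60.0}


def read_trackmate_xml(path: str | Path) -> TrackGraph:
    """Read a TrackMate XML file into a :class:`TrackGraph`.

    Positions are converted to µm and times to seconds using the units the
    file declares (``Model/@spatialunits``, ``Model/@timeunits``).  Pixel
    units require a ``Settings/ImageData`` calibration; a missing unit
    declaration is an error — pixels are never silently assumed.
    """
    tree = etree.parse(str(path))
    model = tree.find("Model")
    if model is None:
        raise ValueError(f"{path}: no <Model> element (not a TrackMate file?)")
    spatial = model.get("spatialunits")
    timeunits = model.get("timeunits")
    if not spatial:
        raise ValueError(f"{path}: missing spatialunits declaration")
    if not timeunits:
        raise ValueError(f"{path}: missing timeunits declaration")

    spatial = spatial.strip().lower()
    if spatial in _SPATIAL_FACTORS:
        sfac = _SPATIAL_FACTORS[spatial]
    elif spatial in {"pixel", "pixels", "px"}:
        image_data = tree.find("Settings/ImageData")
        if image_data is None or image_data.get("pixelwidth") is None:
            raise ValueError(
                f"{path}: positions declared in pixels but no "
                "Settings/ImageData pixelwidth calibration present"
            )
        sfac = float(image_data.get("pixelwidth"))
    else:
        raise ValueError(f"{path}: unsupported spatial unit {spatial!r}")
    tkey = timeunits.strip().lower()
    if tkey not in _TIME_FACTORS:
        raise ValueError(f"{path}: unsupported time unit {timeunits!r}")
    tfac = _TIME_FACTORS[tkey]

    raw_spots: dict[int, dict] = {}
    zvals: dict[int, float] = {}
    for el in model.iterfind("AllSpots/SpotsInFrame/Spot"):
        sid = int(el.get("ID"))
        pos = [float(el.get("POSITION_X")) * sfac, float(el.get("POSITION_Y")) * sfac]
        z = el.get("POSITION_Z")
        if z is not None:
            zvals[sid] = float(z) * sfac
        q = el.get("QUALITY")
        raw_spots[sid] = {
            "frame": int(el.get("FRAME")),
            "t": float(el.get("POSITION_T")) * tfac,
            "position": tuple(pos),
            "quality": float(q) if q is not None else None,
        }
    # TrackMate writes POSITION_Z=0 for planar data; keep z only if it varies
    if zvals and any(z != 0.0 for z in zvals.values()):
        for sid, rec in raw_spots.items():
            rec["position"] = rec["position"] + (zvals.get(sid, 0.0),)

    edges: list[tuple[int, int]] = []
    spot_track: dict[int, int] = {}
    for track in model.iterfind("AllTracks/Track"):
        tid = int(track.get("TRACK_ID"))
        for edge in track.iterfind("Edge"):
            src = int(edge.get("SPOT_SOURCE_ID"))
            dst = int(edge.get("SPOT_TARGET_ID"))
            for sid in (src, dst):
                if sid not in raw_spots:
                    raise ValueError(f"{path}: edge references unknown spot id {sid}")
                spot_track[sid] = tid
            edges.append((src, dst))

    spots = {}
    for sid, rec in raw_spots.items():
        # spots outside every track become singleton tracks keyed by spot id,
        # offset past the real track ids to avoid collision
        tid = spot_track.get(sid, sid + max(spot_track.values(), default=0) + 1)
        spots[sid] = Spot(spot_id=sid, track_id=tid, **rec)
    return TrackGraph(spots=spots, edges=edges)


def read_spots_csv(
    spots_path: str | Path | io.IOBase,
    edges_path: str | Path | io.IOBase | None = None,
) -> TrackGraph:
    """Read spots (and optionally edges) CSV into a :class:`TrackGraph`.

    Without an edges file, consecutive-frame linking is inferred within each
    track: spots are sorted by frame and chained; a duplicate (track, frame)
    pair is then ambiguous and raises.  Header variants are accepted per
    :data:`SPOTS_COLUMN_ALIASES`.  Positions must already be in µm and times
    in seconds.
    """
    df = pd.read_csv(spots_path)
    rename = {c: SPOTS_COLUMN_ALIASES[c] for c in df.columns if c in SPOTS_COLUMN_ALIASES}
    df = df.rename(columns=rename)
    required = {"track_id", "spot_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spots CSV missing required columns: {sorted(missing)}")
    for col in ("x", "y") + (("z",) if "z" in df.columns else ()):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric coordinate in column {col!r} at row {row}")
        df[col] = vals
    if "t" not in df.columns:
        raise ValueError("spots CSV missing time column (POSITION_T / t)")

    dims = ["x", "y"] + (["z"] if "z" in df.columns else [])
    spots: dict[int, Spot] = {}
    for rec in df.itertuples(index=False):
        sid = int(rec.spot_id)
        if sid in spots:
            raise ValueError(f"duplicate spot id {sid}")
        spots[sid] = Spot(
            spot_id=sid,
            track_id=int(rec.track_id),
            frame=int(rec.frame),
            t=float(rec.t),
            position=tuple(float(getattr(rec, d)) for d in dims),
            quality=float(rec.quality) if "quality" in df.columns else None,
        )

    if edges_path is not None:
        edf = pd.read_csv(edges_path)
        ecols = {c.upper(): c for c in edf.columns}
        try:
            src_c = ecols["SPOT_SOURCE_ID"]
            dst_c = ecols["SPOT_TARGET_ID"]
        except KeyError as exc:
            raise ValueError("edges CSV needs SPOT_SOURCE_ID and SPOT_TARGET_ID") from exc
        edges = [(int(s), int(d)) for s, d in zip(edf[src_c], edf[dst_c])]
    else:
        edges = []
        for tid, grp in df.groupby("track_id", sort=False):
            if grp["frame"].duplicated().any():
                f = int(grp["frame"][grp["frame"].duplicated()].iloc[0])
                raise ValueError(
                    f"track {tid}: duplicate frame {f} but no edges file; "
                    "linking is ambiguous"
                )
            ordered = grp.sort_values("frame")["spot_id"].astype(int).tolist()
            edges.extend(zip(ordered, ordered[1:]))
    return TrackGraph(spots=spots, edges=edges)


# ---------------------------------------------------------------------------
# branch splitting
# ---------------------------------------------------------------------------


def split_branches(graph: TrackGraph, min_spots: int = 5) -> BranchCollection:
    """Split every track graph into maximal linear branches.

    Branches shorter than ``min_spots`` are discarded and counted in the
    returned report.  A cyclic graph is an error.
    """
    succ: dict[int, list[int]] = {sid: [] for sid in graph.spots}
    pred: dict[int, list[int]] = {sid: [] for sid in graph.spots}
    for src, dst in graph.edges:
        succ[src].append(dst)
        pred[dst].append(src)

    def is_start(sid: int) -> bool:
        np_ = len(pred[sid])
        if np_ == 0 or np_ > 1:  # chain head, or merge spot (downstream branch)
            return True
        return len(succ[pred[sid][0]]) > 1  # first spot after a split

    branch_seqs: list[list[int]] = []
    visited: set[int] = set()
    for sid in graph.spots:
        if not is_start(sid):
            continue
        seq = [sid]
        visited.add(sid)
        cur = sid
        while len(succ[cur]) == 1:
            nxt = succ[cur][0]
            if len(pred[nxt]) > 1:  # merge spot starts its own branch
                break
            if nxt in visited:
                raise ValueError("cyclic track graph")
            seq.append(nxt)
            visited.add(nxt)
            cur = nxt
            if len(succ[cur]) > 1:  # split spot belongs to the parent; stop
                break
        branch_seqs.append(seq)
    if len(visited) != len(graph.spots):
        # nodes never reached from any start spot can only lie on a cycle
        raise ValueError("cyclic track graph")

    branches: list[Branch] = []
    n_discarded = 0
    discarded_tracks: list[int] = []
    bid = 0
    for seq in branch_seqs:
        spots = sorted((graph.spots[s] for s in seq), key=lambda s: s.frame)
        if len(spots) < max(min_spots, 2):
            n_discarded += 1
            discarded_tracks.append(spots[0].track_id)
            continue
        branches.append(Branch(branch_id=bid, track_id=spots[0].track_id, spots=spots))
        bid += 1
    return BranchCollection(branches, n_discarded, discarded_tracks)


def write_spots_csv(
    spots: pd.DataFrame, edges: pd.DataFrame, spots_path: str | Path, edges_path: str | Path
) -> None:
    """Write TrackMate-style spots and edges tables to CSV."""
    spots.to_csv(spots_path, index=False)
    edges.to_csv(edges_path, index=False)
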
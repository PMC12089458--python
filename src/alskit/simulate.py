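"""Seeded generators for every input the pipeline consumes.

Each generator emulates the *output* of an upstream tool with known ground
truth, so every downstream stage is testable without the study's deposited
data:

``simulate_tracks``
    Detected-spot tables in TrackMate CSV form.  Motile mitochondria drift
    along ±axis at a per-branch speed drawn from a Gaussian, sampled at
    0.5 Hz (2 s frame interval) over 180 frames (~6 min) with isotropic
    positional noise; stationary mitochondria jitter around a fixed point.
    Tracks are linear chains by default (no fusion/fission) so the
    ground-truth class of every branch is unambiguous; optional reversal
    and split probabilities exist for stress tests.

``simulate_expression``
    A genes × cells RPKM matrix with lognormal marker expression per cell
    class, optional dropout, and per-cell QC metadata — targeting the
    marker-threshold decision tree.

``simulate_gene_sets``
    2–4 named directional sets realizing exactly prescribed Venn-region
    cardinalities over a universe.

``simulate_cases``
    A case-report table with group-wise Gaussian onset (years) and disease
    duration (months), truncated at zero, with optional missingness.  The
    default configuration encodes the published group statistics of the
    ALS-FUS case-report literature (P525L onset 21 ± 8 y, duration
    17 ± 10 mo; R495X 31 ± 11 y, 20 ± 18 mo; other mutations 41 ± 18 y;
    502 cases in total) and is a synthetic stand-in for that aggregated
    table, not the table itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from alskit.celltyper import ClassifierThresholds
from alskit.setcompare import DirectionalSetCollection, region_label

__all__ = [
    "TrackSimConfig",
    "ExprSimConfig",
    "SetSimConfig",
    "CaseSimConfig",
    "simulate_tracks",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_cases",
    "default_expr_config",
    "default_case_config",
]

TRACK_CLASSES = ("stationary", "anterograde", "retrograde", "orthogonal")


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"axis must be a unit vector (norm {n})")
    return v


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


@dataclass
class TrackSimConfig:
    """Study conditions for the trajectory simulator.

    The sampling rate (0.5 Hz) and recording length (~6 min) follow the
    imaging protocol the analysis targets; speeds are in the range reported
    for fast axonal transport of mitochondria (~0.3–0.5 µm/s).  The
    stationary jitter sd of 0.01 µm keeps every jitter step below the
    0.05 µm/s speed threshold with overwhelming probability, so simulated
    class labels are unambiguous ground truth.
    """

    n_branches_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"stationary": 1200, "anterograde": 400, "retrograde": 400}
    )
    frame_interval_s: float = 2.0  # 0.5 Hz
    n_frames: int = 180  # ~6 min
    axis: tuple[float, ...] = (1.0, 0.0)
    speed_mean_um_s: Mapping[str, float] = field(
        default_factory=lambda: {"anterograde": 0.4, "retrograde": 0.4, "orthogonal": 0.4}
    )
    speed_sd_um_s: Mapping[str, float] = field(
        default_factory=lambda: {"anterograde": 0.1, "retrograde": 0.1, "orthogonal": 0.1}
    )
    stationary_jitter_sd_um: float = 0.01
    positional_noise_sd_um: float = 0.02
    field_extent_um: float = 100.0
    reversal_prob: float = 0.0  # per-step direction flip (stress tests only)
    split_prob: float = 0.0  # per-track probability of one fork (stress tests)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        for cls, n in self.n_branches_per_class.items():
            if cls not in TRACK_CLASSES:
                raise ValueError(f"unknown track class {cls!r}")
            if n < 0:
                raise ValueError("branch counts must be non-negative")
        _unit(self.axis)


def _orthonormal(axis: np.ndarray) -> np.ndarray:
    """Any unit vector orthogonal to the axis (2D or 3D)."""
    if len(axis) == 2:
        return np.array([-axis[1], axis[0]])
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(axis, helper)
    return v / np.linalg.norm(v)


def simulate_tracks(
    config: TrackSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate detected spots with ground-truth motility classes.

    Returns (spots, edges, truth): TrackMate-style spot and edge tables
    plus one truth row per simulated branch (track_id, true_class,
    true_speed_um_s).
    """
    rng = np.random.default_rng(config.seed)
    axis = _unit(config.axis)
    dim = len(axis)
    ortho = _orthonormal(axis)
    dt = config.frame_interval_s
    t_grid = np.arange(config.n_frames) * dt

    spot_cols = ["TRACK_ID", "SPOT_ID", "FRAME", "POSITION_X", "POSITION_Y"]
    if dim == 3:
        spot_cols.append("POSITION_Z")
    spot_cols.append("POSITION_T")

    spots_rows: list[tuple] = []
    edges_rows: list[tuple[int, int]] = []
    truth_rows: list[dict] = []
    spot_id = 0
    track_id = 0

    def emit_chain(positions: np.ndarray, tid: int) -> list[int]:
        nonlocal spot_id
        ids = []
        for f, p in enumerate(positions):
            row = (tid, spot_id, f, *np.round(p, 6), t_grid[f])
            spots_rows.append(row)
            ids.append(spot_id)
            spot_id += 1
        edges_rows.extend(zip(ids, ids[1:]))
        return ids

    for cls in TRACK_CLASSES:
        n = config.n_branches_per_class.get(cls, 0)
        for _ in range(n):
            start = rng.uniform(0.0, config.field_extent_um, size=dim)
            if cls == "stationary":
                pos = start + rng.normal(
                    0.0, config.stationary_jitter_sd_um, size=(config.n_frames, dim)
                )
                speed = 0.0
            else:
                direction = {
                    "anterograde": axis,
                    "retrograde": -axis,
                    "orthogonal": ortho,
                }[cls]
                speed = max(
                    rng.normal(config.speed_mean_um_s[cls], config.speed_sd_um_s[cls]), 0.05
                )
                if config.reversal_prob > 0:
                    signs = np.ones(config.n_frames - 1)
                    flips = rng.random(config.n_frames - 1) < config.reversal_prob
                    sign = 1.0
                    for k in range(config.n_frames - 1):
                        if flips[k]:
                            sign = -sign
                        signs[k] = sign
                    steps = np.outer(signs * speed * dt, direction)
                    drift = np.vstack([np.zeros(dim), np.cumsum(steps, axis=0)])
                else:
                    drift = np.outer(t_grid, direction * speed)
                noise = rng.normal(
                    0.0, config.positional_noise_sd_um, size=(config.n_frames, dim)
                )
                pos = start + drift + noise
            ids = emit_chain(pos, track_id)
            if config.split_prob > 0 and rng.random() < config.split_prob:
                # fork: a sibling chain budding off mid-track (shares one spot)
                k = int(rng.integers(config.n_frames // 3, 2 * config.n_frames // 3))
                branch_pos = pos[k] + np.cumsum(
                    rng.normal(0.0, config.stationary_jitter_sd_um, size=(config.n_frames - k - 1, dim)),
                    axis=0,
                )
                nonlocal_ids = []
                for off, p in enumerate(branch_pos, start=k + 1):
                    spots_rows.append((track_id, spot_id, off, *np.round(p, 6), t_grid[off]))
                    nonlocal_ids.append(spot_id)
                    spot_id += 1
                if nonlocal_ids:
                    edges_rows.append((ids[k], nonlocal_ids[0]))
                    edges_rows.extend(zip(nonlocal_ids, nonlocal_ids[1:]))
            truth_rows.append(
                {"track_id": track_id, "true_class": cls, "true_speed_um_s": speed}
            )
            track_id += 1

    spots = pd.DataFrame(spots_rows, columns=spot_cols)
    edges = pd.DataFrame(edges_rows, columns=["SPOT_SOURCE_ID", "SPOT_TARGET_ID"])
    truth = pd.DataFrame(truth_rows, columns=["track_id", "true_class", "true_speed_um_s"])
    return spots, edges, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

#: log-RPKM means per cell class for the genes the decision tree reads, plus
#: the descriptive progenitor/proliferation markers.  Values put each class
#: at least tenfold away from every threshold it must clear or stay under.
_HI, _LO = math.log(1000.0), math.log(0.01)
_DEFAULT_MARKER_MEANS: dict[str, dict[str, float]] = {
    "motor_neuron": {
        "NEFM": _HI, "SNAP25": math.log(100.0),
        "ISL1": math.log(50.0), "ISL2": math.log(20.0), "MNX1": math.log(30.0),
        "SLC18A3": math.log(50.0), "SLC5A7": math.log(50.0),
        "VSX2": _LO, "SIM1": _LO, "SOX14": _LO,
        "SOX2": _LO, "MKI67": _LO, "CDK1": _LO,
    },
    "v2a_interneuron": {
        "NEFM": _HI, "SNAP25": math.log(100.0),
        "ISL1": _LO, "ISL2": _LO, "MNX1": _LO,
        "SLC18A3": _LO, "SLC5A7": _LO,
        "VSX2": math.log(30.0), "SOX14": math.log(20.0), "SIM1": _LO,
        "SOX2": _LO, "MKI67": _LO, "CDK1": _LO,
    },
    "other_interneuron": {
        "NEFM": _HI, "SNAP25": math.log(100.0),
        "ISL1": _LO, "ISL2": _LO, "MNX1": _LO,
        "SLC18A3": _LO, "SLC5A7": _LO,
        "VSX2": _LO, "SOX14": _LO, "SIM1": math.log(20.0),
        "SOX2": _LO, "MKI67": _LO, "CDK1": _LO,
    },
    "progenitor": {
        "NEFM": math.log(1.0), "SNAP25": math.log(0.5),
        "ISL1": _LO, "ISL2": _LO, "MNX1": _LO,
        "SLC18A3": _LO, "SLC5A7": _LO,
        "VSX2": _LO, "SOX14": _LO, "SIM1": _LO,
        "SOX2": math.log(100.0), "MKI67": _LO, "CDK1": _LO,
    },
    "proliferating": {
        "NEFM": math.log(1.0), "SNAP25": math.log(0.5),
        "ISL1": _LO, "ISL2": _LO, "MNX1": _LO,
        "SLC18A3": _LO, "SLC5A7": _LO,
        "VSX2": _LO, "SOX14": _LO, "SIM1": _LO,
        "SOX2": math.log(50.0), "MKI67": math.log(100.0), "CDK1": math.log(100.0),
    },
}

#: the label the decision tree should produce for each simulated class
EXPECTED_LABELS: dict[str, str] = {
    "motor_neuron": "motor_neuron",
    "v2a_interneuron": "v2a_interneuron",
    "other_interneuron": "other_interneuron",
    "progenitor": "non_neuronal",
    "proliferating": "non_neuronal",
}


@dataclass
class ExprSimConfig:
    """Parameters of the single-cell RPKM simulator (log-RPKM scale)."""

    n_cells_per_class: Mapping[str, int] = field(
        default_factory=lambda: {k: 60 for k in _DEFAULT_MARKER_MEANS}
    )
    marker_log_mean: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MARKER_MEANS.items()}
    )
    marker_log_sd: float | Mapping[str, Mapping[str, float]] = 0.3
    dropout_prob: float | Mapping[str, Mapping[str, float]] = 0.0
    n_background_genes: int = 200
    background_log_mean: float = 0.0
    background_log_sd: float = 1.0
    qc_reads_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {k: (200_000, 2_000_000) for k in _DEFAULT_MARKER_MEANS}
    )
    qc_genes_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {k: (6_000, 9_000) for k in _DEFAULT_MARKER_MEANS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.n_cells_per_class.items():
            if n < 0:
                raise ValueError("cell counts must be non-negative")
            if n > 0 and label not in self.marker_log_mean:
                raise ValueError(f"no marker parameters for class {label!r}")
        for label, markers in self.marker_log_mean.items():
            for g in markers:
                p = self._dropout(label, g)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"dropout probability out of [0,1] for ({label}, {g})")

    def _per_marker(self, value, label: str, gene: str, default: float) -> float:
        if isinstance(value, Mapping):
            return float(value.get(label, {}).get(gene, default))
        return float(value)

    def _sd(self, label: str, gene: str) -> float:
        return self._per_marker(self.marker_log_sd, label, gene, 0.3)

    def _dropout(self, label: str, gene: str) -> float:
        return self._per_marker(self.dropout_prob, label, gene, 0.0)


def default_expr_config(**overrides) -> ExprSimConfig:
    """The default five-class configuration, optionally tweaked."""
    return ExprSimConfig(**overrides)


def simulate_expression(
    config: ExprSimConfig,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate an RPKM matrix, true class labels and per-cell QC metadata.

    Every marker gene the decision tree reads must have parameters for every
    simulated class; a missing one is an error naming the gene.
    """
    for label, n in config.n_cells_per_class.items():
        if n == 0:
            continue
        for g in thresholds.marker_genes():
            if g not in config.marker_log_mean[label]:
                raise ValueError(
                    f"classifier marker gene {g!r} missing from simulation "
                    f"parameters for class {label!r}"
                )
    rng = np.random.default_rng(config.seed)
    marker_genes = list(
        dict.fromkeys(g for m in config.marker_log_mean.values() for g in m)
    )
    bg_genes = [f"BG{i:05d}" for i in range(config.n_background_genes)]
    genes = marker_genes + bg_genes

    columns, labels, qc_rows = [], [], []
    data = []
    for label in sorted(config.n_cells_per_class):
        n = config.n_cells_per_class[label]
        for i in range(n):
            cell_id = f"{label}_{i:04d}"
            vec = np.empty(len(genes))
            for gi, g in enumerate(marker_genes):
                mu = config.marker_log_mean[label].get(g, config.background_log_mean)
                x = math.exp(rng.normal(mu, config._sd(label, g)))
                if rng.random() < config._dropout(label, g):
                    x = 0.0
                vec[gi] = x
            vec[len(marker_genes):] = np.exp(
                rng.normal(config.background_log_mean, config.background_log_sd, len(bg_genes))
            )
            data.append(vec)
            columns.append(cell_id)
            labels.append(label)
            lo_r, hi_r = config.qc_reads_range[label]
            lo_g, hi_g = config.qc_genes_range[label]
            qc_rows.append(
                {
                    "cell_id": cell_id,
                    "uniquely_mapped_reads": int(rng.integers(lo_r, hi_r + 1)),
                    "detected_genes": int(rng.integers(lo_g, hi_g + 1)),
                    "line_id": "simline",
                }
            )
    if columns:
        rpkm = pd.DataFrame(np.array(data).T, index=genes, columns=columns)
    else:
        rpkm = pd.DataFrame(index=pd.Index(genes), columns=pd.Index([], dtype=object), dtype=float)
    truth = pd.Series(labels, index=pd.Index(columns, name="cell_id"), name="true_class")
    qc = pd.DataFrame(qc_rows, columns=["cell_id", "uniquely_mapped_reads", "detected_genes", "line_id"])
    qc = qc.set_index("cell_id") if len(qc) else qc
    return rpkm, truth, qc


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass
class SetSimConfig:
    """Venn-region cardinalities to realize over a universe of ids.

    ``region_cardinalities`` is keyed by '&'-joined set-name signatures,
    e.g. ``{"A": 2, "B": 3, "A&B": 1}``.
    """

    universe_size: int
    region_cardinalities: Mapping[str, int]
    direction_split: Mapping[str, float] | float = 0.5  # P(up) per set
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.region_cardinalities.values()):
            raise ValueError("region cardinalities must be non-negative")
        total = sum(self.region_cardinalities.values())
        if total > self.universe_size:
            raise ValueError(
                f"region cardinalities sum to {total} > universe size {self.universe_size}"
            )
        if isinstance(self.direction_split, Mapping):
            fracs = self.direction_split.values()
        else:
            fracs = [self.direction_split]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("direction_split fractions must be in [0, 1]")

    @property
    def set_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for sig in self.region_cardinalities:
            for n in sig.split("&"):
                if n not in names:
                    names.append(n)
        if not 1 <= len(names) <= 4:
            raise ValueError("between 1 and 4 set names supported")
        return tuple(names)


def simulate_gene_sets(config: SetSimConfig) -> DirectionalSetCollection:
    """Realize directional sets with exactly the prescribed Venn regions."""
    rng = np.random.default_rng(config.seed)
    width = max(6, len(str(config.universe_size)))
    universe = [f"g{i:0{width}d}" for i in range(config.universe_size)]
    pool = list(rng.permutation(universe))
    names = config.set_names
    sets: dict[str, dict[str, str]] = {n: {} for n in names}

    def p_up(name: str) -> float:
        if isinstance(config.direction_split, Mapping):
            return float(config.direction_split.get(name, 0.5))
        return float(config.direction_split)

    for sig, count in config.region_cardinalities.items():
        members_of = [n for n in sig.split("&")]
        for n in members_of:
            if n not in sets:
                raise ValueError(f"region {sig!r} names unknown set {n!r}")
        canonical = region_label(members_of)
        if canonical != sig and canonical in config.region_cardinalities:
            raise ValueError(f"duplicate region signature {sig!r} / {canonical!r}")
        taken, pool_rest = pool[:count], pool[count:]
        pool = pool_rest
        for item in taken:
            for n in members_of:
                sets[n][item] = "up" if rng.random() < p_up(n) else "down"
    return DirectionalSetCollection(sets=sets, universe=frozenset(universe))


# ---------------------------------------------------------------------------
# case reports
# ---------------------------------------------------------------------------


@dataclass
class CaseSimConfig:
    """Group-wise Gaussian onset/duration parameters for case simulation."""

    n_per_mutation: Mapping[str, int]
    onset_mean_y: Mapping[str, float]
    onset_sd_y: Mapping[str, float]
    duration_mean_mo: Mapping[str, float]
    duration_sd_mo: Mapping[str, float]
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_mutation.values()):
            raise ValueError("counts must be non-negative")
        for m in (self.onset_sd_y, self.duration_sd_mo):
            if any(sd < 0 for sd in m.values()):
                raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")


def default_case_config(seed: int = 0) -> CaseSimConfig:
    """Synthetic stand-in for the aggregated ALS-FUS case-report table.

    Encodes the published per-mutation statistics — P525L: onset 21 ± 8 y,
    duration 17 ± 10 mo; R495X: 31 ± 11 y, 20 ± 18 mo; other mutations:
    41 ± 18 y (duration more variable, 60 ± 40 mo chosen as a realistic
    slower progression) — with group sizes summing to the 502 aggregated
    cases.
    """
    return CaseSimConfig(
        n_per_mutation={"P525L": 120, "R495X": 60, "other": 322},
        onset_mean_y={"P525L": 21.0, "R495X": 31.0, "other": 41.0},
        onset_sd_y={"P525L": 8.0, "R495X": 11.0, "other": 18.0},
        duration_mean_mo={"P525L": 17.0, "R495X": 20.0, "other": 60.0},
        duration_sd_mo={"P525L": 10.0, "R495X": 18.0, "other": 40.0},
        seed=seed,
    )


def simulate_cases(config: CaseSimConfig) -> pd.DataFrame:
    """Simulate a case-report table (one row per case)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    case = 0
    for mutation in config.n_per_mutation:
        n = config.n_per_mutation[mutation]
        onset = np.clip(
            rng.normal(config.onset_mean_y[mutation], config.onset_sd_y[mutation], n), 0, None
        )
        dur = np.clip(
            rng.normal(config.duration_mean_mo[mutation], config.duration_sd_mo[mutation], n),
            0,
            None,
        )
        endpoints = rng.choice(
            ["respiratory_failure", "tracheostomy", "death"], size=n, p=[0.3, 0.1, 0.6]
        )
        for i in range(n):
            rows.append(
                {
                    "case_id": f"case{case:04d}",
                    "mutation": mutation,
                    "onset_age_y": float(onset[i]),
                    "duration_mo": float(dur[i]),
                    "endpoint_type": endpoints[i],
                    "censored": False,
                    "source_id": f"synthetic:{mutation}",
                }
            )
            case += 1
    columns = [
        "case_id", "mutation", "onset_age_y", "duration_mo", "endpoint_type", "censored", "source_id",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if config.missing_fraction > 0 and len(df):
        for col in ("onset_age_y", "duration_mo"):
            mask = rng.random(len(df)) < config.missing_fraction
            df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_expression_tsv(rpkm: pd.DataFrame, qc: pd.DataFrame, path, qc_path) -> None:
    """Write a genes × cells TSV plus QC sidecar."""
    rpkm.to_csv(path, sep="\t", index_label="gene")
    qc.reset_index().to_csv(qc_path, sep="\t", index=False)


def write_expression_mtx(rpkm: pd.DataFrame, prefix) -> None:
    """Write MatrixMarket triplets with gene/cell name sidecars."""
    from scipy import io as spio
    from scipy.sparse import csr_matrix

    spio.mmwrite(f"{prefix}.mtx", csr_matrix(rpkm.to_numpy()))
    with open(f"{prefix}.genes.txt", "w") as fh:
        fh.write("\n".join(map(str, rpkm.index)) + "\n")
    with open(f"{prefix}.cells.txt", "w") as fh:
        fh.write("\n".join(map(str, rpkm.columns)) + "\n")
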
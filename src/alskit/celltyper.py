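"""QC filtering and marker-threshold cell typing of single-cell RPKM data.

Cells are first filtered on mapping depth and library complexity: a cell is
excluded when it has fewer than 100,000 uniquely mapped reads or fewer than
5,000 detected genes (a gene counts as detected at RPKM > 1).  Passing cells
run through a fixed decision tree on HGNC marker symbols, all comparisons
strict exactly as stated:

1. *neuron* iff NEFM > 100 RPKM and SNAP25 > 10 RPKM; otherwise
   *non-neuronal* (progenitor/proliferating cells are not subdivided — the
   tree defines no thresholds for them);
2. a neuron is a *motor neuron* iff at least one of the transcription
   factors ISL1, ISL2, MNX1 exceeds 1 RPKM, combined with a cholinergic
   transporter (SLC18A3 (VAChT) or SLC5A7 (ChT)) above 5 RPKM, while the
   interneuron markers VSX2 and SIM1 both stay below 1 RPKM;
3. a remaining neuron is a *V2a interneuron* iff both VSX2 (CHX10) and
   SOX14 exceed 1 RPKM;
4. every other neuron is an *other interneuron*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellLabel",
    "ClassifierThresholds",
    "ExpressionMatrix",
    "qc_filter",
    "classify_cell",
    "classify_matrix",
    "DEFAULT_ALIASES",
]

#: common alternative symbols mapped to the HGNC names the tree uses
DEFAULT_ALIASES: Mapping[str, str] = {
    "VACHT": "SLC18A3",
    "CHT": "SLC5A7",
    "CHX10": "VSX2",
    "HB9": "MNX1",
}


class CellLabel(enum.Enum):
    MOTOR_NEURON = "motor_neuron"
    V2A_INTERNEURON = "v2a_interneuron"
    OTHER_INTERNEURON = "other_interneuron"
    NON_NEURONAL = "non_neuronal"


@dataclass(frozen=True)
class ClassifierThresholds:
    """All cut-offs of the QC filter and the decision tree (RPKM unless noted)."""

    qc_min_reads: int = 100_000
    qc_min_genes: int = 5_000
    detect_rpkm: float = 1.0
    nefm_min: float = 100.0
    snap25_min: float = 10.0
    mn_tf_genes: tuple[str, ...] = ("ISL1", "ISL2", "MNX1")
    mn_tf_min: float = 1.0
    mn_cholinergic_genes: tuple[str, ...] = ("SLC18A3", "SLC5A7")
    mn_cholinergic_min: float = 5.0
    mn_exclusion_genes: tuple[str, ...] = ("VSX2", "SIM1")
    mn_exclusion_max: float = 1.0
    v2a_genes: tuple[str, ...] = ("VSX2", "SOX14")
    v2a_min: float = 1.0

    def marker_genes(self) -> tuple[str, ...]:
        return tuple(
            dict.fromkeys(
                ("NEFM", "SNAP25")
                + self.mn_tf_genes
                + self.mn_cholinergic_genes
                + self.mn_exclusion_genes
                + self.v2a_genes
            )
        )


@dataclass
class ExpressionMatrix:
    """Genes × cells RPKM matrix plus per-cell QC metadata.

    ``qc`` is indexed by cell id with a ``uniquely_mapped_reads`` column and
    optionally ``detected_genes`` (derived from the matrix when absent) and
    ``line_id``.
    """

    rpkm: pd.DataFrame
    qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.rpkm.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.rpkm.columns.duplicated().any():
            raise ValueError("duplicate cell ids")
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("negative RPKM values")

    @property
    def genes(self) -> pd.Index:
        return self.rpkm.index

    @property
    def cells(self) -> pd.Index:
        return self.rpkm.columns

    def detected_genes(self, detect_rpkm: float = 1.0) -> pd.Series:
        """Detected-gene count per cell (strict RPKM > threshold)."""
        return (self.rpkm > detect_rpkm).sum(axis=0)

    def with_aliases(self, aliases: Mapping[str, str] = DEFAULT_ALIASES) -> "ExpressionMatrix":
        """Rename rows whose symbol is a known alias of a tree marker."""
        renamed = self.rpkm.rename(index=dict(aliases))
        return ExpressionMatrix(rpkm=renamed, qc=self.qc)


def qc_filter(
    matrix: ExpressionMatrix,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    allow_missing_reads: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the read-depth / library-complexity filter.

    Returns the passing cell ids and a per-cell report with the exclusion
    reason(s).  A matrix without read counts is an error unless
    ``allow_missing_reads`` is set (then only the detected-genes rule runs).
    """
    cells = matrix.cells
    if matrix.qc is not None and "detected_genes" in matrix.qc.columns:
        detected = matrix.qc["detected_genes"].reindex(cells)
    else:
        detected = matrix.detected_genes(thresholds.detect_rpkm)
    if matrix.qc is not None and "uniquely_mapped_reads" in matrix.qc.columns:
        reads = matrix.qc["uniquely_mapped_reads"].reindex(cells)
    elif allow_missing_reads:
        reads = pd.Series(np.inf, index=cells)
    else:
        raise ValueError(
            "uniquely_mapped_reads missing from QC metadata; "
            "pass allow_missing_reads=True to filter on detected genes only"
        )
    low_reads = reads < thresholds.qc_min_reads
    low_genes = detected < thresholds.qc_min_genes
    report = pd.DataFrame(
        {
            "uniquely_mapped_reads": reads,
            "detected_genes": detected,
            "fail_reads": low_reads,
            "fail_genes": low_genes,
            "passed": ~(low_reads | low_genes),
        }
    )
    return list(cells[report["passed"]]), report


def _require(values: pd.Series, genes: Sequence[str]) -> None:
    for g in genes:
        if g not in values.index:
            raise KeyError(f"marker gene {g!r} missing from expression vector")
        if pd.isna(values[g]):
            raise ValueError(f"marker gene {g!r} has missing (NaN) expression")


def classify_cell(
    rpkm: pd.Series, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> CellLabel:
    """Run the decision tree on one cell's RPKM vector."""
    t = thresholds
    _require(rpkm, ("NEFM", "SNAP25"))
    if not (rpkm["NEFM"] > t.nefm_min and rpkm["SNAP25"] > t.snap25_min):
        return CellLabel.NON_NEURONAL
    _require(rpkm, t.mn_tf_genes + t.mn_cholinergic_genes + t.mn_exclusion_genes + t.v2a_genes)
    mn_tf = any(rpkm[g] > t.mn_tf_min for g in t.mn_tf_genes)
    mn_chol = any(rpkm[g] > t.mn_cholinergic_min for g in t.mn_cholinergic_genes)
    mn_excl = all(rpkm[g] < t.mn_exclusion_max for g in t.mn_exclusion_genes)
    if mn_tf and mn_chol and mn_excl:
        return CellLabel.MOTOR_NEURON
    if all(rpkm[g] > t.v2a_min for g in t.v2a_genes):
        return CellLabel.V2A_INTERNEURON
    return CellLabel.OTHER_INTERNEURON


def classify_matrix(
    matrix: ExpressionMatrix,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    cells: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every (passing) cell and summarize composition per line.

    ``cells`` restricts classification, normally to the QC-passing ids.
    Returns (labels table, composition table).  Line ids come from the QC
    metadata when present, else a single pseudo-line ``"all"``.
    """
    ids = list(cells) if cells is not None else list(matrix.cells)
    if matrix.qc is not None and "line_id" in matrix.qc.columns:
        lines = matrix.qc["line_id"].reindex(ids)
    else:
        lines = pd.Series("all", index=pd.Index(ids))
    labels = [classify_cell(matrix.rpkm[c], thresholds).value for c in ids]
    table = pd.DataFrame({"cell_id": ids, "line_id": lines.to_numpy(), "label": labels})
    if table.empty:
        comp = pd.DataFrame(columns=["line_id", "label", "n", "proportion"])
    else:
        comp = (
            table.groupby(["line_id", "label"], sort=True).size().rename("n").reset_index()
        )
        comp["proportion"] = comp["n"] / comp.groupby("line_id")["n"].transform("sum")
    return table, comp


def read_rpkm_tsv(path, qc_path=None) -> ExpressionMatrix:
    """Read a genes × cells RPKM TSV (and optional QC TSV keyed by cell_id)."""
    rpkm = pd.read_csv(path, sep="\t", index_col=0)
    qc = None
    if qc_path is not None:
        qc = pd.read_csv(qc_path, sep="\t").set_index("cell_id")
    return ExpressionMatrix(rpkm=rpkm, qc=qc)
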
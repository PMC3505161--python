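"""Count-matrix and lane-annotation containers with TSV round-trip IO.

The analysis endpoint is total reads (counts) per gene.  Counts arrive as a
genes x lanes table together with a lane annotation table describing the
experimental layout (subject, response group, flow cell, lane, lane-pair
position, library-prep batch, software version, technical-replicate index).
Technical-replicate lanes of a specimen are summed into subject-level counts
before biological-variation modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns every lane annotation table must carry
DESIGN_COLUMNS = [
    "lane_id",
    "subject_id",
    "group",
    "flowcell_id",
    "lane_number",
    "lane_pair_id",
    "batch_id",
    "software_version",
    "tech_rep_index",
    "status",
]


@dataclass
class CountMatrix:
    """Genes x samples table of non-negative integer counts."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {name} identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.index.to_numpy(), np.asarray(frame.columns, dtype=object),
                   frame.to_numpy())


@dataclass
class LaneDesign:
    """Per-lane experimental metadata.

    Wraps a DataFrame with the :data:`DESIGN_COLUMNS`; ``status`` is ``"ok"``
    for analysable lanes and a short reason (``"failed"``, ``"excluded"``)
    otherwise, mirroring the study's exclusion flow.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"lane design table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        ok = self.ok()
        per_fc = ok.groupby("subject_id")["flowcell_id"].nunique()
        if (per_fc > 1).any():
            bad = per_fc[per_fc > 1].index.tolist()
            raise ValueError(f"subjects on more than one flow cell: {bad}")
        per_subj = ok.groupby("subject_id").size()
        if (per_subj > 2).any():
            bad = per_subj[per_subj > 2].index.tolist()
            raise ValueError(f"subjects with more than 2 technical-replicate lanes: {bad}")

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "ok"]

    @property
    def lane_ids(self) -> np.ndarray:
        return self.table["lane_id"].to_numpy()

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.ok()["subject_id"]))


def read_counts(path) -> CountMatrix:
    """Read a gene x sample count TSV (header = sample ids, col 1 = gene ids)."""
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: no header")
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    arr = frame.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells present")
    if arr.size and not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: non-integer counts present")
    try:
        return CountMatrix(frame.index.to_numpy(), np.asarray(frame.columns, dtype=object),
                           arr.astype(np.int64) if arr.size else arr.reshape(frame.shape))
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def write_counts(matrix: CountMatrix, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t")


def read_design(path) -> LaneDesign:
    return LaneDesign(pd.read_csv(path, sep="\t", comment="#"))


def write_design(design: LaneDesign, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        design.table.to_csv(fh, sep="\t", index=False)


def sum_lane_pairs(matrix: CountMatrix, design: LaneDesign,
                   strict: bool = True) -> CountMatrix:
    """Collapse technical-replicate lanes to subject-level counts.

    Each retained subject must have exactly two ``status == "ok"`` lanes;
    the subject-level count is their per-gene sum.  With ``strict=False``
    subjects with a different lane count are dropped with a logged warning
    (the study dropped such subjects); with ``strict=True`` they raise.
    """
    ok = design.ok()
    lane_pos = {lid: i for i, lid in enumerate(matrix.sample_ids)}
    unknown = [l for l in ok["lane_id"] if l not in lane_pos]
    if unknown:
        raise ValueError(f"design lanes absent from count matrix: {unknown}")
    cols, subjects = [], []
    for subject, sub in ok.groupby("subject_id", sort=False):
        if len(sub) != 2:
            msg = f"subject {subject!r} has {len(sub)} usable lanes (need 2)"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; dropping subject", msg)
            continue
        idx = [lane_pos[l] for l in sub["lane_id"]]
        cols.append(matrix.counts[:, idx].sum(axis=1))
        subjects.append(subject)
    if not cols:
        raise ValueError("no subject with a complete lane pair")
    return CountMatrix(matrix.gene_ids, np.asarray(subjects, dtype=object),
                       np.column_stack(cols))


def subject_table(design: LaneDesign) -> pd.DataFrame:
    """Per-subject metadata (group, flow cell, lane-pair position, batch).

    Lane-level attributes shared by a subject's two lanes collapse to one row,
    indexed by subject in first-lane order — the companion of
    :func:`sum_lane_pairs` for model building.
    """
    ok = design.ok()
    rows = ok.groupby("subject_id", sort=False).agg(
        group=("group", "first"),
        flowcell_id=("flowcell_id", "first"),
        lane_pair_id=("lane_pair_id", "first"),
        batch_id=("batch_id", "first"),
        software_version=("software_version", "first"),
    )
    return rows


def filter_expressed(matrix: CountMatrix) -> CountMatrix:
    """Retain genes with at least one count across all samples."""
    keep = matrix.counts.sum(axis=1) >= 1
    if not keep.any():
        warnings.warn("no expressed genes; returning empty matrix")
    return CountMatrix(matrix.gene_ids[keep], matrix.sample_ids, matrix.counts[keep])
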
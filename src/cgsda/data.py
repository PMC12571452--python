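"""Association lists, feature matrices, and the heterogeneous block graph.

The snoRNA-disease network is a bipartite graph: rows of the binary
association matrix ``A`` (shape ``N_S x N_D``) are snoRNAs, columns are
diseases, and ``A[i, j] = 1`` records an experimentally validated
association while 0 means unconfirmed/unknown.  For graph convolution the
bipartite network is embedded in a single symmetric block adjacency

    Y = [[0,         A_train],
         [A_train^T, 0      ]]

with snoRNAs occupying node indices ``0 .. N_S-1`` and diseases
``N_S .. N_S+N_D-1``.  Every downstream matrix in the package follows this
snoRNAs-first, 0-based ordering.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "TrainSplit",
    "HeteroGraph",
    "DegreeStats",
    "load_association_list",
    "write_association_list",
    "load_feature_matrix",
    "build_block_adjacency",
    "degree_summary",
]


@dataclass
class AssociationDataset:
    """The bipartite node sets and the 0/1 association matrix."""

    snorna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray  # (N_S, N_D) int8, entries in {0, 1}

    def __post_init__(self) -> None:
        if len(set(self.snorna_ids)) != len(self.snorna_ids):
            raise ValueError("duplicate snoRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.snorna_ids), len(self.disease_ids)):
            raise ValueError(
                f"A has shape {self.A.shape}, expected "
                f"({len(self.snorna_ids)}, {len(self.disease_ids)})"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary")
        self.A = self.A.astype(np.int8)

    @property
    def n_snorna(self) -> int:
        return len(self.snorna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def snorna_index(self, snorna_id: str) -> int:
        return self.snorna_ids.index(snorna_id)

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def positive_pairs(self) -> np.ndarray:
        """All (snoRNA index, disease index) pairs with A == 1, row-major."""
        return np.argwhere(self.A == 1)


@dataclass
class TrainSplit:
    """Training mask of the association matrix plus the held-out positives."""

    A_train: np.ndarray
    held_out_positives: list[tuple[int, int]]

    @classmethod
    def full(cls, dataset: AssociationDataset) -> "TrainSplit":
        """Keep every known association for training (case-study setting)."""
        return cls(A_train=dataset.A.copy(), held_out_positives=[])

    @classmethod
    def holding_out(
        cls, dataset: AssociationDataset, pairs: list[tuple[int, int]]
    ) -> "TrainSplit":
        A_train = dataset.A.copy()
        for i, j in pairs:
            if A_train[i, j] != 1:
                raise ValueError(f"pair ({i}, {j}) is not a known positive")
            A_train[i, j] = 0
        return cls(A_train=A_train, held_out_positives=[tuple(p) for p in pairs])

    def validate_against(self, dataset: AssociationDataset) -> None:
        if self.A_train.shape != dataset.A.shape:
            raise ValueError("split dimensions do not match dataset")
        if (self.A_train > dataset.A).any():
            raise ValueError("A_train must be elementwise <= A")
        removed = set(map(tuple, np.argwhere((dataset.A == 1) & (self.A_train == 0))))
        if removed != set(self.held_out_positives):
            raise ValueError("held_out_positives inconsistent with A_train mask")


@dataclass
class HeteroGraph:
    """Symmetric block adjacency over all nodes, snoRNAs first."""

    Y: np.ndarray  # (N_S+N_D, N_S+N_D) float64
    n_snorna: int
    n_disease: int

    @property
    def n_nodes(self) -> int:
        return self.n_snorna + self.n_disease

    def neighbors(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.Y[v])

    def degrees(self) -> np.ndarray:
        return self.Y.sum(axis=1)


@dataclass
class DegreeStats:
    """Per-side degree summary mirroring the dataset overview table."""

    snorna_min: int
    snorna_max: int
    snorna_mean: float
    snorna_median: float
    disease_min: int
    disease_max: int
    disease_mean: float
    disease_median: float
    n_snorna: int
    n_disease: int
    n_associations: int

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per statistic, one column per side."""
        rows = [
            ("min_degree", self.snorna_min, self.disease_min),
            ("max_degree", self.snorna_max, self.disease_max),
            ("mean_degree", round(self.snorna_mean, 2), round(self.disease_mean, 2)),
            ("median_degree", self.snorna_median, self.disease_median),
            ("total", self.n_snorna, self.n_disease),
        ]
        frame = pd.DataFrame(rows, columns=["statistic", "snorna", "disease"])
        frame.loc[len(frame)] = ("associations", self.n_associations, self.n_associations)
        return frame


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a 2+ column delimited file, auto-detecting tab/comma and header.

    A header is assumed when the first row repeats no value of the second
    row's shape heuristics; in practice deposits either carry textual column
    names (non-numeric-looking, e.g. ``snorna_id``) or begin directly with
    data rows.  Ids are kept case-sensitive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    header_names = {"snorna_id", "disease_id", "snorna", "disease", "rna", "id"}
    first = [c.strip().lower() for c in text.splitlines()[0].split(sep)]
    has_header = any(c in header_names for c in first)
    frame = pd.read_csv(
        io.StringIO(text),
        sep=sep,
        header=0 if has_header else None,
        dtype=str,
        skip_blank_lines=True,
    )
    return frame


def load_association_list(path: str | Path) -> AssociationDataset:
    """Parse a two-column (snoRNA id, disease id) edge list.

    Ids are deduplicated preserving first-seen order; duplicated pairs
    collapse to a single association with a warning.  Rows with missing
    fields raise with their line number.
    """
    frame = _read_delimited(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns, got {frame.shape[1]}")
    bad = frame.iloc[:, :2].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: row with missing field at data line {line}")

    snorna_ids: list[str] = []
    disease_ids: list[str] = []
    s_index: dict[str, int] = {}
    d_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_dup = 0
    for s, d in frame.iloc[:, :2].itertuples(index=False):
        s, d = str(s).strip(), str(d).strip()
        if s not in s_index:
            s_index[s] = len(snorna_ids)
            snorna_ids.append(s)
        if d not in d_index:
            d_index[d] = len(disease_ids)
            disease_ids.append(d)
        pair = (s_index[s], d_index[d])
        if pair in pairs:
            n_dup += 1
        pairs.add(pair)
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate association row(s)")

    A = np.zeros((len(snorna_ids), len(disease_ids)), dtype=np.int8)
    for i, j in pairs:
        A[i, j] = 1
    return AssociationDataset(snorna_ids=snorna_ids, disease_ids=disease_ids, A=A)


def write_association_list(dataset: AssociationDataset, path: str | Path) -> Path:
    """Write the edge list back as tab-delimited text (round-trips exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("snorna_id\tdisease_id\n")
        for i, j in dataset.positive_pairs():
            fh.write(f"{dataset.snorna_ids[i]}\t{dataset.disease_ids[j]}\n")
    return path


def load_feature_matrix(path: str | Path, id_order: list[str]) -> np.ndarray:
    """Load a per-node feature matrix keyed by id in its first column.

    Rows are reordered to match ``id_order`` exactly; the feature width is
    whatever the file provides.  Missing ids and non-numeric cells raise.
    """
    frame = _read_delimited(path)
    ids = [str(x).strip() for x in frame.iloc[:, 0]]
    lookup = {i: r for r, i in enumerate(ids)}
    missing = [i for i in id_order if i not in lookup]
    if missing:
        raise KeyError(f"{path}: ids missing from feature file: {missing}")
    values = frame.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at data row {r + 1}, feature column {c + 1}"
        )
    matrix = numeric.to_numpy(dtype=np.float64)
    order = [lookup[i] for i in id_order]
    return matrix[order]


def write_feature_matrix(
    ids: list[str], matrix: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(f"f{k}" for k in range(matrix.shape[1])) + "\n")
        for i, row in zip(ids, matrix):
            fh.write(i + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    return path


def build_block_adjacency(
    dataset: AssociationDataset, split: TrainSplit
) -> HeteroGraph:
    """Assemble ``Y = [[0, A_train], [A_train^T, 0]]`` (snoRNAs first)."""
    if split.A_train.shape != dataset.A.shape:
        raise ValueError(
            f"split shape {split.A_train.shape} does not match dataset {dataset.A.shape}"
        )
    n_s, n_d = dataset.A.shape
    Y = np.zeros((n_s + n_d, n_s + n_d), dtype=np.float64)
    Y[:n_s, n_s:] = split.A_train
    Y[n_s:, :n_s] = split.A_train.T
    return HeteroGraph(Y=Y, n_snorna=n_s, n_disease=n_d)


def degree_summary(dataset: AssociationDataset) -> DegreeStats:
    """Min/max/mean/median node degree per side plus totals."""
    if dataset.n_snorna == 0 or dataset.n_disease == 0:
        raise ValueError("empty dataset")
    s_deg = dataset.A.sum(axis=1)
    d_deg = dataset.A.sum(axis=0)
    return DegreeStats(
        snorna_min=int(s_deg.min()),
        snorna_max=int(s_deg.max()),
        snorna_mean=float(s_deg.mean()),
        snorna_median=float(np.median(s_deg)),
        disease_min=int(d_deg.min()),
        disease_max=int(d_deg.max()),
        disease_mean=float(d_deg.mean()),
        disease_median=float(np.median(d_deg)),
        n_snorna=dataset.n_snorna,
        n_disease=dataset.n_disease,
        n_associations=dataset.n_associations,
    )
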
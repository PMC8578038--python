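"""FA-weighted connectome container, assembly from streamline summaries,
and the group-prevalence edge filter.

A connectome here is an undirected network over labelled grey-matter
regions in which the weight of edge (i, j) is the mean fractional
anisotropy (FA) along the streamlines connecting regions i and j, so
weights live in [0, 1] and a zero entry means "no streamline observed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum tolerated asymmetry when reading a matrix from disk.
SYMMETRY_TOL = 1e-8


class ConnectomeError(ValueError):
    """Raised when a matrix violates the connectome contract."""


@dataclass
class Connectome:
    """One subject's symmetric, non-negative FA-weighted adjacency matrix.

    Parameters
    ----------
    labels : list of str
        Region names defining node order.
    weights : ndarray, shape (n, n)
        Symmetric matrix with zero diagonal and entries in [0, 1].
    """

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.shape != (n, n):
            raise ConnectomeError(
                f"weight matrix shape {w.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("non-finite weights")
        if not np.allclose(w, w.T, rtol=0.0, atol=SYMMETRY_TOL):
            raise ConnectomeError("weight matrix is not symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ConnectomeError("diagonal must be zero (no self-loops)")
        if w.min() < 0.0 or w.max() > 1.0:
            raise ConnectomeError(
                f"weights outside [0, 1]: min={w.min():.4g} max={w.max():.4g}"
            )
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def to_tsv(self, path: str | Path) -> None:
        """Write as a labelled TSV (first row and column are node labels)."""
        frame = pd.DataFrame(self.weights, index=self.labels, columns=self.labels)
        frame.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Connectome":
        """Read a labelled matrix TSV, enforcing the connectome contract.

        Matrices whose halves disagree by less than ``SYMMETRY_TOL`` are
        symmetrized by averaging; larger asymmetries raise, since they
        indicate a malformed file rather than floating-point round-off.
        """
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ConnectomeError(f"{path}: row and column labels disagree")
        w = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ConnectomeError(
                f"{path}: non-finite value at cell "
                f"({frame.index[bad[0]]}, {frame.columns[bad[1]]})"
            )
        asym = np.abs(w - w.T).max()
        if asym >= SYMMETRY_TOL:
            raise ConnectomeError(
                f"{path}: asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        w = 0.5 * (w + w.T)
        return cls(labels=list(frame.columns), weights=w)

    def relabelled(self, perm: np.ndarray) -> "Connectome":
        """Return the connectome with nodes reordered by permutation ``perm``."""
        perm = np.asarray(perm)
        return Connectome(
            labels=[self.labels[i] for i in perm],
            weights=self.weights[np.ix_(perm, perm)],
        )


@dataclass
class StreamlineTable:
    """Per-streamline summaries: records of (node_i, node_j, mean FA).

    Node indices are 0-based into a label list; orientation (i, j) vs
    (j, i) carries no meaning.
    """

    records: pd.DataFrame  # columns: node_i, node_j, mean_fa

    def __post_init__(self) -> None:
        required = {"node_i", "node_j", "mean_fa"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"streamline table missing columns {sorted(missing)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StreamlineTable":
        return cls(pd.read_csv(path))


def build_connectome(streamlines: StreamlineTable, node_labels: list[str]) -> Connectome:
    """Assemble a connectome: w_ij = mean streamline FA pooled over orientations.

    Node pairs with no streamline record get weight 0 (no edge).

    Raises
    ------
    ConnectomeError
        On an out-of-range node index or a self-loop record, naming the
        offending record.
    """
    if not node_labels:
        raise ValueError("node label list is empty")
    n = len(node_labels)
    rec = streamlines.records
    w_sum = np.zeros((n, n))
    w_cnt = np.zeros((n, n))
    if len(rec):
        i = rec["node_i"].to_numpy(dtype=int)
        j = rec["node_j"].to_numpy(dtype=int)
        fa = rec["mean_fa"].to_numpy(dtype=float)
        bad = (i < 0) | (i >= n) | (j < 0) | (j >= n)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise ConnectomeError(
                f"record {k} has out-of-range node index: ({i[k]}, {j[k]})"
            )
        if (i == j).any():
            k = int(np.flatnonzero(i == j)[0])
            raise ConnectomeError(f"record {k} is a self-loop on node {i[k]}")
        if fa.min() < 0.0 or fa.max() > 1.0:
            raise ConnectomeError("streamline FA outside [0, 1]")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        np.add.at(w_sum, (lo, hi), fa)
        np.add.at(w_cnt, (lo, hi), 1.0)
    with np.errstate(invalid="ignore"):
        w = np.where(w_cnt > 0, w_sum / np.where(w_cnt > 0, w_cnt, 1.0), 0.0)
    w = w + w.T
    return Connectome(labels=list(node_labels), weights=w)


def edge_prevalence_mask(weights: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Boolean mask of edges present in strictly more than 50% of each group.

    "Present" means weight > 0 (at least one streamline); exactly 50%
    prevalence is excluded.

    Parameters
    ----------
    weights : ndarray, shape (n_subjects, n_nodes, n_nodes)
        Stacked connectome matrices, subject order matching ``is_case``.
    is_case : boolean ndarray, shape (n_subjects,)

    Returns
    -------
    mask : boolean ndarray, shape (n_nodes, n_nodes), symmetric, False diagonal.
    """
    weights = np.asarray(weights)
    is_case = np.asarray(is_case, dtype=bool)
    n_case = int(is_case.sum())
    n_control = int((~is_case).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both groups must contain at least one subject")
    present = weights > 0
    frac_case = present[is_case].mean(axis=0)
    frac_control = present[~is_case].mean(axis=0)
    mask = (frac_case > 0.5) & (frac_control > 0.5)
    np.fill_diagonal(mask, False)
    return mask
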
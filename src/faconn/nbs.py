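"""Network-based statistic (NBS) for group differences in the
edge-weight-score slope, with permutation FWER control.

The procedure, per edge of the prevalence-filtered mask:

1. fit a general linear model of edge weight on
   [intercept, group, score, group x score, age, sex] and compare it to
   the reduced model without the interaction, giving an F statistic for
   the group difference in slope;
2. remove edges whose F falls below a threshold (given explicitly or as
   an upper-tail probability converted at the design's actual degrees of
   freedom);
3. record the size (edge count) of every connected component of the
   surviving edges;
4. repeat over random permutations of the data to build the null
   distribution of the largest component size;
5. assign each observed component the FWER-corrected p-value
   p = (# permutations with max size >= component size) / K.

Two permutation schemes are available. The default, ``group_label``,
permutes the group assignment as a whole row (the group main effect and
the interaction column are rebuilt from the permuted labels while score,
age and sex stay attached to their subjects); when the groups are
exchangeable under the null this scheme is exact, for the single-edge
statistic and, importantly, for the max-component-size statistic too.
``freedman_lane`` permutes reduced-model residuals, the usual choice for
a GLM contrast with nuisance covariates; note, however, that because one
permutation is shared by every edge, the permuted residual covariance
(P R_Z P' instead of R_Z) couples edges and inflates the variance of the
per-permutation supra-threshold edge count, which fattens the tail of
the max-component-size null and makes component p-values conservative at
small n. Both schemes give valid (FWER-controlling) inference; the
group-label scheme is the calibrated default here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .cohort import CohortData
from .connectome import edge_prevalence_mask

logger = logging.getLogger(__name__)

_RSS_EPS = 1e-12


def f_threshold(df1: int, df2: int, alpha: float) -> float:
    """Upper-tail F critical value: P(F_{df1,df2} > value) = alpha."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.f.isf(alpha, df1, df2))


@dataclass
class EdgeStatMap:
    """Per-edge interaction F statistics over the testable edge mask."""

    f: np.ndarray          # (n_nodes, n_nodes), NaN where untested
    mask: np.ndarray       # boolean, symmetric, False diagonal
    df1: int
    df2: int
    edge_index: np.ndarray  # (n_edges, 2) upper-triangle indices tested

    @property
    def f_values(self) -> np.ndarray:
        return self.f[self.edge_index[:, 0], self.edge_index[:, 1]]


@dataclass
class Subnetwork:
    """A connected set of supra-threshold edges with its FWER p-value."""

    edges: list[tuple[int, int]]
    nodes: list[int]
    size: int
    p: float = float("nan")

    def edge_labels(self, labels: list[str]) -> list[tuple[str, str]]:
        return [(labels[i], labels[j]) for i, j in self.edges]


def _design_matrices(
    manifest: pd.DataFrame, score: str, covariates: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Full and reduced (no interaction) design matrices."""
    g = (manifest["group"] == "case").to_numpy(dtype=float)
    s = manifest[score].to_numpy(dtype=float)
    z = manifest[list(covariates)].to_numpy(dtype=float)
    n = len(g)
    full = np.column_stack([np.ones(n), g, s, g * s, z])
    reduced = np.column_stack([np.ones(n), g, s, z])
    return full, reduced


def _nested_f(
    q_full: np.ndarray, q_red: np.ndarray, y: np.ndarray, df2: int
) -> np.ndarray:
    """Vectorised nested-model F over columns of y (one column per edge)."""
    tot = (y**2).sum(axis=0)
    rss_full = tot - ((q_full.T @ y) ** 2).sum(axis=0)
    rss_red = tot - ((q_red.T @ y) ** 2).sum(axis=0)
    rss_full = np.maximum(rss_full, 0.0)
    num = np.maximum(rss_red - rss_full, 0.0)
    denom = rss_full / df2
    return np.where(denom > _RSS_EPS, num / np.where(denom > _RSS_EPS, denom, 1.0), 0.0)


def edge_interaction_fstats(
    cohort: CohortData,
    score: str = "mabc2_total",
    mask: np.ndarray | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> EdgeStatMap:
    """Group x score interaction F statistic at every testable edge.

    F compares the full GLM (intercept, group, score, group x score,
    covariates) to the reduced model without the interaction:
    F = (RSS_red - RSS_full) / (RSS_full / (n - rank_full)). Edges with
    constant weight across subjects get F = 0 with a log entry.
    """
    keep = cohort.complete_score(score)
    manifest = cohort.manifest[keep]
    if (manifest["group"] == "case").sum() < 3 or (manifest["group"] == "control").sum() < 3:
        raise ValueError("need at least 3 scored subjects per group")
    if mask is None:
        mask = edge_prevalence_mask(cohort.weight_stack(), cohort.is_case)
    if not mask.any():
        raise ValueError("edge mask is empty")
    full, reduced = _design_matrices(manifest, score, covariates)
    p_full = full.shape[1]
    if np.linalg.matrix_rank(full) < p_full:
        raise ValueError("rank-deficient design matrix")
    n = full.shape[0]
    df1, df2 = 1, n - p_full
    q_full, _ = np.linalg.qr(full)
    q_red, _ = np.linalg.qr(reduced)
    iu = np.triu_indices(mask.shape[0], 1)
    tested = mask[iu]
    edge_index = np.column_stack([iu[0][tested], iu[1][tested]])
    stack = cohort.weight_stack()[keep]
    y = stack[:, edge_index[:, 0], edge_index[:, 1]]
    const = np.ptp(y, axis=0) == 0.0
    if const.any():
        logger.info("%d edge(s) with constant weight: F set to 0", int(const.sum()))
    f = _nested_f(q_full, q_red, y, df2)
    f[const] = 0.0
    fmat = np.full(mask.shape, np.nan)
    fmat[edge_index[:, 0], edge_index[:, 1]] = f
    fmat[edge_index[:, 1], edge_index[:, 0]] = f
    return EdgeStatMap(f=fmat, mask=mask, df1=df1, df2=df2, edge_index=edge_index)


def _components_from_edges(
    edge_index: np.ndarray, supra: np.ndarray, n_nodes: int
) -> list[Subnetwork]:
    """Connected components of the supra-threshold edge graph."""
    sel = edge_index[supra]
    if len(sel) == 0:
        return []
    adj = sparse.coo_matrix(
        (np.ones(len(sel)), (sel[:, 0], sel[:, 1])), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in sel:
        comps.setdefault(labels[i], []).append((int(i), int(j)))
    out = [
        Subnetwork(
            edges=sorted(edges),
            nodes=sorted({k for e in edges for k in e}),
            size=len(edges),
        )
        for edges in comps.values()
    ]
    return sorted(out, key=lambda s: -s.size)


def supra_threshold_components(
    stat_map: EdgeStatMap, threshold: float
) -> list[Subnetwork]:
    """Connected components of edges with F >= threshold, largest first."""
    supra = stat_map.f_values >= threshold
    return _components_from_edges(stat_map.edge_index, supra, stat_map.mask.shape[0])


class NBSInteraction:
    """NBS model for a group difference in the edge-weight-score slope.

    Parameters
    ----------
    cohort : CohortData
    score : str
        Manifest score column the slopes are taken against.
    mask : boolean ndarray, optional
        Testable-edge mask; defaults to the >50%-per-group prevalence
        filter computed from the cohort.
    covariates : tuple of str
        Nuisance covariates, default ("age", "sex").
    """

    def __init__(
        self,
        cohort: CohortData,
        score: str = "mabc2_total",
        mask: np.ndarray | None = None,
        covariates: tuple[str, ...] = ("age", "sex"),
    ) -> None:
        self.cohort = cohort
        self.score = score
        self.covariates = tuple(covariates)
        self.mask = (
            mask
            if mask is not None
            else edge_prevalence_mask(cohort.weight_stack(), cohort.is_case)
        )

    def fit(
        self,
        n_permutations: int = 10000,
        edge_alpha: float = 0.01,
        edge_f: float | None = None,
        seed: int | None = None,
        scheme: str = "group_label",
        add_one: bool = False,
    ) -> "NBSResults":
        """Run the five-step permutation procedure.

        Parameters
        ----------
        n_permutations : int
            Number of random permutations K (>= 100).
        edge_alpha : float
            Upper-tail probability converted to an F threshold at the
            design's actual degrees of freedom; ignored when ``edge_f``
            is given explicitly.
        edge_f : float, optional
            Explicit edge F threshold.
        seed : int
            Master seed; each permutation draws its own substream.
        scheme : {"group_label", "freedman_lane"}
        add_one : bool
            Use p = (b + 1) / (K + 1) instead of the plain b / K. The
            plain estimator can return p = 0 at finite K.
        """
        if n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if scheme not in ("freedman_lane", "group_label"):
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        alpha_resolution = 1.0 / n_permutations
        if alpha_resolution > 0.05:
            warnings.warn(
                f"K={n_permutations} resolves p only to {alpha_resolution:.3g}",
                stacklevel=2,
            )
        observed = edge_interaction_fstats(
            self.cohort, self.score, self.mask, self.covariates
        )
        threshold = (
            float(edge_f)
            if edge_f is not None
            else f_threshold(observed.df1, observed.df2, edge_alpha)
        )
        components = supra_threshold_components(observed, threshold)

        keep = self.cohort.complete_score(self.score)
        manifest = self.cohort.manifest[keep]
        full, reduced = _design_matrices(manifest, self.score, self.covariates)
        n, p_full = full.shape
        q_full, _ = np.linalg.qr(full)
        q_red, _ = np.linalg.qr(reduced)
        stack = self.cohort.weight_stack()[keep]
        y = stack[:, observed.edge_index[:, 0], observed.edge_index[:, 1]]
        hz_y = q_red @ (q_red.T @ y)
        rz_y = y - hz_y

        streams = np.random.SeedSequence(seed if seed is not None else 0).spawn(
            n_permutations
        )
        null_max = np.zeros(n_permutations, dtype=int)
        n_nodes = self.mask.shape[0]
        for k, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            perm = rng.permutation(n)
            if scheme == "freedman_lane":
                y_perm = hz_y + rz_y[perm]
                f_perm = _nested_f(q_full, q_red, y_perm, observed.df2)
            else:
                g_perm = full[:, 1][perm]
                full_p = full.copy()
                full_p[:, 1] = g_perm
                full_p[:, 3] = g_perm * full[:, 2]
                red_p = reduced.copy()
                red_p[:, 1] = g_perm
                qf_p, _ = np.linalg.qr(full_p)
                qr_p, _ = np.linalg.qr(red_p)
                f_perm = _nested_f(qf_p, qr_p, y, observed.df2)
            supra = f_perm >= threshold
            comps = _components_from_edges(observed.edge_index, supra, n_nodes)
            null_max[k] = comps[0].size if comps else 0
            if (k + 1) % 1000 == 0:
                logger.info("permutation %d / %d", k + 1, n_permutations)

        for comp in components:
            b = int((null_max >= comp.size).sum())
            comp.p = (b + 1) / (n_permutations + 1) if add_one else b / n_permutations

        return NBSResults(
            components=components,
            edge_stats=observed,
            threshold=threshold,
            null_max_sizes=null_max,
            node_labels=self.cohort.node_labels,
            config={
                "score": self.score,
                "n_permutations": n_permutations,
                "edge_alpha": None if edge_f is not None else edge_alpha,
                "edge_f": threshold,
                "df": [observed.df1, observed.df2],
                "scheme": scheme,
                "add_one": add_one,
                "seed": seed,
                "covariates": list(self.covariates),
            },
        )


@dataclass
class NBSResults:
    """Observed components, the edge statistics and the permutation null."""

    components: list[Subnetwork]
    edge_stats: EdgeStatMap
    threshold: float
    null_max_sizes: np.ndarray
    node_labels: list[str]
    config: dict = field(default_factory=dict)

    @property
    def significant(self) -> list[Subnetwork]:
        return [c for c in self.components if c.p < 0.05]

    def summary(self) -> str:
        df1, df2 = self.edge_stats.df1, self.edge_stats.df2
        lines = [
            f"NBS, group x {self.config.get('score', 'score')} interaction; "
            f"edge threshold F({df1},{df2}) >= {self.threshold:.4f}, "
            f"K = {self.config.get('n_permutations')} permutations "
            f"({self.config.get('scheme')})",
            f"tested edges: {len(self.edge_stats.edge_index)}",
            "",
        ]
        if not self.components:
            lines.append("no suprathreshold component")
        for i, comp in enumerate(self.components):
            mark = " *" if comp.p < 0.05 else ""
            lines.append(
                f"component {i + 1}: {len(comp.nodes)} nodes, "
                f"{comp.size} edges, FWER p = {comp.p:.4f}{mark}"
            )
        return "\n".join(lines)

    def to_bundle(self, out_dir: str | Path, centroids: pd.DataFrame | None = None) -> Path:
        """Write JSON summary, per-component edge CSVs, and BrainNet-style
        ``.node`` / ``.edge`` text files for significant components."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hist = np.bincount(self.null_max_sizes)
        payload = {
            "config": self.config,
            "threshold": self.threshold,
            "null_max_size_histogram": hist.tolist(),
            "components": [
                {"size": c.size, "n_nodes": len(c.nodes), "p": c.p}
                for c in self.components
            ],
        }
        (out_dir / "nbs_result.json").write_text(json.dumps(payload, indent=1))
        if centroids is None:
            from .parcellation import dk84_centroids

            try:
                centroids = dk84_centroids()
            except Exception:  # non-84-node cohorts have no bundled table
                centroids = None
        for i, comp in enumerate(self.components):
            rows = [
                {
                    "node_i": i_, "node_j": j_,
                    "label_i": self.node_labels[i_], "label_j": self.node_labels[j_],
                    "F": self.edge_stats.f[i_, j_],
                }
                for i_, j_ in comp.edges
            ]
            pd.DataFrame(rows).to_csv(
                out_dir / f"component_{i + 1}_edges.csv", index=False,
                float_format="%.6g",
            )
            if comp.p < 0.05:
                self._write_brainnet(out_dir, i + 1, comp, centroids)
        return out_dir

    def _write_brainnet(
        self, out_dir: Path, idx: int, comp: Subnetwork, centroids: pd.DataFrame | None
    ) -> None:
        n = len(self.node_labels)
        degree = np.zeros(n, dtype=int)
        adj = np.zeros((n, n), dtype=int)
        for i, j in comp.edges:
            degree[i] += 1
            degree[j] += 1
            adj[i, j] = adj[j, i] = 1
        if centroids is not None and len(centroids) == n:
            xyz = centroids[["x", "y", "z"]].to_numpy()
        else:
            xyz = np.zeros((n, 3))
        with open(out_dir / f"component_{idx}.node", "w") as fh:
            for k, label in enumerate(self.node_labels):
                fh.write(
                    f"{xyz[k, 0]:.1f}\t{xyz[k, 1]:.1f}\t{xyz[k, 2]:.1f}\t"
                    f"1\t{degree[k]}\t{label}\n"
                )
        np.savetxt(out_dir / f"component_{idx}.edge", adj, fmt="%d", delimiter="\t")


def jaccard_edges(
    a: set[tuple[int, int]] | list[tuple[int, int]],
    b: set[tuple[int, int]] | list[tuple[int, int]],
) -> float:
    """Jaccard overlap of two edge sets (orientation-insensitive)."""
    norm = lambda e: (min(e), max(e))  # noqa: E731
    sa = {norm(e) for e in a}
    sb = {norm(e) for e in b}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
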
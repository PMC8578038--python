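"""Synthetic case/control cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two groups (typically 22 cases / 32 controls), FA-weighted
84-node connectomes with edge weights in [0, 1] at tractography-typical
density, MABC-2-style standardized scores (mean 10, SD 3, observed range
clamped to [1, 19]), ages of 6-8 years, Bernoulli(0.5) sex — and,
optionally, a planted subnetwork in which the slope of edge weight on
score differs between groups. The planted edge list is the ground truth
against which recovery is scored.

Randomness comes from a single integer seed expanded into named
substreams (numpy ``SeedSequence``/PCG64), so adding a downstream stage
never perturbs earlier draws and identical (config, seed) pairs
reproduce output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData
from .connectome import Connectome
from .parcellation import dk84_labels
from .tracts import CANONICAL_TRACTS, FAVolume, TractAtlas

SCORE_LO, SCORE_HI = 1.0, 19.0
#: Latent correlation between the total score and each subscale.
SUBSCALE_CORR = 0.5

_STREAMS = ("skeleton", "edge_base", "demographics", "scores", "noise", "dropout")


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the study conditions."""

    n_case: int = 22
    n_control: int = 32
    n_nodes: int = 84
    density: float = 0.35
    base_fa_mean: float = 0.4
    base_fa_sd: float = 0.05
    score_mean: float = 10.0
    score_sd: float = 3.0
    age_range: tuple[float, float] = (6.0, 8.0)
    planted_edges: tuple[tuple[int, int], ...] = ()
    slope_case: float = 0.0
    slope_control: float = 0.0
    noise_sd: float = 0.02
    edge_dropout: float = 0.0  # per-subject, per-edge drop probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("need at least 3 subjects per group")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")
        if self.noise_sd < 0 or self.base_fa_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.edge_dropout < 1.0:
            raise ValueError("edge_dropout must be in [0, 1)")
        edges = []
        for i, j in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) is a self-loop")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"planted edge ({i}, {j}) out of node range")
            edges.append((min(i, j), max(i, j)))
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate planted edges")
        self.planted_edges = tuple(sorted(set(edges)))


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    planted_edges: tuple[tuple[int, int], ...]
    slope_case: float
    slope_control: float
    skeleton_edges: tuple[tuple[int, int], ...]
    rng: dict = field(default_factory=dict)
    tract_effect: float | None = None
    tract_oracle_means: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_edges"] = [list(e) for e in self.planted_edges]
        payload["skeleton_edges"] = [list(e) for e in self.skeleton_edges]
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng_streams(seed: int, names: tuple[str, ...] = _STREAMS) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _truncated_scores(
    z: np.ndarray, mean: float, sd: float
) -> np.ndarray:
    return np.clip(mean + sd * z, SCORE_LO, SCORE_HI)


def _truncnorm_z(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Standard-normal draws truncated so mean + sd*z lies in [1, 19]."""
    a, b = (SCORE_LO - mean) / sd, (SCORE_HI - mean) / sd
    return stats.truncnorm.rvs(a, b, size=n, random_state=rng)


def planted_subnetwork(
    n_sub_nodes: int = 24,
    n_edges: int = 34,
    n_nodes: int = 84,
    seed: int = 7,
) -> tuple[tuple[int, int], ...]:
    """A connected planted subnetwork: spanning tree plus extra edges.

    Defaults give a 24-node, 34-edge component of an 84-node graph, the
    scale of subnetwork the analysis is designed to detect.
    """
    if n_edges < n_sub_nodes - 1:
        raise ValueError("too few edges for a connected subnetwork")
    rng = np.random.default_rng(seed)
    nodes = rng.choice(n_nodes, size=n_sub_nodes, replace=False)
    order = rng.permutation(n_sub_nodes)
    edges = set()
    # random spanning tree: attach each node to an earlier one
    for k in range(1, n_sub_nodes):
        parent = order[rng.integers(0, k)]
        a, b = int(nodes[order[k]]), int(nodes[parent])
        edges.add((min(a, b), max(a, b)))
    while len(edges) < n_edges:
        a, b = rng.choice(n_sub_nodes, size=2, replace=False)
        a, b = int(nodes[a]), int(nodes[b])
        edges.add((min(a, b), max(a, b)))
    return tuple(sorted(edges))


def generate_cohort(cfg: CohortConfig) -> tuple[CohortData, GroundTruth]:
    """Simulate a cohort under ``cfg``; see the module docstring for the model.

    All subjects share one edge skeleton drawn at the requested density
    (``edge_dropout`` then removes edges per subject, to exercise the
    prevalence filter). Planted edges are forced into the skeleton; a
    density too low to accommodate them raises, naming the pairs that
    cannot fit.
    """
    rngs = _rng_streams(cfg.seed)
    n = cfg.n_nodes
    n_sub = cfg.n_case + cfg.n_control
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = int(round(cfg.density * len(pairs)))
    planted = list(cfg.planted_edges)
    if m < len(planted):
        missing = planted[m:]
        raise ValueError(
            f"density {cfg.density} allows only {m} edges; planted edges "
            f"that cannot exist: {missing}"
        )
    other = [p for p in pairs if p not in set(planted)]
    extra_idx = rngs["skeleton"].choice(len(other), size=m - len(planted), replace=False)
    skeleton = sorted(planted + [other[k] for k in sorted(extra_idx)])
    sk_i = np.array([e[0] for e in skeleton])
    sk_j = np.array([e[1] for e in skeleton])
    planted_set = set(planted)
    is_planted = np.array([e in planted_set for e in skeleton])

    base = rngs["edge_base"].normal(cfg.base_fa_mean, cfg.base_fa_sd, size=m)

    age = rngs["demographics"].uniform(*cfg.age_range, size=n_sub)
    sex = rngs["demographics"].integers(0, 2, size=n_sub)

    z_total = _truncnorm_z(rngs["scores"], n_sub, cfg.score_mean, cfg.score_sd)
    total = _truncated_scores(z_total, cfg.score_mean, cfg.score_sd)
    subscales = {}
    for name in ("aiming_catching", "balance", "manual_dexterity"):
        eps = rngs["scores"].standard_normal(n_sub)
        z_sub = SUBSCALE_CORR * z_total + np.sqrt(1 - SUBSCALE_CORR**2) * eps
        subscales[name] = _truncated_scores(z_sub, cfg.score_mean, cfg.score_sd)

    group = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
    slope = np.where(group == "case", cfg.slope_case, cfg.slope_control)

    noise = rngs["noise"].normal(0.0, cfg.noise_sd, size=(n_sub, m))
    w_edges = base[None, :] + noise
    w_edges[:, is_planted] += (slope * (total - cfg.score_mean))[:, None]
    if cfg.edge_dropout > 0:
        keep = rngs["dropout"].random(size=(n_sub, m)) >= cfg.edge_dropout
        w_edges = np.where(keep, w_edges, 0.0)
    # weights are FA means, so they live in [0, 1]; floor slightly above 0
    # so "present" (w > 0) is not confused with a clipped-out edge
    w_edges = np.where(w_edges == 0.0, 0.0, np.clip(w_edges, 1e-6, 1.0))

    labels = dk84_labels() if n == 84 else [f"node{k:03d}" for k in range(n)]
    connectomes = []
    for s in range(n_sub):
        w = np.zeros((n, n))
        w[sk_i, sk_j] = w_edges[s]
        w = w + w.T
        connectomes.append(Connectome(labels=labels, weights=w))

    manifest = pd.DataFrame(
        {
            "subject_id": [f"S{k + 1:03d}" for k in range(n_sub)],
            "group": group,
            "age": np.round(age, 3),
            "sex": sex,
            "mabc2_total": np.round(total, 3),
            "aiming_catching": np.round(subscales["aiming_catching"], 3),
            "balance": np.round(subscales["balance"], 3),
            "manual_dexterity": np.round(subscales["manual_dexterity"], 3),
        }
    )
    truth = GroundTruth(
        planted_edges=tuple(planted),
        slope_case=cfg.slope_case,
        slope_control=cfg.slope_control,
        skeleton_edges=tuple(skeleton),
        rng={
            "bit_generator": "PCG64",
            "numpy": np.__version__,
            "seed": cfg.seed,
            "streams": list(_STREAMS),
        },
    )
    return CohortData(manifest=manifest, connectomes=connectomes), truth


def generate_tract_fixture(
    n_subjects: int,
    n_tracts: int,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    effect: float = 0.0,
    seed: int = 0,
    *,
    base_fa: float = 0.4,
    signal_sd: float = 0.03,
    voxel_noise_sd: float = 0.01,
) -> tuple[list[FAVolume], TractAtlas, np.ndarray, GroundTruth]:
    """Per-subject FA grids plus probabilistic tract masks with a planted
    FA-score correlation.

    Each tract occupies a disjoint cuboid with random occupancy
    probabilities; subject s shifts the in-mask FA by
    ``signal_sd * (effect * z_s + sqrt(1 - effect^2) * eps)`` where
    ``z_s`` is the subject's standardized score, so the extracted tract
    mean correlates with the score at approximately ``effect``.

    Returns volumes, atlas, scores and a GroundTruth whose
    ``tract_oracle_means`` were accumulated voxel-by-voxel (an
    independent arithmetic route from the vectorised extractor).
    """
    if any(g < 8 for g in grid_shape):
        raise ValueError("grid_shape must be at least 8 voxels per axis")
    if not -1.0 < effect < 1.0:
        raise ValueError("effect must satisfy |effect| < 1")
    rngs = _rng_streams(seed, ("masks", "scores", "signal", "voxel_noise"))

    names = list(CANONICAL_TRACTS[:n_tracts])
    names += [f"TRACT{k:02d}" for k in range(len(names), n_tracts)]

    # disjoint 4^3 cuboids on a block grid
    bx, by, bz = (g // 4 for g in grid_shape)
    blocks = [(i, j, k) for i in range(bx) for j in range(by) for k in range(bz)]
    if n_tracts > len(blocks):
        raise ValueError("grid too small for the requested number of tracts")
    chosen = rngs["masks"].choice(len(blocks), size=n_tracts, replace=False)
    masks = {}
    for name, b in zip(names, chosen):
        i, j, k = blocks[b]
        mask = np.zeros(grid_shape)
        probs = rngs["masks"].uniform(0.2, 1.0, size=(4, 4, 4))
        mask[4 * i : 4 * i + 4, 4 * j : 4 * j + 4, 4 * k : 4 * k + 4] = probs
        masks[name] = mask
    atlas = TractAtlas(tracts=masks)

    z = _truncnorm_z(rngs["scores"], n_subjects, 10.0, 3.0)
    scores = _truncated_scores(z, 10.0, 3.0)
    zs = (scores - scores.mean()) / scores.std()

    eps = rngs["signal"].standard_normal((n_subjects, n_tracts))
    amp = signal_sd * (effect * zs[:, None] + np.sqrt(1 - effect**2) * eps)

    volumes = []
    for s in range(n_subjects):
        vol = np.full(grid_shape, base_fa)
        for t, name in enumerate(names):
            vol += amp[s, t] * (masks[name] > 0)
        vol += rngs["voxel_noise"].normal(0.0, voxel_noise_sd, size=grid_shape)
        volumes.append(FAVolume(values=vol))

    oracle = {name: [] for name in names}
    for s in range(n_subjects):
        flat = volumes[s].values.ravel()
        for name in names:
            mflat = masks[name].ravel()
            num = 0.0
            den = 0.0
            for p, v in zip(mflat, flat):
                if p > 0:
                    num += p * v
                    den += p
            oracle[name].append(num / den)
    truth = GroundTruth(
        planted_edges=(),
        slope_case=0.0,
        slope_control=0.0,
        skeleton_edges=(),
        rng={"bit_generator": "PCG64", "numpy": np.__version__, "seed": seed},
        tract_effect=effect,
        tract_oracle_means=oracle,
    )
    return volumes, atlas, scores, truth
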
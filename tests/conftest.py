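import numpy as np
import pandas as pd
import pytest

from faconn import CohortConfig, CohortData, Connectome, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Default-sized cohort with no planted interaction."""
    cohort, truth = generate_cohort(CohortConfig(seed=123))
    return cohort, truth


def make_cohort(weight_stack, groups, scores=None, ages=None, sexes=None):
    """Assemble a CohortData from raw weight matrices for hand-built tests."""
    weight_stack = np.asarray(weight_stack, dtype=float)
    n_sub, n_nodes, _ = weight_stack.shape
    labels = [f"n{k}" for k in range(n_nodes)]
    rng = np.random.default_rng(0)
    if scores is None:
        scores = rng.normal(10, 3, n_sub)
    if ages is None:
        ages = rng.uniform(6, 8, n_sub)
    if sexes is None:
        sexes = rng.integers(0, 2, n_sub)
    manifest = pd.DataFrame(
        {
            "subject_id": [f"S{k:03d}" for k in range(n_sub)],
            "group": groups,
            "age": ages,
            "sex": sexes,
            "mabc2_total": scores,
            "aiming_catching": scores,
            "balance": scores,
            "manual_dexterity": scores,
        }
    )
    conns = [Connectome(labels=labels, weights=w) for w in weight_stack]
    return CohortData(manifest=manifest, connectomes=conns)


# ---------------------------------------------------------------- oracles


def floyd_warshall(w):
    """Exhaustive all-pairs shortest paths on inverse-weight lengths."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_metrics_oracle(w):
    """Characteristic path length and global efficiency from Floyd-Warshall."""
    d = floyd_warshall(w)
    n = w.shape[0]
    cpl_terms, eff_terms = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                cpl_terms.append(d[i, j])
                eff_terms.append(1.0 / d[i, j])
            else:
                eff_terms.append(0.0)
    cpl = float(np.mean(cpl_terms)) if cpl_terms else float("inf")
    return cpl, float(np.mean(eff_terms))


def local_efficiency_oracle(w):
    """Brute-force neighbourhood-subgraph local efficiency (cube-root variant)."""
    n = w.shape[0]
    vals = []
    for u in range(n):
        v = [j for j in range(n) if w[u, j] > 0]
        k = len(v)
        if k < 2:
            vals.append(0.0)
            continue
        sub = w[np.ix_(v, v)]
        # within-subgraph lengths are (1/w)^(1/3): a graph weighted by
        # w^(1/3) has exactly those inverse weights
        d = floyd_warshall(np.cbrt(np.where(sub > 0, sub, 0.0)))
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    acc += np.cbrt(w[u, v[a]] * w[u, v[b]]) / d[a, b]
        vals.append(acc / (k * (k - 1)))
    return float(np.mean(vals))


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration of same-margin tables."""
    from scipy.special import comb

    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(n1, k)
    total = comb(n1 + n2, k)
    probs = {x: comb(n1, x) * comb(n2, k - x) / total for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def bh_stepup_oracle(p):
    """Textbook BH step-up adjusted p-values, computed from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out
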
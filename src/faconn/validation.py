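"""Simulation-based validation protocols for the NBS stage.

These are the package's standard measurement procedures for
(i) family-wise error calibration on null cohorts and (ii) recovery of
a planted interaction subnetwork — used both by the test suite and by
``scripts/acceptance.py`` so the two always measure the same thing.
"""

from __future__ import annotations

import numpy as np

from .nbs import NBSInteraction, jaccard_edges
from .simulate import CohortConfig, generate_cohort, planted_subnetwork


def fwer_calibration(
    seed: int, n_datasets: int = 200, n_permutations: int = 500
) -> float:
    """Fraction of null cohorts (22/32, no planted interaction) on which
    the NBS reports any component at FWER p < 0.05.

    The NBS max-component-size statistic is discrete, so the procedure
    is conservative: the long-run rate sits below the nominal 0.05
    (about 0.03 at these settings) while still controlling FWER.
    """
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    hits = 0
    for child in children:
        data_seed, perm_seed = (int(s) for s in child.generate_state(2) % (2**31 - 1))
        cohort, _ = generate_cohort(CohortConfig(seed=data_seed))
        res = NBSInteraction(cohort).fit(
            n_permutations=n_permutations, seed=perm_seed
        )
        if any(c.p < 0.05 for c in res.components):
            hits += 1
    return hits / n_datasets


def subnetwork_recovery(
    seed: int,
    n_seeds: int = 20,
    n_permutations: int = 1000,
    slope_case: float = 0.010,
    noise_sd: float = 0.02,
) -> tuple[float, float]:
    """Median Jaccard overlap between significant NBS components and a
    planted 24-node / 34-edge subnetwork whose edge-weight-score slope
    differs between groups, over ``n_seeds`` replicate cohorts.

    Returns (median Jaccard, FWER p of the best component on the first
    replicate).
    """
    planted = planted_subnetwork()
    children = np.random.SeedSequence((seed, 1)).spawn(n_seeds)
    jaccards: list[float] = []
    first_p = None
    for child in children:
        data_seed, perm_seed = (int(s) for s in child.generate_state(2) % (2**31 - 1))
        cfg = CohortConfig(
            planted_edges=planted, slope_case=slope_case, slope_control=0.0,
            noise_sd=noise_sd, seed=data_seed,
        )
        cohort, truth = generate_cohort(cfg)
        res = NBSInteraction(cohort).fit(
            n_permutations=n_permutations, seed=perm_seed
        )
        jaccards.append(
            max(
                (jaccard_edges(c.edges, truth.planted_edges) for c in res.significant),
                default=0.0,
            )
        )
        if first_p is None:
            first_p = min((c.p for c in res.components), default=1.0)
    return float(np.median(jaccards)), float(first_p)
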
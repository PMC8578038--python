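"""Covariate-adjusted association of features with motor scores.

``ScoreAssociation`` is a model object in the statsmodels style: it is
built from a feature table (tract FA or network metrics) and a cohort,
and ``fit()`` returns a results object holding, per group and feature,
the partial Pearson correlation with the chosen score (age and sex as
nuisance covariates), its two-tailed p-value, and Benjamini-Hochberg
adjusted p-values computed within each (group, family) of features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortData
from .stats import bh_fdr, partial_pearson

logger = logging.getLogger(__name__)

ALPHA_FDR = 0.05


class ScoreAssociation:
    """Per-group partial correlation of features with a motor score.

    Parameters
    ----------
    features : DataFrame
        Indexed by subject_id, one column per feature (e.g. 18 tract FA
        values or the 7 network metrics).
    cohort : CohortData
    score : str
        Manifest score column, default ``"mabc2_total"``.
    family : str
        Label for the FDR family this feature set forms; adjustment is
        applied within (group, family).
    covariates : sequence of str
        Manifest columns residualized out (default age and sex).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        cohort: CohortData,
        score: str = "mabc2_total",
        family: str = "features",
        covariates: tuple[str, ...] = ("age", "sex"),
    ) -> None:
        manifest = cohort.manifest.set_index("subject_id")
        missing = set(features.index) - set(manifest.index)
        if missing:
            raise ValueError(f"features contain unknown subjects {sorted(missing)}")
        self.features = features
        self.manifest = manifest.loc[features.index]
        self.score = score
        self.family = family
        self.covariates = tuple(covariates)

    def fit(self) -> "AssociationResults":
        rows = []
        for group in ("case", "control"):
            in_group = self.manifest["group"] == group
            score_ok = self.manifest[self.score].notna()
            dropped = in_group & ~score_ok
            if dropped.any():
                logger.info(
                    "%s: excluding %d subject(s) with missing %s: %s",
                    group, int(dropped.sum()), self.score,
                    list(self.manifest.index[dropped]),
                )
            sel = in_group & score_ok
            sub = self.manifest[sel]
            y = sub[self.score].to_numpy(dtype=float)
            z = sub[list(self.covariates)].to_numpy(dtype=float)
            pvals, partial = [], []
            for feat in self.features.columns:
                x = self.features.loc[sel.to_numpy(), feat].to_numpy(dtype=float)
                r, p, df = partial_pearson(x, y, z)
                t = r * np.sqrt(df / (1 - r**2)) if abs(r) < 1 else np.inf
                partial.append((feat, group, r, t, df, int(sel.sum()), p))
                pvals.append(p)
            p_adj = bh_fdr(np.array(pvals))
            for (feat, grp, r, t, df, n, p), q in zip(partial, p_adj):
                rows.append(
                    {
                        "feature": feat,
                        "group": grp,
                        "r": r,
                        "t": t,
                        "df": df,
                        "n": n,
                        "p": p,
                        "p_fdr": q,
                        "significant": q < ALPHA_FDR,
                    }
                )
        table = pd.DataFrame(rows)
        return AssociationResults(
            table=table, score=self.score, family=self.family,
            covariates=self.covariates,
        )


@dataclass
class AssociationResults:
    """Fitted association table with a text summary."""

    table: pd.DataFrame
    score: str
    family: str
    covariates: tuple[str, ...]

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> str:
        lines = [
            f"Partial Pearson correlation with {self.score} "
            f"(covariates: {', '.join(self.covariates)}); "
            f"BH-FDR within group x {self.family}",
            "",
        ]
        fmt = "{:<28s} {:>8s} {:>8s} {:>4s} {:>9s} {:>9s}  {}"
        lines.append(fmt.format("feature", "group", "r", "df", "p", "p_fdr", ""))
        for _, row in self.table.iterrows():
            lines.append(
                fmt.format(
                    str(row["feature"])[:28], row["group"], f"{row['r']:.3f}",
                    str(row["df"]), f"{row['p']:.4f}", f"{row['p_fdr']:.4f}",
                    "*" if row["significant"] else "",
                )
            )
        return "\n".join(lines)
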
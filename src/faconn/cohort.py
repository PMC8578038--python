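"""Aligned case/control cohort: manifest, connectomes and optional tract FA.

The manifest carries one row per subject with group membership
(case/control), demographic covariates (age in years, sex coded 0/1)
and MABC-2 motor scores: the total score plus the three subscales
(aiming & catching, balance, manual dexterity), each standardized to
mean 10 / SD 3 in the population norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("mabc2_total", "aiming_catching", "balance", "manual_dexterity")
MANIFEST_COLUMNS = ("subject_id", "group", "age", "sex") + SCORE_COLUMNS


@dataclass
class CohortData:
    """Manifest plus per-subject connectomes, aligned by row order."""

    manifest: pd.DataFrame
    connectomes: list[Connectome]
    tract_fa: pd.DataFrame | None = None  # indexed by subject_id

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.manifest.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        if self.manifest["subject_id"].duplicated().any():
            dup = self.manifest.loc[
                self.manifest["subject_id"].duplicated(), "subject_id"
            ].iloc[0]
            raise ValueError(f"duplicate subject id {dup!r}")
        groups = set(self.manifest["group"].unique())
        if not groups <= {"case", "control"}:
            raise ValueError(f"unrecognised group values {groups - {'case', 'control'}}")
        if len(self.connectomes) != len(self.manifest):
            raise ValueError(
                f"{len(self.connectomes)} connectomes for "
                f"{len(self.manifest)} manifest rows"
            )
        labels = self.connectomes[0].labels if self.connectomes else []
        for c in self.connectomes:
            if c.labels != labels:
                raise ValueError("connectomes have inconsistent node labels")
        self.manifest = self.manifest.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.manifest)

    @property
    def node_labels(self) -> list[str]:
        return self.connectomes[0].labels

    @property
    def is_case(self) -> np.ndarray:
        return (self.manifest["group"] == "case").to_numpy()

    def weight_stack(self) -> np.ndarray:
        """Stacked weight matrices, shape (n_subjects, n_nodes, n_nodes)."""
        return np.stack([c.weights for c in self.connectomes])

    def complete_score(self, score: str) -> np.ndarray:
        """Boolean mask of subjects with a non-missing value for ``score``."""
        ok = self.manifest[score].notna().to_numpy()
        n_dropped = int((~ok).sum())
        if n_dropped:
            ids = self.manifest.loc[~ok, "subject_id"].tolist()
            logger.info("excluding %d subject(s) missing %s: %s", n_dropped, score, ids)
        return ok

    def write(self, out_dir: str | Path) -> Path:
        """Write manifest CSV + one matrix TSV per subject; return manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mat_dir = out_dir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for sid, conn in zip(manifest["subject_id"], self.connectomes):
            rel = Path("matrices") / f"{sid}.tsv"
            conn.to_tsv(out_dir / rel)
            paths.append(str(rel))
        manifest["matrix_path"] = paths
        manifest_path = out_dir / "manifest.csv"
        manifest.to_csv(manifest_path, index=False, float_format="%.10g")
        if self.tract_fa is not None:
            self.tract_fa.to_csv(out_dir / "tract_fa.csv", float_format="%.10g")
        return manifest_path


def read_cohort(manifest_path: str | Path) -> CohortData:
    """Load a cohort from a manifest CSV, validating every matrix on load.

    Group labels are normalised case-insensitively; matrix paths are
    resolved relative to the manifest's directory. Subjects with missing
    scores are loaded (exclusion happens per-analysis, with a log entry).
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = set(MANIFEST_COLUMNS) | {"matrix_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")
    manifest["group"] = manifest["group"].astype(str).str.strip().str.lower()
    connectomes = []
    for rel in manifest["matrix_path"]:
        p = Path(rel)
        if not p.is_absolute():
            p = manifest_path.parent / p
        connectomes.append(Connectome.from_tsv(p))
    tract_fa = None
    tract_path = manifest_path.parent / "tract_fa.csv"
    if tract_path.exists():
        tract_fa = pd.read_csv(tract_path, index_col=0)
    return CohortData(
        manifest=manifest.drop(columns=["matrix_path"]),
        connectomes=connectomes,
        tract_fa=tract_fa,
    )
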
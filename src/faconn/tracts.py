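"""Probability-weighted mean FA per white-matter tract.

Given a subject's FA map and a probabilistic tract atlas (each tract a
voxelwise probability-of-occupancy grid in atlas space), the tract's FA
summary is the probability-weighted mean over voxels:

    FA_tract = sum_v p(v) * FA(v) / sum_v p(v)

Subject volumes are assumed to already be in atlas space; nonlinear
registration is out of scope for this package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical tract order: 8 bilateral pairs then the two forceps.
CANONICAL_TRACTS = (
    "ATR-L", "ATR-R",
    "CG-L", "CG-R",
    "CH-L", "CH-R",
    "CST-L", "CST-R",
    "IFOF-L", "IFOF-R",
    "ILF-L", "ILF-R",
    "SLF-L", "SLF-R",
    "UF-L", "UF-R",
    "Fminor", "Fmajor",
)


@dataclass
class FAVolume:
    """A 3-D fractional-anisotropy grid with its voxel-to-world affine."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("FA volume must be a non-empty 3-D grid")
        if not np.all(np.isfinite(self.values) | np.isnan(self.values)):
            raise ValueError("FA volume contains infinities")

    @classmethod
    def from_nifti(cls, path: str | Path) -> "FAVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(values=np.asarray(img.get_fdata(), dtype=float), affine=img.affine)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


@dataclass
class TractAtlas:
    """Named probabilistic tract masks sharing one grid shape and affine."""

    tracts: dict[str, np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if not self.tracts:
            raise ValueError("atlas has no tracts")
        shapes = {np.asarray(m).shape for m in self.tracts.values()}
        if len(shapes) != 1:
            raise ValueError(f"atlas masks have inconsistent shapes: {shapes}")
        for name, mask in self.tracts.items():
            mask = np.asarray(mask, dtype=float)
            if mask.min() < 0.0 or mask.max() > 1.0:
                raise ValueError(f"tract {name!r}: probabilities outside [0, 1]")
            if not (mask > 0).any():
                raise ValueError(f"tract {name!r}: zero-probability mask")
            self.tracts[name] = mask

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.tracts.values())).shape

    @property
    def names(self) -> list[str]:
        """Tract names in canonical order where applicable, then the rest."""
        known = [t for t in CANONICAL_TRACTS if t in self.tracts]
        extra = [t for t in self.tracts if t not in CANONICAL_TRACTS]
        return known + extra

    @classmethod
    def from_nifti(cls, paths: dict[str, str | Path]) -> "TractAtlas":
        import nibabel as nib

        tracts, affine = {}, None
        for name, path in paths.items():
            img = nib.load(str(path))
            tracts[name] = np.asarray(img.get_fdata(), dtype=float)
            affine = img.affine if affine is None else affine
        return cls(tracts=tracts, affine=affine)


def weighted_mean_fa(
    fa: FAVolume | np.ndarray,
    mask: np.ndarray,
    *,
    threshold: float | None = None,
) -> float:
    """Probability-weighted mean FA over a tract mask.

    Parameters
    ----------
    fa : FAVolume or ndarray
        Subject FA grid, atlas space.
    mask : ndarray
        Probability-of-occupancy grid, same shape as ``fa``.
    threshold : float, optional
        If given, probabilities below ``threshold`` are zeroed before
        weighting (binarised-style averaging); default is continuous
        weighting with the probabilities as they stand.

    Notes
    -----
    NaN FA voxels are excluded from numerator and denominator with a log
    entry. FA values outside [0, 1] are included (they usually flag
    tensor-fit artefacts) but counted and reported as a warning.
    """
    values = fa.values if isinstance(fa, FAVolume) else np.asarray(fa, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if values.shape != mask.shape:
        raise ValueError(f"shape mismatch: FA {values.shape} vs mask {mask.shape}")
    if threshold is not None:
        mask = np.where(mask >= threshold, mask, 0.0)
    nan = np.isnan(values)
    if nan.any():
        logger.info("excluding %d NaN FA voxel(s) from weighted mean", int(nan.sum()))
    w = np.where(nan, 0.0, mask)
    v = np.where(nan, 0.0, values)
    denom = w.sum()
    if denom <= 0.0:
        raise ValueError("empty mask: sum of probabilities is zero")
    n_out = int(np.count_nonzero((w > 0) & ((v < 0) | (v > 1))))
    if n_out:
        warnings.warn(
            f"{n_out} in-mask FA voxel(s) outside [0, 1] included in the mean",
            stacklevel=2,
        )
    return float((w * v).sum() / denom)


def tract_fa_table(
    volumes: dict[str, FAVolume | None],
    atlas: TractAtlas,
    *,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-subject, per-tract probability-weighted mean FA.

    Parameters
    ----------
    volumes : dict subject_id -> FAVolume (or None for a missing scan)
    atlas : TractAtlas

    Returns
    -------
    DataFrame indexed by subject_id with one column per tract in
    canonical order; rows for missing volumes are all-NaN (flagged, not
    dropped).
    """
    names = atlas.names
    for sid, vol in volumes.items():
        if vol is not None and vol.values.shape != atlas.shape:
            raise ValueError(
                f"subject {sid!r}: FA grid {vol.values.shape} does not match "
                f"atlas grid {atlas.shape}"
            )
    rows = {}
    for sid, vol in volumes.items():
        if vol is None:
            logger.warning("subject %s: missing FA volume, row flagged missing", sid)
            rows[sid] = [np.nan] * len(names)
            continue
        rows[sid] = [
            weighted_mean_fa(vol, atlas.tracts[t], threshold=threshold) for t in names
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    table.index.name = "subject_id"
    return table
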
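"""Candidate feature extraction from T2* maps and feature standardization.

Eleven size-invariant or size-normalized candidate features are computed per
ligament: median, mean, SD, skew, Q1 and Q3 of the in-mask T2* distribution;
average cross-sectional area (CSA = ligament volume / ligament length); and
four sub-volume proportions — the fraction of in-mask voxels whose T2* falls
in each of four 12.5 ms bins spanning 0–50 ms.  Shorter T2* reflects more
organized collagen, so Prop 1 tracks the most organized tissue and Prop 4
the least organized.

Binning convention: half-open [lo, hi) bins except the top bin, which is
closed at 50 ms.  Voxels above 50 ms count in the denominator (total
ligament volume) but in no bin, so the four proportions may sum to < 1.

Standardization is plain z-scoring.  A :class:`StandardizationReference`
freezes per-feature means and SDs (e.g. from the porcine training set) so
that a clinical cohort can be scaled onto the training distribution before
prediction.  Limb type is a dichotomous 0/1 code and is never z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .relaxometry import T2StarMap, ValidationError

__all__ = [
    "CONTINUOUS_FEATURES",
    "CANDIDATE_FEATURES",
    "DEFAULT_BIN_EDGES",
    "T2Statistics",
    "StandardizationReference",
    "t2star_statistics",
    "subvolume_proportions",
    "average_csa",
    "mask_principal_length",
    "extract_features",
    "standardize",
    "destandardize",
    "harmonize_by_scanner",
]

#: The continuous MR candidate features, in frozen table order.
CONTINUOUS_FEATURES = (
    "median_t2", "mean_t2", "sd_t2", "skew_t2", "q1_t2", "q3_t2",
    "csa", "prop1", "prop2", "prop3", "prop4",
)
#: Full candidate set: the MR features plus the dichotomous limb-type code.
CANDIDATE_FEATURES = CONTINUOUS_FEATURES + ("limb_type",)

DEFAULT_BIN_EDGES = (0.0, 12.5, 25.0, 37.5, 50.0)


class T2Statistics(NamedTuple):
    median: float
    mean: float
    sd: float
    skew: float
    q1: float
    q3: float


def _in_mask_values(map_or_values) -> np.ndarray:
    if isinstance(map_or_values, T2StarMap):
        return map_or_values.values
    return np.asarray(map_or_values, dtype=float).ravel()


def t2star_statistics(map_or_values) -> T2Statistics:
    """Order statistics and moments of the in-mask T2* distribution.

    Skew is the adjusted Fisher–Pearson coefficient (bias-corrected), and is
    defined as 0 for a zero-variance sample.  Quartiles use linear
    interpolation.  Requires at least two voxels (SD is undefined below).
    """
    v = _in_mask_values(map_or_values)
    if v.size < 2:
        raise ValidationError("need at least 2 in-mask voxels for T2* statistics")
    sd = float(np.std(v, ddof=1))
    skew = 0.0 if sd == 0.0 else float(stats.skew(v, bias=False))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return T2Statistics(float(med), float(np.mean(v)), sd, skew, float(q1), float(q3))


def subvolume_proportions(
    map_or_values, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> tuple[float, float, float, float]:
    """Fraction of in-mask voxels per T2* bin, over the TOTAL voxel count.

    Bins are [lo, hi) with the final bin closed at its upper edge; voxels
    beyond the top edge contribute to the denominator only.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size != 5 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be 5 strictly increasing values")
    v = _in_mask_values(map_or_values)
    if v.size == 0:
        raise ValidationError("empty mask: no voxels to bin")
    n = v.size
    props = []
    for i in range(4):
        lo, hi = edges[i], edges[i + 1]
        if i == 3:
            count = np.sum((v >= lo) & (v <= hi))
        else:
            count = np.sum((v >= lo) & (v < hi))
        props.append(float(count) / n)
    return tuple(props)


def average_csa(
    mask: np.ndarray,
    voxel_size: Sequence[float],
    ligament_length: float,
) -> float:
    """Average cross-sectional area: ligament volume / ligament length (mm²)."""
    if ligament_length <= 0:
        raise ValidationError("ligament_length must be positive")
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("mask is empty")
    return n * float(np.prod(np.asarray(voxel_size, float))) / float(ligament_length)


def mask_principal_length(mask: np.ndarray, voxel_size: Sequence[float]) -> float:
    """Ligament length estimated as the mask extent along its principal axis.

    Voxel coordinates (mm) are projected onto the leading eigenvector of
    their covariance; the length is the projection range plus one voxel
    (so a single-voxel mask has the extent of that voxel).
    """
    mask = np.asarray(mask).astype(bool)
    coords = np.argwhere(mask) * np.asarray(voxel_size, float)
    if coords.shape[0] == 0:
        raise ValidationError("mask is empty")
    if coords.shape[0] == 1:
        return float(np.max(voxel_size))
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    # one voxel extent along the axis, to convert centre-to-centre range to edges
    edge = float(np.abs(axis) @ np.asarray(voxel_size, float))
    return float(proj.max() - proj.min()) + edge


def extract_features(
    t2map: T2StarMap,
    subject_id: str,
    limb_type: str,
    ligament_length: float | None = None,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    **extra,
) -> dict:
    """One limb's full candidate feature record as a plain dict.

    ``limb_type`` is encoded surgical = 1, contralateral = 0.  If
    ``ligament_length`` is not supplied it defaults to the mask
    principal-axis extent.
    """
    if limb_type not in ("surgical", "contralateral"):
        raise ValidationError(f"unknown limb_type {limb_type!r}")
    s = t2star_statistics(t2map)
    p1, p2, p3, p4 = subvolume_proportions(t2map, bin_edges)
    if ligament_length is None:
        ligament_length = mask_principal_length(t2map.mask, t2map.voxel_size)
    csa = average_csa(t2map.mask, t2map.voxel_size, ligament_length)
    rec = {
        "subject_id": subject_id,
        "limb_type": 1 if limb_type == "surgical" else 0,
        "median_t2": s.median, "mean_t2": s.mean, "sd_t2": s.sd,
        "skew_t2": s.skew, "q1_t2": s.q1, "q3_t2": s.q3,
        "csa": csa, "prop1": p1, "prop2": p2, "prop3": p3, "prop4": p4,
    }
    rec.update(extra)
    return rec


@dataclass
class StandardizationReference:
    """Frozen per-feature means and SDs used for z-scoring.

    Built from a training table (typically the porcine training split) and
    applied unchanged to any later cohort, so cross-cohort features land on
    the training scale.
    """

    means: dict[str, float]
    sds: dict[str, float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if sd <= 0:
                raise ValidationError(f"reference SD for {name!r} must be > 0")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        features: Iterable[str] | None = None,
        source: str = "train",
    ) -> "StandardizationReference":
        feats = [f for f in (features or CONTINUOUS_FEATURES) if f in table.columns]
        means = {f: float(table[f].mean()) for f in feats}
        sds = {f: float(table[f].std(ddof=1)) for f in feats}
        for f, sd in sds.items():
            if not sd > 0:
                raise ValidationError(f"feature {f!r} has zero variance in reference table")
        return cls(means, sds, source)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(
            {"source": self.source, "means": self.means, "sds": self.sds}
        ))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StandardizationReference":
        d = yaml.safe_load(Path(path).read_text())
        return cls(d["means"], d["sds"], d.get("source", "unspecified"))


def standardize(table: pd.DataFrame, reference: StandardizationReference) -> pd.DataFrame:
    """Z-score continuous features with the reference statistics.

    Non-feature columns (ids, limb_type, outcomes) pass through untouched.
    """
    out = table.copy()
    missing = [f for f in reference.means if f not in table.columns]
    if missing:
        raise ValidationError(f"table lacks reference features: {missing}")
    for f, mu in reference.means.items():
        out[f] = (table[f] - mu) / reference.sds[f]
    return out


def destandardize(table: pd.DataFrame, reference: StandardizationReference) -> pd.DataFrame:
    """Invert :func:`standardize` with the same reference."""
    out = table.copy()
    for f, mu in reference.means.items():
        out[f] = table[f] * reference.sds[f] + mu
    return out


def harmonize_by_scanner(
    table: pd.DataFrame,
    scanner_col: str = "scanner_id",
    features: Iterable[str] | None = None,
    rescale: bool = True,
) -> pd.DataFrame:
    """Per-scanner z-scoring of continuous features.

    A declared stand-in for cross-scanner harmonization: removes per-scanner
    location/scale differences so cohorts acquired with different echo
    trains or intensity calibrations are comparable.  With ``rescale``
    (default) the z-scores are mapped back onto the pooled cohort's mean and
    SD, so features keep their physical scale and can subsequently be
    standardized against an external (e.g. porcine) reference; with
    ``rescale=False`` the plain per-scanner z-scores are returned.  Each
    scanner needs at least 2 records.
    """
    if scanner_col not in table.columns:
        raise ValidationError(f"missing scanner column {scanner_col!r}")
    feats = [f for f in (features or CONTINUOUS_FEATURES) if f in table.columns]
    counts = table[scanner_col].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"scanners with <2 records: {list(small.index)}")
    out = table.copy()
    pooled_mean = table[feats].mean()
    pooled_sd = table[feats].std(ddof=1).replace(0.0, 1.0)
    for _, idx in table.groupby(scanner_col).groups.items():
        sub = table.loc[idx, feats]
        sd = sub.std(ddof=1).replace(0.0, 1.0)  # constant feature: center only
        z = (sub - sub.mean()) / sd
        out.loc[idx, feats] = z * pooled_sd + pooled_mean if rescale else z
    return out
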
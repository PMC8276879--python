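"""Distributed deviating-voxel statistics against a normative reference.

Each subject's CBF map is converted voxelwise into a z-score
``z = (x_i - x_ref) / SD_ref`` where ``x_ref`` and ``SD_ref`` are the
per-voxel mean and sample SD over a reference group.  Members of the
reference group are scored against the remaining n-1 members
(leave-one-out).  Voxels deviating beyond the two-sided confidence
threshold (|z| > 2.576 at 99%) are counted per atlas region, separately
for the negative (hypoperfusion) and positive tails, and reported as a
percentage of the subject's intracranial volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceModel",
    "ZMap",
    "RegionAtlas",
    "DeviationTally",
    "critical_z",
    "build_reference",
    "zscore_map",
    "flag_and_tally",
    "CORTICAL_REGIONS",
    "REGION_LABELS",
]

# canonical atlas label scheme used by the synthetic phantom and tallies;
# cortical sub-regions (1-4) partition the cerebral cortex
REGION_LABELS: dict[int, str] = {
    1: "frontal_cortex",
    2: "temporal_cortex",
    3: "parietal_cortex",
    4: "occipital_cortex",
    5: "subcortical_gm",
}
CORTICAL_REGIONS = ("frontal_cortex", "temporal_cortex",
                    "parietal_cortex", "occipital_cortex")


def critical_z(confidence: float) -> float:
    """Two-sided standard-normal threshold for the given coverage.

    ``critical_z(0.99)`` is 2.576 (to 3 decimal places): a voxel deviates
    with 99% confidence when |z| exceeds this value.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    return float(norm.ppf(1.0 - (1.0 - confidence) / 2.0))


@dataclass
class RegionAtlas:
    """Integer label volume with named GM regions.

    ``gm_restriction`` limits voxel counting to grey matter.  Labels
    follow :data:`REGION_LABELS` unless ``region_names`` overrides them.
    """

    labels: np.ndarray
    region_names: dict[int, str] = field(
        default_factory=lambda: dict(REGION_LABELS)
    )
    gm_restriction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.gm_restriction is None:
            self.gm_restriction = self.labels > 0
        self.gm_restriction = np.asarray(self.gm_restriction, dtype=bool)
        missing = [
            name for lbl, name in self.region_names.items()
            if not np.any(self.labels == lbl)
        ]
        if missing:
            raise ValueError(f"atlas regions empty/absent: {missing}")

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask for a named region or an aggregate.

        Aggregates: ``cerebral_cortex`` (union of cortical sub-regions)
        and ``whole_cerebrum`` (all labeled regions).
        """
        if name == "whole_cerebrum":
            labels = list(self.region_names)
        elif name == "cerebral_cortex":
            labels = [l for l, n in self.region_names.items()
                      if n in CORTICAL_REGIONS]
        else:
            labels = [l for l, n in self.region_names.items() if n == name]
            if not labels:
                raise KeyError(f"unknown region '{name}'")
        return np.isin(self.labels, labels) & self.gm_restriction

    @property
    def report_regions(self) -> list[str]:
        return (["whole_cerebrum", "cerebral_cortex"]
                + [n for n in self.region_names.values()])


@dataclass
class ReferenceModel:
    """Per-voxel normative mean and SD over the reference group.

    ``member_values`` holds the stacked reference maps (NaN outside each
    subject's valid mask) so that leave-one-out scoring can rebuild the
    model exactly; it is absent when the model was loaded from persisted
    mean/SD maps only, in which case LOO is unavailable.
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    n_ref: int
    member_ids: tuple[str, ...]
    common_mask: np.ndarray
    smoothing_fwhm: float = 0.0
    member_values: np.ndarray | None = None  # (n_ref, x, y, z)

    def __post_init__(self) -> None:
        if self.n_ref < 3:
            raise ValueError(f"reference group needs >= 3 members, got {self.n_ref}")
        if np.any(self.sd_map[self.common_mask] < 0):
            raise ValueError("negative SD in reference model")


@dataclass
class ZMap:
    """Voxelwise z-scores of one subject against the reference."""

    z: np.ndarray
    valid_mask: np.ndarray
    subject_id: str
    loo_applied: bool
    excluded_voxels: int


def _smooth(values: np.ndarray, mask: np.ndarray,
            fwhm_mm: float, voxel_dims: tuple[float, ...]) -> np.ndarray:
    """Isotropic Gaussian smoothing restricted to a mask (NaN-aware)."""
    sigma = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / d for d in voxel_dims]
    filled = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(mask, out, np.nan)


def build_reference(
    ref_maps: list,
    smoothing_fwhm: float = 0.0,
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 7.0),
) -> ReferenceModel:
    """Aggregate reference CBF maps into a per-voxel mean/SD model.

    The model is defined on the intersection of the members' valid masks.
    The SD uses the n-1 denominator.  Optional Gaussian smoothing (FWHM in
    mm) is applied to each input map before aggregation; the default is
    no smoothing.
    """
    if len(ref_maps) < 3:
        raise ValueError(
            f"insufficient reference maps: need >= 3, got {len(ref_maps)}"
        )
    shape = ref_maps[0].values.shape
    common = np.ones(shape, dtype=bool)
    for m in ref_maps:
        if m.values.shape != shape:
            raise ValueError("reference maps are not on one grid")
        common &= m.valid_mask
    if not common.any():
        raise ValueError("empty common mask across reference maps")
    stack = np.empty((len(ref_maps),) + shape, dtype=float)
    for i, m in enumerate(ref_maps):
        vals = m.values
        if smoothing_fwhm > 0:
            vals = _smooth(vals, m.valid_mask, smoothing_fwhm, voxel_dims)
        stack[i] = np.where(common, vals, np.nan)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    ids = tuple(
        m.subject_id if m.subject_id is not None else f"ref{i:03d}"
        for i, m in enumerate(ref_maps)
    )
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in reference group")
    return ReferenceModel(
        mean_map=np.where(common, mean, np.nan),
        sd_map=np.where(common, sd, np.nan),
        n_ref=len(ref_maps),
        member_ids=ids,
        common_mask=common,
        smoothing_fwhm=smoothing_fwhm,
        member_values=stack,
    )


def zscore_map(subject, model: ReferenceModel) -> ZMap:
    """Score a subject's CBF map against the normative reference.

    Reference-group members are scored leave-one-out: the mean/SD are
    recomputed from the other n-1 members before scoring.  Voxels with
    zero reference SD are excluded and counted rather than producing
    infinite z.
    """
    if subject.values.shape != model.mean_map.shape:
        raise ValueError("subject map is not on the reference grid")
    sid = subject.subject_id or ""
    is_member = sid in model.member_ids
    if is_member:
        if model.member_values is None:
            raise ValueError(
                "leave-one-out scoring requires a model built in-memory "
                "(member maps unavailable in persisted mean/SD model)"
            )
        if model.n_ref == 3:
            logger.warning(
                "leave-one-out with n_ref=3 leaves only 2 reference "
                "subjects; z-scores are unreliable"
            )
        keep = [i for i, m in enumerate(model.member_ids) if m != sid]
        sub = model.member_values[keep]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
    else:
        mean, sd = model.mean_map, model.sd_map
    valid = model.common_mask & subject.valid_mask
    zero_sd = valid & ~(sd > 0)
    excluded = int(zero_sd.sum())
    valid = valid & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (subject.values - mean) / sd
    z = np.where(valid, z, np.nan)
    return ZMap(
        z=z, valid_mask=valid, subject_id=sid,
        loo_applied=is_member, excluded_voxels=excluded,
    )


def flag_and_tally(
    zmap: ZMap,
    atlas: RegionAtlas,
    z_crit: float,
    icv: float,
    voxel_volume: float,
) -> "DeviationTally":
    """Count deviating voxels per region and express them as % of ICV.

    Strict inequalities are used (z < -z_crit, z > +z_crit); counting is
    restricted to atlas GM voxels inside the z-map's valid domain; the
    fraction denominator is the subject's intracranial volume.
    """
    if z_crit <= 0:
        raise ValueError(f"z_crit must be > 0, got {z_crit}")
    if icv <= 0:
        raise ValueError(f"icv must be > 0, got {icv}")
    if voxel_volume <= 0:
        raise ValueError(f"voxel_volume must be > 0, got {voxel_volume}")
    if atlas.labels.shape != zmap.z.shape:
        raise ValueError("atlas grid does not match z-map grid")
    neg = (zmap.z < -z_crit) & zmap.valid_mask
    pos = (zmap.z > z_crit) & zmap.valid_mask
    rows = []
    for name in atlas.report_regions:
        rmask = atlas.region_mask(name) & zmap.valid_mask
        n_neg = int(np.sum(neg & rmask))
        n_pos = int(np.sum(pos & rmask))
        rows.append({
            "region": name,
            "n_voxels": int(rmask.sum()),
            "n_neg": n_neg,
            "n_pos": n_pos,
            "frac_neg_icv_pct": 100.0 * n_neg * voxel_volume / icv,
            "frac_pos_icv_pct": 100.0 * n_pos * voxel_volume / icv,
        })
    return DeviationTally(
        table=pd.DataFrame(rows),
        subject_id=zmap.subject_id,
        z_crit=z_crit,
        icv=icv,
        voxel_volume=voxel_volume,
    )


@dataclass
class DeviationTally:
    """Per-region deviating-voxel counts and ICV fractions for a subject."""

    table: pd.DataFrame
    subject_id: str
    z_crit: float
    icv: float
    voxel_volume: float

    def __post_init__(self) -> None:
        t = self.table
        if (t["n_neg"] < 0).any() or (t["n_pos"] < 0).any():
            raise ValueError("negative deviation counts")
        if ((t["n_neg"] + t["n_pos"]) > t["n_voxels"]).any():
            raise ValueError("more flagged voxels than evaluated voxels")

    def fraction(self, region: str, tail: str = "neg") -> float:
        col = f"frac_{tail}_icv_pct"
        row = self.table.loc[self.table["region"] == region, col]
        if row.empty:
            raise KeyError(f"region '{region}' not in tally")
        return float(row.iloc[0])

    def to_records(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "subject", self.subject_id)
        return out
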
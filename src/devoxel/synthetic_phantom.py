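"""Seeded synthetic phantoms: anatomy, ASL series, PC cines, cohorts.

Everything here is deterministic for a fixed seed.  The default phantom
mirrors a 2D multislice ASL geometry at desk scale (40 x 48 x 17 voxels
of 3 x 3 x 7 mm) with grey-matter CBF around 30 ml/100 g/min and
between-subject spread, so the full quantification and deviating-voxel
pipeline can be exercised without any acquired data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from devoxel.asl_cbf import (
    AslAcquisition,
    AslSeries,
    CbfMap,
    GmProbabilityMap,
    effective_pld,
)
from devoxel.carotid_qflow import PhaseContrastCine, VesselRoi
from devoxel.deviating_voxels import REGION_LABELS, RegionAtlas
from devoxel.regional_analysis import CohortTable

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "make_phantom_anatomy",
    "true_cbf_map",
    "simulate_asl_series",
    "inject_lesions",
    "simulate_pc_cine",
    "simulate_cohort",
    "simulate_subject_map",
]

DEFAULT_REGION_CBF = {
    "frontal_cortex": 32.0,
    "temporal_cortex": 31.0,
    "parietal_cortex": 30.0,
    "occipital_cortex": 33.0,
    "subcortical_gm": 28.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of the synthetic phantom."""

    shape: tuple[int, int, int] = (40, 48, 17)
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 7.0)
    region_cbf: dict = field(default_factory=lambda: dict(DEFAULT_REGION_CBF))
    between_subject_sd: float = 2.0   # global offset SD (ml/100 g/min)
    voxel_sd: float = 4.0             # per-voxel across-subject SD
    asl_noise_sd: float = 0.5         # signal units per repetition
    n_pairs: int = 50
    si_pd_level: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.shape[:2]) or self.shape[2] < 1:
            raise ValueError(f"grid too small: {self.shape}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.asl_noise_sd < 0 or self.voxel_sd < 0 or self.between_subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.si_pd_level <= 0:
            raise ValueError("si_pd_level must be > 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass(frozen=True)
class LesionSpec:
    """Scattered hypoperfusion lesions for one cohort arm.

    ``depth`` is in units of the local reference SD (negative =
    hypoperfusion); lesion locations are re-randomized per subject and,
    in ``non_overlapping`` mode, disjoint across subjects.
    """

    region: str = "subcortical_gm"
    fraction: float = 0.05
    depth: float = -4.0
    scatter: str = "non_overlapping"  # or "independent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"lesion fraction must be in [0, 1], got {self.fraction}")
        if not np.isfinite(self.depth):
            raise ValueError("lesion depth must be finite")
        if self.scatter not in ("non_overlapping", "independent"):
            raise ValueError(f"unknown scatter mode '{self.scatter}'")


def _ellipsoid(shape, scale) -> np.ndarray:
    nx, ny, nz = shape
    x = (np.arange(nx) - (nx - 1) / 2) / (0.48 * nx)
    y = (np.arange(ny) - (ny - 1) / 2) / (0.48 * ny)
    z = (np.arange(nz) - (nz - 1) / 2) / (0.52 * nz)
    r2 = (x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2)
    return r2 <= scale ** 2


def make_phantom_anatomy(
    spec: PhantomSpec,
) -> tuple[RegionAtlas, GmProbabilityMap, float]:
    """Build the atlas, GM probability map and intracranial volume.

    The cortical ribbon (between two ellipsoids) is partitioned exactly
    into frontal/temporal/parietal/occipital sectors by anterior-posterior
    and dorso-ventral position; an inner ellipsoid forms subcortical GM.
    ICV is the intracranial (outer-ellipsoid) voxel count times voxel
    volume.
    """
    nx, ny, nz = spec.shape
    brain = _ellipsoid(spec.shape, 1.0)
    inner = _ellipsoid(spec.shape, 0.62)
    subcort = _ellipsoid(spec.shape, 0.34)
    cortex = brain & ~inner
    labels = np.zeros(spec.shape, dtype=np.int32)

    yc = (np.arange(ny) - (ny - 1) / 2) / (0.48 * ny)
    zc = (np.arange(nz) - (nz - 1) / 2) / (0.52 * nz)
    Y = np.broadcast_to(yc[None, :, None], spec.shape)
    Z = np.broadcast_to(zc[None, None, :], spec.shape)
    frontal = cortex & (Y > 0.30)
    occipital = cortex & (Y < -0.30)
    mid = cortex & ~frontal & ~occipital
    parietal = mid & (Z > 0)
    temporal = mid & (Z <= 0)
    labels[frontal] = 1
    labels[temporal] = 2
    labels[parietal] = 3
    labels[occipital] = 4
    labels[subcort] = 5

    for lbl, name in REGION_LABELS.items():
        if not np.any(labels == lbl):
            raise ValueError(
                f"phantom geometry leaves region '{name}' empty for shape {spec.shape}"
            )
    gm_mask = labels > 0
    rng = np.random.default_rng(spec.seed)
    prob = np.zeros(spec.shape)
    prob[brain] = 0.05
    prob[gm_mask] = 0.75 + 0.25 * rng.random(int(gm_mask.sum()))
    atlas = RegionAtlas(labels=labels, gm_restriction=gm_mask)
    icv = float(brain.sum()) * spec.voxel_volume
    return atlas, GmProbabilityMap(prob=prob), icv


def true_cbf_map(spec: PhantomSpec, atlas: RegionAtlas) -> np.ndarray:
    """Noise-free ground-truth CBF volume from the per-region table."""
    cbf = np.zeros(spec.shape)
    for lbl, name in atlas.region_names.items():
        cbf[atlas.labels == lbl] = spec.region_cbf[name]
    return cbf


def _delta_si_from_cbf(
    cbf: np.ndarray, si_pd: np.ndarray, acq: AslAcquisition
) -> np.ndarray:
    """Algebraic inversion of the quantification model, per slice."""
    t1b_s = acq.t1_blood / 1000.0
    tau_s = acq.tau / 1000.0
    nz = cbf.shape[2]
    pld_s = np.array([effective_pld(z, acq) / 1000.0 for z in range(1, nz + 1)])
    decay = np.exp(pld_s / t1b_s)[None, None, :]
    denom_const = 2.0 * acq.alpha * acq.alpha_inv * t1b_s * (
        1.0 - np.exp(-tau_s / t1b_s)
    )
    return cbf * denom_const * si_pd / (6000.0 * acq.lambda_bp * decay)


def simulate_asl_series(
    true_cbf: np.ndarray,
    acq: AslAcquisition,
    spec: PhantomSpec,
    brain_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AslSeries, np.ndarray]:
    """Forward-simulate an interleaved control/label series plus PD image.

    The control/label signals are ``baseline +/- dSI/2`` with i.i.d.
    Gaussian noise per repetition, where ``dSI`` inverts the
    quantification model so that noise-free recovery is exact.
    """
    true_cbf = np.asarray(true_cbf, dtype=float)
    if not np.all(np.isfinite(true_cbf)):
        raise ValueError("true_cbf must be finite")
    if true_cbf.shape[2] != acq.n_slices:
        raise ValueError("true_cbf slice count does not match acquisition")
    if brain_mask is None:
        brain_mask = np.ones(true_cbf.shape, dtype=bool)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    si_pd = np.where(brain_mask, spec.si_pd_level, 0.0)
    delta = _delta_si_from_cbf(true_cbf, si_pd, acq)
    base = si_pd  # baseline signal ~ PD level inside the brain
    n_rep = 2 * spec.n_pairs
    vols = np.empty(true_cbf.shape + (n_rep,))
    for p in range(spec.n_pairs):
        noise_c = rng.normal(0.0, spec.asl_noise_sd, true_cbf.shape) \
            if spec.asl_noise_sd > 0 else 0.0
        noise_l = rng.normal(0.0, spec.asl_noise_sd, true_cbf.shape) \
            if spec.asl_noise_sd > 0 else 0.0
        vols[..., 2 * p] = base + delta / 2.0 + noise_c
        vols[..., 2 * p + 1] = base - delta / 2.0 + noise_l
    series = AslSeries(volumes=vols, control_first=True,
                       voxel_dims=spec.voxel_dims)
    return series, si_pd


def inject_lesions(
    true_cbf: np.ndarray,
    ref_sd_map: np.ndarray,
    lesion: LesionSpec,
    atlas: RegionAtlas,
    rng: np.random.Generator,
    occupied: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift a random subset of region voxels by ``depth * local SD``.

    ``occupied`` marks voxels already lesioned in other subjects; in
    non-overlapping scatter mode new lesions avoid them (the caller keeps
    the running mask).  Returns the modified map and the lesion mask.
    """
    region = atlas.region_mask(lesion.region)
    n_target = int(round(lesion.fraction * region.sum()))
    out = np.array(true_cbf, dtype=float, copy=True)
    mask = np.zeros(true_cbf.shape, dtype=bool)
    if n_target == 0:
        return out, mask
    candidates = region.copy()
    if lesion.scatter == "non_overlapping" and occupied is not None:
        candidates &= ~occupied
    idx = np.flatnonzero(candidates)
    if len(idx) < n_target:
        raise ValueError(
            f"cannot place {n_target} lesion voxels: only {len(idx)} "
            f"free candidates in region '{lesion.region}'"
        )
    chosen = rng.choice(idx, size=n_target, replace=False)
    mask.flat[chosen] = True
    out.flat[chosen] += lesion.depth * np.asarray(ref_sd_map).flat[chosen]
    return out, mask


def simulate_pc_cine(
    waveform: np.ndarray,
    vessel_radius_px: float = 4.0,
    venc: float = 120.0,
    grid_shape: tuple[int, int] = (64, 48),
    pixel_area: float = 0.0137,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PhaseContrastCine, list[VesselRoi]]:
    """Simulate a bilateral phase-contrast cine with a known flow waveform.

    Each vessel carries a parabolic through-plane velocity profile scaled
    so that the *discrete* ROI integral equals the requested volumetric
    flow (cm^3/s) in every frame; the recovered flow is therefore exact
    up to phase noise.  A peak velocity beyond venc triggers an aliasing
    warning and the phase is wrapped.
    """
    waveform = np.atleast_1d(np.asarray(waveform, dtype=float))
    nx, ny = grid_shape
    n_frames = len(waveform)
    rng = np.random.default_rng(seed)
    centers = {"left": (nx // 4, ny // 2), "right": (3 * nx // 4, ny // 2)}
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    velocity = np.zeros((nx, ny, n_frames))
    magnitude = np.ones((nx, ny, n_frames))
    rois = []
    for side, (cx, cy) in centers.items():
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        mask = d2 <= vessel_radius_px ** 2
        profile = np.where(mask, 1.0 - d2 / vessel_radius_px ** 2, 0.0)
        weight = profile[mask].sum() * pixel_area  # discrete integral of profile
        for f, q in enumerate(waveform):
            v0 = q / weight
            if abs(v0) > venc:
                warnings.warn(
                    f"peak velocity {v0:.1f} cm/s exceeds venc {venc} cm/s: "
                    "phase aliasing", RuntimeWarning, stacklevel=2,
                )
            velocity[..., f] += v0 * profile
        magnitude[mask, :] = 2.0
        rois.append(VesselRoi(mask=mask, side_label=side))
    phase = np.pi * velocity / venc
    if noise_sd > 0:
        phase = phase + rng.normal(0.0, noise_sd, phase.shape)
    # wrap into (-pi, pi]
    phase = np.angle(np.exp(1j * phase))
    cine = PhaseContrastCine(
        magnitude=magnitude, phase=phase, venc=venc, pixel_area=pixel_area,
    )
    return cine, rois


def simulate_subject_map(
    base_cbf: np.ndarray,
    spec: PhantomSpec,
    atlas: RegionAtlas,
    rng: np.random.Generator,
    subject_id: str,
) -> CbfMap:
    """One subject's CBF map: truth + global offset + voxel variation."""
    offset = rng.normal(0.0, spec.between_subject_sd) \
        if spec.between_subject_sd > 0 else 0.0
    vals = base_cbf + offset
    if spec.voxel_sd > 0:
        vals = vals + rng.normal(0.0, spec.voxel_sd, base_cbf.shape)
    valid = atlas.gm_restriction.copy()
    vals = np.where(valid, vals, np.nan)
    return CbfMap(values=vals, valid_mask=valid, subject_id=subject_id)


def reference_sd_map(spec: PhantomSpec) -> np.ndarray:
    """Theoretical across-subject SD per voxel for lesion-depth scaling."""
    sd = float(np.hypot(spec.between_subject_sd, spec.voxel_sd))
    return np.full(spec.shape, sd)


def simulate_cohort(
    n_per_group: int,
    effect: LesionSpec | dict | None,
    spec: PhantomSpec,
    seed: int,
) -> dict:
    """Simulate a two-group cohort of CBF maps with a controlled effect.

    The control group is drawn effect-free; the test (T2DM) group
    receives either scattered lesions (:class:`LesionSpec`) or uniform
    regional CBF offsets (dict region -> offset).  Covariates are drawn
    from plausible distributions (age ~ 62 +/- 8 y).

    Returns a dict with keys ``maps`` (list of CbfMap), ``cohort``
    (CohortTable), ``atlas``, ``gm``, ``icv``, ``lesion_masks``.
    """
    if n_per_group < 4:
        raise ValueError("n_per_group must be >= 4")
    rng = np.random.default_rng(seed)
    atlas, gm, icv = make_phantom_anatomy(spec)
    base = true_cbf_map(spec, atlas)
    sd_map = reference_sd_map(spec)

    maps: list[CbfMap] = []
    rows = []
    lesion_masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(spec.shape, dtype=bool)
    for grp, prefix in ((False, "ctl"), (True, "t2d")):
        for i in range(n_per_group):
            sid = f"{prefix}{i:03d}"
            subject_base = base
            if grp and effect is not None:
                if isinstance(effect, LesionSpec):
                    subject_base, lmask = inject_lesions(
                        base, sd_map, effect, atlas, rng, occupied=occupied,
                    )
                    if effect.scatter == "non_overlapping":
                        occupied |= lmask
                    lesion_masks[sid] = lmask
                else:
                    subject_base = base.copy()
                    for region, off in effect.items():
                        subject_base[atlas.region_mask(region)] += off
            maps.append(
                simulate_subject_map(subject_base, spec, atlas, rng, sid)
            )
            rows.append({
                "id": sid,
                "group_t2dm": grp,
                "cognition": "high" if (not grp and i < max(3, n_per_group // 2))
                             else "low",
                "age": float(np.clip(rng.normal(62.0, 8.0), 40, 85)),
                "sex": int(rng.integers(0, 2)),
                "atrophy_ml": float(np.clip(rng.normal(30.0, 10.0), 5, 90)),
                "icv_mm3": icv,
                "carotid_flow": float(np.clip(rng.normal(10.6, 2.0), 4, 20)),
                "exclusion_reasons": "",
            })
    return {
        "maps": maps,
        "cohort": CohortTable(pd.DataFrame(rows)),
        "atlas": atlas,
        "gm": gm,
        "icv": icv,
        "lesion_masks": lesion_masks,
    }
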
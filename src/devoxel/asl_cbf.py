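"""Quantitative CBF mapping from 2D multislice pCASL control/label series.

The single-compartment quantification model used throughout is

    CBF = 6000 * lambda * dSI * exp(PLD_z / T1b)
          -------------------------------------------------
          2 * alpha * alpha_inv * T1b * SI_PD * (1 - exp(-tau / T1b))

with ``PLD_z = T_delay + T_slice * (z - 1)`` the effective post-labeling
delay of slice ``z`` (1-based) in a sequential 2D readout.  Acquisition
times are accepted in milliseconds (matching scanner protocol sheets) and
converted to seconds internally so that the factor 6000 yields
ml/100 g/min.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import median_abs_deviation

logger = logging.getLogger(__name__)

__all__ = [
    "AslAcquisition",
    "AslSeries",
    "PerfusionDifference",
    "CbfMap",
    "GmProbabilityMap",
    "split_and_difference",
    "reject_outlier_pairs",
    "effective_pld",
    "quantify_cbf",
    "gm_partial_volume_correct",
]


@dataclass(frozen=True)
class AslAcquisition:
    """Acquisition parameters of a 2D multislice pCASL protocol.

    All times are in milliseconds.  Defaults correspond to a 3T
    pseudo-continuous protocol with background suppression and a 17-slice
    sequential feet-head EPI readout.

    Attributes
    ----------
    lambda_bp : float
        Blood-brain partition coefficient (ml/g).
    alpha : float
        Labeling efficiency, in (0, 1].
    alpha_inv : float
        Background-suppression correction factor, in (0, 1].
    t1_blood : float
        Longitudinal relaxation time of arterial blood (ms).
    t_delay : float
        Post-labeling delay of the first slice (ms).
    t_slice : float
        Acquisition time of a single slice (ms).
    tau : float
        Label duration (ms).
    n_slices : int
        Number of slices in the readout.
    slice_order : sequence of int, optional
        Temporal acquisition index (1-based) of each spatial slice.
        ``None`` means ascending spatial order equals temporal order.
    """

    lambda_bp: float = 0.9
    alpha: float = 0.85
    alpha_inv: float = 0.83
    t1_blood: float = 1650.0
    t_delay: float = 1525.0
    t_slice: float = 35.0
    tau: float = 1650.0
    n_slices: int = 17
    slice_order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("t1_blood", "t_delay", "t_slice", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.alpha_inv <= 1:
            raise ValueError(f"alpha_inv must be in (0, 1], got {self.alpha_inv}")
        if self.lambda_bp <= 0:
            raise ValueError(f"lambda_bp must be > 0, got {self.lambda_bp}")
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.slice_order is not None:
            order = tuple(int(i) for i in self.slice_order)
            if sorted(order) != list(range(1, self.n_slices + 1)):
                raise ValueError(
                    "slice_order must be a permutation of 1..n_slices"
                )
            object.__setattr__(self, "slice_order", order)

    def to_dict(self) -> dict:
        return {
            "lambda_bp": self.lambda_bp,
            "alpha": self.alpha,
            "alpha_inv": self.alpha_inv,
            "t1_blood_ms": self.t1_blood,
            "t_delay_ms": self.t_delay,
            "t_slice_ms": self.t_slice,
            "tau_ms": self.tau,
            "n_slices": self.n_slices,
            "slice_order": list(self.slice_order) if self.slice_order else None,
        }


@dataclass
class AslSeries:
    """Interleaved control/label ASL time series.

    Attributes
    ----------
    volumes : ndarray, shape (x, y, slices, repetitions)
        Raw scanner-unit volumes; repetitions alternate control and label.
    control_first : bool
        If True, even repetition indices (0, 2, ...) are control volumes.
    voxel_dims : tuple of float
        Physical voxel size in mm.
    """

    volumes: np.ndarray
    control_first: bool = True
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 7.0)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError(
                f"expected 4D (x, y, slice, repetition) array, got {self.volumes.ndim}D"
            )
        if self.volumes.shape[-1] % 2 != 0:
            raise ValueError(
                "malformed series: repetition count must be even "
                f"(got {self.volumes.shape[-1]})"
            )
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be > 0, got {self.voxel_dims}")

    @property
    def n_pairs(self) -> int:
        return self.volumes.shape[-1] // 2

    def control_label(self) -> tuple[np.ndarray, np.ndarray]:
        """Split into (control, label) stacks of shape (x, y, slice, pair)."""
        a = self.volumes[..., 0::2]
        b = self.volumes[..., 1::2]
        return (a, b) if self.control_first else (b, a)


@dataclass
class PerfusionDifference:
    """Mean control-minus-label difference plus bookkeeping.

    ``delta_si`` is defined only where ``brain_mask`` is True and is the
    arithmetic mean over ``kept_pairs`` of (control - label).
    """

    delta_si: np.ndarray
    si_pd: np.ndarray
    brain_mask: np.ndarray
    kept_pairs: tuple[int, ...]
    rejected_pairs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        kept, rej = set(self.kept_pairs), set(self.rejected_pairs)
        if kept & rej:
            raise ValueError("kept and rejected pair sets overlap")


@dataclass
class CbfMap:
    """Voxelwise cerebral blood flow in ml/100 g/min.

    ``values`` are finite on ``valid_mask``; voxels outside the mask carry
    NaN.  Negative values are retained (not clipped) so that downstream
    z-statistics remain unbiased.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    gm_corrected: bool = False
    gm_threshold_used: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite CBF values inside valid_mask")

    @property
    def n_negative(self) -> int:
        """Count of negative CBF voxels inside the valid mask (QC metric)."""
        return int(np.sum(self.values[self.valid_mask] < 0))


@dataclass
class GmProbabilityMap:
    """Grey-matter probability per voxel, values in [0, 1]."""

    prob: np.ndarray

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("GM probabilities must lie in [0, 1]")


def split_and_difference(
    series: AslSeries,
    si_pd: np.ndarray,
    brain_mask: np.ndarray | None = None,
) -> PerfusionDifference:
    """Average the control-minus-label difference over all pairs.

    No pair QC is applied here; use :func:`reject_outlier_pairs` for the
    automated outlier rule.

    Parameters
    ----------
    series : AslSeries
        Interleaved control/label series (even repetition count enforced
        at construction).
    si_pd : ndarray
        Proton-density image on the same grid, used downstream to scale
        the difference signal.
    brain_mask : ndarray of bool, optional
        Restrict the difference map to these voxels; default everywhere.
    """
    si_pd = np.asarray(si_pd, dtype=float)
    if si_pd.shape != series.volumes.shape[:3]:
        raise ValueError("si_pd grid does not match series grid")
    if brain_mask is None:
        brain_mask = np.ones(si_pd.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not series.volumes.any():
        warnings.warn("ASL series is all zeros", RuntimeWarning, stacklevel=2)
    control, label = series.control_label()
    delta = (control - label).mean(axis=-1)
    delta = np.where(brain_mask, delta, np.nan)
    return PerfusionDifference(
        delta_si=delta,
        si_pd=si_pd,
        brain_mask=brain_mask,
        kept_pairs=tuple(range(series.n_pairs)),
    )


def reject_outlier_pairs(
    series: AslSeries,
    si_pd: np.ndarray,
    k: float = 3.0,
    brain_mask: np.ndarray | None = None,
) -> PerfusionDifference:
    """Robust automated control-label pair QC.

    A pair is rejected when its whole-volume mean absolute difference
    deviates from the median over pairs by more than ``k`` times the
    SD-consistent MAD (scale factor 1.4826).  A zero MAD (e.g. identical
    pairs) yields no rejections.  This is a deterministic surrogate for
    visual inspection of subtraction images.

    Raises
    ------
    ValueError
        If fewer than 4 pairs are supplied, or if every pair would be
        rejected (which demands manual review).
    """
    if series.n_pairs < 4:
        raise ValueError(f"pair QC requires >= 4 pairs, got {series.n_pairs}")
    if brain_mask is None:
        brain_mask = np.ones(series.volumes.shape[:3], dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    control, label = series.control_label()
    diffs = control - label
    # per-pair whole-volume mean |difference| inside the brain mask
    scores = np.abs(diffs[brain_mask]).mean(axis=0)
    med = np.median(scores)
    mad = median_abs_deviation(scores, scale="normal")
    if mad == 0 or not np.isfinite(k):
        rejected: np.ndarray = np.zeros(series.n_pairs, dtype=bool)
    else:
        rejected = np.abs(scores - med) > k * mad
    if rejected.all():
        raise ValueError(
            "all control-label pairs rejected by the MAD rule; "
            "manual review of the series is required"
        )
    kept_idx = tuple(int(i) for i in np.flatnonzero(~rejected))
    rej_idx = tuple(int(i) for i in np.flatnonzero(rejected))
    if rej_idx:
        logger.info(
            "pair QC: rejected %d/%d pairs (indices %s) at k=%.3g",
            len(rej_idx), series.n_pairs, list(rej_idx), k,
        )
    delta = diffs[..., list(kept_idx)].mean(axis=-1)
    delta = np.where(brain_mask, delta, np.nan)
    si_pd = np.asarray(si_pd, dtype=float)
    return PerfusionDifference(
        delta_si=delta,
        si_pd=si_pd,
        brain_mask=brain_mask,
        kept_pairs=kept_idx,
        rejected_pairs=rej_idx,
    )


def effective_pld(slice_index: int, acq: AslAcquisition) -> float:
    """Effective post-labeling delay of a spatial slice, in ms.

    ``PLD_z = T_delay + T_slice * (t - 1)`` where ``t`` is the temporal
    acquisition index of the slice (equal to the 1-based spatial index
    for the default ascending readout).
    """
    if not 1 <= slice_index <= acq.n_slices:
        raise IndexError(
            f"slice_index {slice_index} out of range 1..{acq.n_slices}"
        )
    t = slice_index if acq.slice_order is None else acq.slice_order[slice_index - 1]
    return acq.t_delay + acq.t_slice * (t - 1)


def quantify_cbf(diff: PerfusionDifference, acq: AslAcquisition) -> CbfMap:
    """Convert a perfusion difference map to absolute CBF (ml/100 g/min).

    Applies the single-compartment model with slice-dependent
    post-labeling delay.  Voxels with non-positive proton density are
    excluded from the valid mask; negative CBF values are retained.
    """
    nz = diff.delta_si.shape[2]
    if nz != acq.n_slices:
        raise ValueError(
            f"difference map has {nz} slices but acquisition declares {acq.n_slices}"
        )
    t1b_s = acq.t1_blood / 1000.0
    tau_s = acq.tau / 1000.0
    # per-slice decay compensation; times converted ms -> s
    pld_s = np.array(
        [effective_pld(z, acq) / 1000.0 for z in range(1, nz + 1)]
    )
    decay = np.exp(pld_s / t1b_s)[np.newaxis, np.newaxis, :]
    denom_const = (
        2.0 * acq.alpha * acq.alpha_inv * t1b_s * (1.0 - np.exp(-tau_s / t1b_s))
    )
    valid = diff.brain_mask & (diff.si_pd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = (6000.0 * acq.lambda_bp * diff.delta_si * decay) / (
            denom_const * diff.si_pd
        )
    cbf = np.where(valid, cbf, np.nan)
    n_neg = int(np.sum(cbf[valid] < 0))
    if n_neg:
        logger.info("quantify_cbf: %d negative CBF voxels retained", n_neg)
    return CbfMap(values=cbf, valid_mask=valid)


def gm_partial_volume_correct(
    cbf: CbfMap, gm: GmProbabilityMap, min_gm: float = 0.3
) -> CbfMap:
    """Correct CBF for the grey-matter fraction of each voxel.

    Divides by the GM probability where it is at least ``min_gm``;
    voxels below the cutoff are dropped from the valid mask (dividing by
    a near-zero fraction would only amplify noise).
    """
    if gm.prob.shape != cbf.values.shape:
        raise ValueError(
            f"grid mismatch: cbf {cbf.values.shape} vs gm {gm.prob.shape}"
        )
    keep = cbf.valid_mask & (gm.prob >= min_gm)
    if not keep.any():
        warnings.warn(
            "GM partial-volume correction removed every voxel "
            f"(min_gm={min_gm})", RuntimeWarning, stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(keep, cbf.values / gm.prob, np.nan)
    return CbfMap(
        values=corrected,
        valid_mask=keep,
        gm_corrected=True,
        gm_threshold_used=min_gm,
        subject_id=cbf.subject_id,
    )
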
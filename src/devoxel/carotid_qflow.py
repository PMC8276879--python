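"""Carotid flow quantification from velocity-encoded phase-contrast cine.

Pixel phase is proportional to through-plane velocity up to the encoding
velocity (venc): ``v = venc * phase / pi``.  Flow per cardiac frame is the
velocity integrated over a vessel cross-section ROI, and the reported
value is the time average over the cardiac cycle, in cm^3/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseContrastCine",
    "VesselRoi",
    "FlowResult",
    "phase_to_velocity",
    "frame_flow",
    "time_average_and_combine",
]


@dataclass
class PhaseContrastCine:
    """Magnitude/phase cine covering one cardiac cycle.

    ``phase`` is in radians in [-pi, pi]; frame is the last axis.
    ``pixel_area`` is in cm^2 and ``venc`` in cm/s.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: float = 120.0
    pixel_area: float = 0.0137  # 150/128 x 105/88 mm -> cm^2
    static_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.ndim != 3:
            raise ValueError("expected 3D (x, y, frame) cine arrays")
        if np.any(np.abs(self.phase) > np.pi + 1e-12):
            raise ValueError(
                "phase outside [-pi, pi]; aliasing is not unwrapped"
            )
        if self.venc <= 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")
        if self.pixel_area <= 0:
            raise ValueError(f"pixel_area must be > 0, got {self.pixel_area}")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[-1]


@dataclass
class VesselRoi:
    """Single-vessel cross-section mask on the cine grid."""

    mask: np.ndarray
    side_label: str  # "left" | "right"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError(f"empty ROI mask for side '{self.side_label}'")
        if self.side_label not in ("left", "right"):
            raise ValueError("side_label must be 'left' or 'right'")


@dataclass
class FlowResult:
    """Per-frame, per-side and combined carotid flow in cm^3/s."""

    per_frame_flow: dict[str, np.ndarray]
    side_mean_flow: dict[str, float]
    total_flow: float
    combine: str = "sum"  # "sum" | "mean" over sides
    complete: bool = True

    def as_records(self, subject: str = "") -> list[dict]:
        """Rows for the tabular output (one per side plus the total)."""
        n = len(next(iter(self.per_frame_flow.values())))
        rows = [
            {
                "subject": subject,
                "side": side,
                "mean_flow_cm3_s": self.side_mean_flow[side],
                "total_flow_cm3_s": self.total_flow,
                "n_frames": n,
                "complete": self.complete,
            }
            for side in sorted(self.per_frame_flow)
        ]
        return rows


def phase_to_velocity(cine: PhaseContrastCine) -> np.ndarray:
    """Decode phase to through-plane velocity (cm/s, craniocaudal positive)."""
    return cine.venc * cine.phase / np.pi


def frame_flow(
    velocity: np.ndarray, roi: VesselRoi, pixel_area: float
) -> np.ndarray:
    """Integrate velocity over the vessel cross-section per frame.

    Parameters
    ----------
    velocity : ndarray, shape (x, y, frame)
        Velocity field in cm/s.
    roi : VesselRoi
        Cross-section mask on the (x, y) grid.
    pixel_area : float
        Pixel area in cm^2.

    Returns
    -------
    ndarray of shape (n_frames,) with flow in cm^3/s.
    """
    velocity = np.asarray(velocity, dtype=float)
    if roi.mask.shape != velocity.shape[:2]:
        raise ValueError("ROI mask does not match velocity grid")
    return velocity[roi.mask].sum(axis=0) * pixel_area


def time_average_and_combine(
    per_frame: dict[str, np.ndarray], combine: str = "sum"
) -> FlowResult:
    """Average per-frame flow over the cardiac cycle and combine sides.

    The bilateral total defaults to left + right (configurable to the
    mean).  A missing side yields a result flagged incomplete whose total
    equals the available side.
    """
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")
    if not per_frame:
        raise ValueError("no per-frame flows supplied")
    lengths = {len(np.atleast_1d(v)) for v in per_frame.values()}
    if len(lengths) > 1:
        raise ValueError("sides have differing frame counts")
    means = {
        side: float(np.mean(np.atleast_1d(flows)))
        for side, flows in per_frame.items()
    }
    complete = {"left", "right"} <= set(per_frame)
    if not complete:
        warnings.warn(
            "only one vessel side present; total flow flagged incomplete",
            RuntimeWarning, stacklevel=2,
        )
    vals = list(means.values())
    total = float(np.sum(vals)) if combine == "sum" else float(np.mean(vals))
    return FlowResult(
        per_frame_flow={s: np.atleast_1d(np.asarray(v, float)) for s, v in per_frame.items()},
        side_mean_flow=means,
        total_flow=total,
        combine=combine,
        complete=complete,
    )


def quantify_flow(
    cine: PhaseContrastCine,
    rois: list[VesselRoi],
    combine: str = "sum",
    background_correct: bool = False,
) -> FlowResult:
    """Full cine-to-flow pipeline for one or two vessel ROIs.

    Optionally subtracts the median phase in ``cine.static_mask`` from all
    frames (background phase-offset correction; off by default).  Emits a
    warning when any in-ROI velocity reaches venc, indicating probable
    aliasing.
    """
    phase = cine.phase
    if background_correct:
        if cine.static_mask is None:
            raise ValueError("background correction requested without static_mask")
        offset = np.median(phase[np.asarray(cine.static_mask, bool)])
        phase = np.clip(phase - offset, -np.pi, np.pi)
        cine = PhaseContrastCine(
            magnitude=cine.magnitude, phase=phase,
            venc=cine.venc, pixel_area=cine.pixel_area,
        )
    velocity = phase_to_velocity(cine)
    per_frame: dict[str, np.ndarray] = {}
    for roi in rois:
        if np.any(np.abs(velocity[roi.mask]) >= cine.venc):
            warnings.warn(
                f"velocity at/above venc in ROI '{roi.side_label}': "
                "possible phase aliasing",
                RuntimeWarning, stacklevel=2,
            )
        per_frame[roi.side_label] = frame_flow(velocity, roi, cine.pixel_area)
    return time_average_and_combine(per_frame, combine=combine)
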
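"""Simulation experiments built on the phantom + deviating-voxel stack.

These are the desk-scale calibration and power studies: null coverage of
the z-threshold at finite reference size, and head-to-head power of the
deviating-voxel tally versus the plain ROI-mean t-test for scattered,
non-overlapping lesions.
"""

from __future__ import annotations

import numpy as np

from devoxel.asl_cbf import CbfMap
from devoxel.deviating_voxels import (
    build_reference,
    critical_z,
    flag_and_tally,
    zscore_map,
)
from devoxel.regional_analysis import group_compare, roi_mean_cbf
from devoxel.synthetic_phantom import LesionSpec, PhantomSpec, simulate_cohort

__all__ = ["null_coverage", "deviating_vs_roi_power"]


def null_coverage(
    n_ref: int,
    n_voxels: int,
    z_crit: float | None = None,
    seed: int = 0,
    chunk: int = 100_000,
) -> dict:
    """Fraction of null voxels (un)flagged at a z threshold.

    Reference subjects and one test subject are drawn from the same
    standard normal per voxel; the test subject is scored against the
    empirical reference mean/SD and flagged at ``|z| > z_crit``.  Voxels
    are processed in chunks so memory stays bounded at large ``n_voxels``.
    """
    if z_crit is None:
        z_crit = critical_z(0.99)
    rng = np.random.default_rng(seed)
    flagged = 0
    evaluated = 0
    remaining = n_voxels
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        shape = (m, 1, 1)
        ref = [
            CbfMap(
                values=rng.standard_normal(shape),
                valid_mask=np.ones(shape, bool),
                subject_id=f"r{i}",
            )
            for i in range(n_ref)
        ]
        model = build_reference(ref)
        subject = CbfMap(
            values=rng.standard_normal(shape),
            valid_mask=np.ones(shape, bool),
            subject_id="null_subject",
        )
        zm = zscore_map(subject, model)
        flagged += int(np.sum(np.abs(zm.z[zm.valid_mask]) > z_crit))
        evaluated += int(zm.valid_mask.sum())
    return {
        "n_ref": n_ref,
        "n_voxels": evaluated,
        "z_crit": z_crit,
        "flagged_fraction": flagged / evaluated,
        "unflagged_fraction": 1.0 - flagged / evaluated,
    }


def deviating_vs_roi_power(
    n_rep: int,
    n_per_group: int,
    lesion: LesionSpec | None,
    spec: PhantomSpec,
    seed: int,
    region: str = "whole_cerebrum",
    confidence: float = 0.99,
    alpha: float = 0.05,
) -> dict:
    """Empirical power of the deviating-voxel tally vs the ROI mean.

    Each replicate simulates a fresh cohort (controls double as the
    normative reference, scored leave-one-out), computes per subject the
    negative-tail deviating fraction and the ROI-mean CBF for ``region``,
    and applies the two-sample t-test to both.  Power is the rejection
    rate at ``alpha`` over replicates; with ``lesion=None`` this measures
    type-I error instead.
    """
    z_crit = critical_z(confidence)
    p_dev = np.empty(n_rep)
    p_roi = np.empty(n_rep)
    seeds = np.random.SeedSequence(seed).spawn(n_rep)
    for r in range(n_rep):
        rep_seed = int(seeds[r].generate_state(1)[0])
        sim = simulate_cohort(n_per_group, lesion, spec, seed=rep_seed)
        atlas, icv = sim["atlas"], sim["icv"]
        controls = [m for m in sim["maps"] if m.subject_id.startswith("ctl")]
        model = build_reference(controls)
        dev_frac, roi_mean, grp = [], [], []
        for m in sim["maps"]:
            zm = zscore_map(m, model)
            tally = flag_and_tally(zm, atlas, z_crit, icv, spec.voxel_volume)
            dev_frac.append(tally.fraction(region, "neg"))
            roi_mean.append(float(roi_mean_cbf(m, atlas)[region]))
            grp.append(m.subject_id.startswith("t2d"))
        p_dev[r] = group_compare(dev_frac, grp).p_value
        p_roi[r] = group_compare(roi_mean, grp).p_value
    return {
        "n_rep": n_rep,
        "p_deviating": p_dev,
        "p_roi_mean": p_roi,
        "power_deviating": float(np.mean(p_dev < alpha)),
        "power_roi_mean": float(np.mean(p_roi < alpha)),
    }
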
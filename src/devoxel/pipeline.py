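"""End-to-end orchestration: simulate -> quantify -> deviate -> stats.

A single YAML config drives the run; every stage writes its outputs under
the run directory and contributes to a machine-readable ``report.json``
that records seeds, parameters, exclusions and all statistical results.
Reports contain no wall-clock information, so reruns with an identical
config are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from devoxel import __version__
from devoxel.asl_cbf import (
    AslAcquisition,
    GmProbabilityMap,
    gm_partial_volume_correct,
    quantify_cbf,
    reject_outlier_pairs,
)
from devoxel.deviating_voxels import (
    build_reference,
    critical_z,
    flag_and_tally,
    zscore_map,
)
from devoxel.io import save_cbf_map, save_nifti
from devoxel.regional_analysis import (
    adjusted_compare,
    group_compare,
    roi_mean_cbf,
    staged_testing,
)
from devoxel.synthetic_phantom import (
    LesionSpec,
    PhantomSpec,
    make_phantom_anatomy,
    reference_sd_map,
    inject_lesions,
    simulate_asl_series,
    simulate_subject_map,
    true_cbf_map,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "cbf", "deviate", "stats")
SUBREGIONS = ("frontal_cortex", "temporal_cortex", "parietal_cortex",
              "occipital_cortex", "subcortical_gm")


@dataclass
class RunConfig:
    """Parsed study configuration (see ``RunConfig.from_yaml``)."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    phantom: dict = field(default_factory=dict)
    n_per_group: int = 6
    lesion: dict | None = None
    acquisition: dict = field(default_factory=dict)
    min_gm: float = 0.3
    outlier_k: float = 3.0
    confidence: float = 0.99
    covariates: tuple[str, ...] = ("age", "sex")
    alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            out_dir=Path(raw.get("out_dir", "run_out")),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            phantom=raw.get("phantom", {}),
            n_per_group=int(raw.get("n_per_group", 6)),
            lesion=raw.get("lesion"),
            acquisition=raw.get("acquisition", {}),
            min_gm=float(raw.get("min_gm", 0.3)),
            outlier_k=float(raw.get("outlier_k", 3.0)),
            confidence=float(raw.get("confidence", 0.99)),
            covariates=tuple(raw.get("covariates", ("age", "sex"))),
            alpha=float(raw.get("alpha", 0.05)),
        )

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "stages": list(self.stages),
            "phantom": self.phantom,
            "n_per_group": self.n_per_group,
            "lesion": self.lesion,
            "acquisition": self.acquisition,
            "min_gm": self.min_gm,
            "outlier_k": self.outlier_k,
            "confidence": self.confidence,
            "covariates": list(self.covariates),
            "alpha": self.alpha,
        }


def _phantom_spec(config: RunConfig) -> PhantomSpec:
    kw = dict(config.phantom)
    if "shape" in kw:
        kw["shape"] = tuple(kw["shape"])
    if "voxel_dims" in kw:
        kw["voxel_dims"] = tuple(kw["voxel_dims"])
    kw.setdefault("seed", config.seed)
    return PhantomSpec(**kw)


def run_study(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write ``report.json``.

    Stage failures abort the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "devoxel_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        fn = {"simulate": _stage_simulate, "cbf": _stage_cbf,
              "deviate": _stage_deviate, "stats": _stage_stats}[stage]
        try:
            report["stages"][stage] = fn(config, state, out)
        except Exception as exc:
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_report(report, out)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    spec = _phantom_spec(config)
    acq_kw = dict(config.acquisition)
    acq_kw.setdefault("n_slices", spec.shape[2])
    acq = AslAcquisition(**acq_kw)
    rng = np.random.default_rng(config.seed)
    atlas, gm, icv = make_phantom_anatomy(spec)
    base = true_cbf_map(spec, atlas)
    sd_map = reference_sd_map(spec)
    lesion = LesionSpec(**config.lesion) if config.lesion else None
    brain = _brain_mask(atlas, gm)

    subjects, rows = {}, []
    occupied = np.zeros(spec.shape, dtype=bool)
    for grp, prefix in ((False, "ctl"), (True, "t2d")):
        for i in range(config.n_per_group):
            sid = f"{prefix}{i:03d}"
            subj_base = base
            if grp and lesion is not None:
                subj_base, lmask = inject_lesions(
                    base, sd_map, lesion, atlas, rng, occupied=occupied)
                if lesion.scatter == "non_overlapping":
                    occupied |= lmask
            truth = simulate_subject_map(subj_base, spec, atlas, rng, sid)
            truth_full = np.where(truth.valid_mask, truth.values, 0.0)
            series, si_pd = simulate_asl_series(
                truth_full, acq, spec, brain_mask=brain, rng=rng)
            subjects[sid] = {"series": series, "si_pd": si_pd, "group_t2dm": grp}
            rows.append({
                "id": sid, "group_t2dm": grp,
                "cognition": "high" if (not grp) else "low",
                "age": float(np.clip(rng.normal(62.0, 8.0), 40, 85)),
                "sex": int(rng.integers(0, 2)),
                "atrophy_ml": float(np.clip(rng.normal(30.0, 10.0), 5, 90)),
                "icv_mm3": icv, "exclusion_reasons": "",
            })
    cohort = pd.DataFrame(rows)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    save_nifti(atlas.labels, out / "atlas.nii", spec.voxel_dims, dtype=np.int16)
    save_nifti(gm.prob, out / "gm.nii", spec.voxel_dims)
    state.update(
        spec=spec, acq=acq, atlas=atlas, gm=gm, icv=icv,
        subjects=subjects, cohort=cohort,
    )
    return {
        "status": "ok", "seed": config.seed, "n_subjects": len(subjects),
        "icv_mm3": icv, "acquisition": acq.to_dict(),
        "lesion": config.lesion,
    }


def _brain_mask(atlas, gm: GmProbabilityMap) -> np.ndarray:
    return (gm.prob > 0) | (atlas.labels > 0)


def _stage_cbf(config: RunConfig, state: dict, out: Path) -> dict:
    if "subjects" not in state:
        raise ValueError("cbf stage requires the simulate stage in this run")
    spec, acq, gm = state["spec"], state["acq"], state["gm"]
    maps, qc = {}, {}
    for sid, rec in state["subjects"].items():
        brain = rec["si_pd"] > 0
        diff = reject_outlier_pairs(
            rec["series"], rec["si_pd"], k=config.outlier_k, brain_mask=brain)
        cbf = quantify_cbf(diff, acq)
        cbf.subject_id = sid
        cbf = gm_partial_volume_correct(cbf, gm, min_gm=config.min_gm)
        maps[sid] = cbf
        qc[sid] = {
            "rejected_pairs": list(diff.rejected_pairs),
            "n_negative_voxels": cbf.n_negative,
        }
        save_cbf_map(cbf, out / f"{sid}_cbf.nii", spec.voxel_dims,
                     sidecar={"acquisition": acq.to_dict(),
                              "kept_pairs": list(diff.kept_pairs),
                              "rejected_pairs": list(diff.rejected_pairs)})
    state["cbf_maps"] = maps
    return {"status": "ok", "n_maps": len(maps), "min_gm": config.min_gm,
            "outlier_k": config.outlier_k, "pair_qc": qc}


def _stage_deviate(config: RunConfig, state: dict, out: Path) -> dict:
    if "cbf_maps" not in state:
        raise ValueError("deviate stage requires the cbf stage in this run")
    spec, atlas, icv = state["spec"], state["atlas"], state["icv"]
    cohort = state["cohort"]
    ref_ids = cohort.loc[
        (~cohort["group_t2dm"]) & (cohort["cognition"] == "high"), "id"
    ].tolist()
    ref_maps = [state["cbf_maps"][s] for s in ref_ids]
    model = build_reference(ref_maps, voxel_dims=spec.voxel_dims)
    z_crit = critical_z(config.confidence)
    records = []
    for sid, cbf in state["cbf_maps"].items():
        zm = zscore_map(cbf, model)
        tally = flag_and_tally(zm, atlas, z_crit, icv, spec.voxel_volume)
        records.append(tally.to_records())
    tallies = pd.concat(records, ignore_index=True)
    tallies.to_csv(out / "tallies.tsv", sep="\t", index=False)
    save_nifti(model.mean_map, out / "reference_mean.nii", spec.voxel_dims)
    save_nifti(model.sd_map, out / "reference_sd.nii", spec.voxel_dims)
    (out / "reference.json").write_text(json.dumps({
        "member_ids": list(model.member_ids), "n_ref": model.n_ref,
        "smoothing_fwhm": model.smoothing_fwhm,
    }, indent=2))
    state["tallies"] = tallies
    return {"status": "ok", "z_crit": z_crit, "n_ref": model.n_ref,
            "reference_ids": ref_ids, "confidence": config.confidence}


def _stage_stats(config: RunConfig, state: dict, out: Path) -> dict:
    if "tallies" not in state:
        raise ValueError("stats stage requires the deviate stage in this run")
    cohort, tallies, atlas = state["cohort"], state["tallies"], state["atlas"]
    merged = tallies.merge(cohort, left_on="subject", right_on="id")

    def region_values(region: str):
        sub = merged[merged["region"] == region]
        return sub["frac_neg_icv_pct"].to_numpy(), sub["group_t2dm"].to_numpy(), sub

    vals, grps, sub = region_values("whole_cerebrum")
    whole = group_compare(vals, grps, region="whole_cerebrum")
    subresults = [
        group_compare(*region_values(r)[:2], region=r) for r in SUBREGIONS
    ]
    staged = staged_testing(whole, subresults, alpha=config.alpha)
    adjusted = None
    if config.covariates:
        cov = sub[list(config.covariates)].reset_index(drop=True)
        adjusted = adjusted_compare(vals, grps, cov, region="whole_cerebrum").to_dict()

    roi_rows = []
    for sid, cbf in state["cbf_maps"].items():
        means = roi_mean_cbf(cbf, atlas)
        roi_rows.append({"subject": sid, **means.to_dict()})
    roi = pd.DataFrame(roi_rows).merge(cohort, left_on="subject", right_on="id")
    roi_whole = group_compare(
        roi["whole_cerebrum"].to_numpy(), roi["group_t2dm"].to_numpy(),
        region="whole_cerebrum")
    result = {
        "status": "ok",
        "deviating_voxels": staged,
        "deviating_voxels_adjusted": adjusted,
        "roi_mean_cbf": roi_whole.to_dict(),
    }
    (out / "stats.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    roi.drop(columns=["id"]).to_csv(out / "roi_means.tsv", sep="\t", index=False)
    return result
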
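"""ROI-mean extraction, exclusion bookkeeping, and staged group statistics.

Exclusion reasons are stage-tagged strings of the form ``"stage:reason"``
with stage ``cbf`` or ``flow``; CBF-stage exclusions propagate to the
flow stage.  Group comparisons are equal-variance two-sample t-tests
(Welch available via flag), and covariate-adjusted comparisons are
ordinary least-squares models ``value ~ group + covariates``.
Sub-region results are gated on whole-cerebrum significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "apply_exclusions",
    "roi_mean_cbf",
    "group_compare",
    "adjusted_compare",
    "staged_testing",
]

STAGES = ("cbf", "flow")


@dataclass
class CohortTable:
    """Subject metadata, covariates and stage-tagged exclusion flags.

    The underlying frame has one row per subject with columns ``id``,
    ``group_t2dm`` (bool), ``cognition`` ('low'|'high'), ``age``, ``sex``
    (0/1), ``atrophy_ml``, ``icv_mm3`` and optional ``carotid_flow``,
    ``depression``.  ``exclusion_reasons`` is a ';'-joined list of
    ``stage:reason`` tags (empty string = included everywhere).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "id" not in df.columns:
            raise ValueError("cohort table requires an 'id' column")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if "exclusion_reasons" not in df.columns:
            df = df.assign(exclusion_reasons="")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def reasons(self, row) -> list[tuple[str, str]]:
        raw = row.exclusion_reasons
        if not isinstance(raw, str) or not raw.strip():
            return []
        out = []
        for tag in raw.split(";"):
            tag = tag.strip()
            if not tag:
                continue
            stage, _, reason = tag.partition(":")
            if stage not in STAGES:
                raise ValueError(
                    f"exclusion tag '{tag}' must be prefixed with a stage in {STAGES}"
                )
            out.append((stage, reason))
        return out

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        if "exclusion_reasons" in df.columns:
            df["exclusion_reasons"] = df["exclusion_reasons"].fillna("")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def apply_exclusions(
    cohort: CohortTable, stage: str
) -> tuple[CohortTable, pd.DataFrame]:
    """Filter the cohort for an analysis stage and report exclusion counts.

    The ``flow`` stage applies the CBF-stage exclusions first and then the
    flow-specific ones.  Returns the included cohort and a per-reason
    count table with columns ``stage``, ``reason``, ``group``, ``n``.
    The operation is idempotent: reapplying a stage to its own output is
    the identity.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage '{stage}'; expected one of {STAGES}")
    active = ("cbf",) if stage == "cbf" else ("cbf", "flow")
    excluded_rows = []
    keep = []
    for row in cohort.frame.itertuples(index=False):
        hits = [(s, r) for s, r in cohort.reasons(row) if s in active]
        if hits:
            grp = "T2DM" if getattr(row, "group_t2dm", False) else "control"
            for s, r in hits:
                excluded_rows.append({"stage": s, "reason": r, "group": grp,
                                      "id": row.id})
            keep.append(False)
        else:
            keep.append(True)
    included = CohortTable(cohort.frame.loc[keep].reset_index(drop=True))
    if excluded_rows:
        report = (
            pd.DataFrame(excluded_rows)
            .groupby(["stage", "reason", "group"], as_index=False)
            .agg(n=("id", "size"))
            .sort_values(["stage", "reason", "group"])
            .reset_index(drop=True)
        )
    else:
        report = pd.DataFrame(columns=["stage", "reason", "group", "n"])
    return included, report


def roi_mean_cbf(cbf, atlas) -> pd.Series:
    """Unweighted mean CBF over valid GM voxels of each atlas region.

    Regions with no valid voxels are reported as NaN; if every region is
    empty the overlap is considered broken and an error is raised.
    """
    means = {}
    any_valid = False
    for name in atlas.report_regions:
        mask = atlas.region_mask(name) & cbf.valid_mask
        if mask.any():
            any_valid = True
            means[name] = float(cbf.values[mask].mean())
        else:
            means[name] = float("nan")
    if not any_valid:
        raise ValueError("no atlas region overlaps the CBF valid mask")
    return pd.Series(means, name="mean_cbf")


@dataclass
class ComparisonResult:
    """Outcome of a two-group comparison, optionally covariate-adjusted."""

    region: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    statistic: float
    p_value: float
    adjusted: tuple[str, ...] = ()
    group_effect: float | None = None
    group_se: float | None = None
    method: str = "student_t"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "group_ns": self.group_ns,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted": list(self.adjusted),
            "group_effect": self.group_effect,
            "group_se": self.group_se,
            "method": self.method,
        }


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.sort(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {list(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 subjects")
    return labels, a, b


def group_compare(
    values, groups, region: str = "", welch: bool = False
) -> ComparisonResult:
    """Independent-samples t-test between two groups (two-sided).

    Uses the equal-variance Student form by default; pass ``welch=True``
    for the unequal-variance form.
    """
    labels, a, b = _split_groups(values, groups)
    if (np.var(a) == 0 and len(a) == 2) or (np.var(b) == 0 and len(b) == 2):
        warnings.warn(
            "a group has zero variance with n=2; t-statistic unstable",
            RuntimeWarning, stacklevel=2,
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(
        region=region,
        group_means={str(labels[0]): float(np.mean(a)),
                     str(labels[1]): float(np.mean(b))},
        group_sds={str(labels[0]): float(np.std(a, ddof=1)),
                   str(labels[1]): float(np.std(b, ddof=1))},
        group_ns={str(labels[0]): int(len(a)), str(labels[1]): int(len(b))},
        statistic=float(t),
        p_value=float(p),
        method="welch_t" if welch else "student_t",
    )


def adjusted_compare(
    values, groups, covariates: pd.DataFrame, region: str = ""
) -> ComparisonResult:
    """OLS model ``value ~ group + covariates``; reports the group effect.

    The group indicator is coded 0/1 over the sorted labels, so the
    effect is (higher label) minus (lower label).  With an
    empty covariate frame this reproduces the pooled-variance t-test.
    """
    labels, a, b = _split_groups(values, groups)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(values)))
    if len(covariates) != len(values):
        raise ValueError("covariate frame length does not match values")
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    g = (groups == labels[1]).astype(float)
    X = pd.DataFrame({"group": g})
    for col in covariates.columns:
        X[col] = pd.to_numeric(covariates[col].to_numpy())
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns "
            f"{list(X.columns)}); check for collinear covariates"
        )
    fit = sm.OLS(values, X).fit()
    return ComparisonResult(
        region=region,
        group_means={str(labels[0]): float(np.mean(a)),
                     str(labels[1]): float(np.mean(b))},
        group_sds={str(labels[0]): float(np.std(a, ddof=1)),
                   str(labels[1]): float(np.std(b, ddof=1))},
        group_ns={str(labels[0]): int(len(a)), str(labels[1]): int(len(b))},
        statistic=float(fit.tvalues["group"]),
        p_value=float(fit.pvalues["group"]),
        adjusted=tuple(covariates.columns),
        group_effect=float(fit.params["group"]),
        group_se=float(fit.bse["group"]),
        method="ols",
    )


def staged_testing(
    whole_cerebrum: ComparisonResult,
    subregions: list[ComparisonResult],
    alpha: float = 0.05,
) -> dict:
    """Gate sub-region results on whole-cerebrum significance.

    Sub-region results are reported only when the whole-cerebrum p-value
    is strictly below ``alpha``; otherwise they are marked not-tested.
    The number of post-hoc tests is always reported.
    """
    gate_open = whole_cerebrum.p_value < alpha
    return {
        "whole_cerebrum": whole_cerebrum.to_dict(),
        "alpha": alpha,
        "gate_open": bool(gate_open),
        "n_posthoc_tests": len(subregions) if gate_open else 0,
        "subregions": (
            [r.to_dict() for r in subregions] if gate_open
            else [{"region": r.region, "status": "not-tested"} for r in subregions]
        ),
    }
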
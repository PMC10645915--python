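"""ROI bias metrics, cohort summaries and paired statistics.

The central quantities are the MRAC-to-CTAC errors of ROI-mean activity,

    relative bias (%) = 100 * (PET_MRAC - PET_CTAC) / PET_CTAC
    absolute bias (%) = 100 * |PET_MRAC - PET_CTAC| / PET_CTAC

computed per (subject, ROI, method, condition).  Cohort aggregation reports
median and interquartile range (linear-interpolation quantiles); method
comparisons are two-sided paired t-tests of absolute bias against the
reference method, corrected for multiple testing with Benjamini-Hochberg
step-up (one call = one family).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ImageVolume, LabelVolume
from .errors import DomainError, EmptyROIError, InsufficientDataError
from .mumaps import DL_DIXON

CSV_COLUMNS = [
    "subject_id",
    "condition",
    "roi_id",
    "roi_name",
    "method",
    "pet_mrac",
    "pet_ctac",
    "relative_bias_pct",
    "absolute_bias_pct",
]


@dataclass(frozen=True)
class BiasRecord:
    """One (subject, ROI, method, condition) bias observation."""

    subject_id: str
    roi_id: str
    roi_name: str
    method: str
    condition: str
    pet_mrac: float
    pet_ctac: float
    relative_bias_pct: float
    absolute_bias_pct: float


@dataclass(frozen=True)
class CohortSummary:
    """Median / IQR of relative bias over subjects for one group."""

    method: str
    roi_id: str
    condition: str
    median_pct: float
    q1_pct: float
    q3_pct: float
    n_subjects: int


@dataclass(frozen=True)
class StatResult:
    """Paired t-test of absolute bias: reference method vs another method."""

    roi_id: str
    condition: str
    comparison: str
    t_statistic: float
    p_value: float
    p_adjusted: float
    n_pairs: int


def roi_mean(
    image: ImageVolume,
    atlas: Optional[LabelVolume] = None,
    roi: int | np.ndarray | None = None,
) -> float:
    """Arithmetic mean of image values over an ROI (label id or boolean mask)."""
    if isinstance(roi, np.ndarray):
        mask = roi.astype(bool)
        if mask.shape != image.grid.shape:
            raise EmptyROIError("ROI mask shape does not match the image grid")
    else:
        if atlas is None:
            raise EmptyROIError("roi_mean needs an atlas when roi is a label id")
        image.grid.require_same(atlas.grid, "image and atlas")
        if roi not in atlas.region_ids:
            raise EmptyROIError(f"atlas has no voxels with label {roi}")
        mask = atlas.labels == roi
    if not mask.any():
        raise EmptyROIError("ROI contains no voxels")
    return float(image.values[mask].mean())


def relative_bias(pet_mrac: float, pet_ctac: float) -> float:
    """Signed MRAC-to-CTAC error in percent."""
    if pet_ctac <= 0:
        raise DomainError(f"reference ROI mean must be > 0, got {pet_ctac}")
    return 100.0 * (pet_mrac - pet_ctac) / pet_ctac


def absolute_bias(pet_mrac: float, pet_ctac: float) -> float:
    """Unsigned MRAC-to-CTAC error in percent; equals |relative_bias|."""
    return abs(relative_bias(pet_mrac, pet_ctac))


def make_record(
    subject_id: str,
    roi_id: str,
    roi_name: str,
    method: str,
    condition: str,
    pet_mrac: float,
    pet_ctac: float,
) -> BiasRecord:
    rel = relative_bias(pet_mrac, pet_ctac)
    return BiasRecord(
        subject_id=str(subject_id),
        roi_id=str(roi_id),
        roi_name=str(roi_name),
        method=method,
        condition=condition,
        pet_mrac=float(pet_mrac),
        pet_ctac=float(pet_ctac),
        relative_bias_pct=rel,
        absolute_bias_pct=abs(rel),
    )


def records_frame(records: Iterable[BiasRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return df[CSV_COLUMNS]


def cohort_summary(records: Sequence[BiasRecord]) -> list[CohortSummary]:
    """Median and (q1, q3) of relative bias per (method, roi, condition)."""
    out: list[CohortSummary] = []
    df = records_frame(records)
    if df.empty:
        return out
    for (method, roi_id, condition), grp in df.groupby(
        ["method", "roi_id", "condition"], sort=True
    ):
        vals = grp["relative_bias_pct"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        out.append(
            CohortSummary(
                method=method,
                roi_id=roi_id,
                condition=condition,
                median_pct=float(med),
                q1_pct=float(q1),
                q3_pct=float(q3),
                n_subjects=len(vals),
            )
        )
    return out


def paired_t_bh(
    records: Sequence[BiasRecord],
    reference_method: str = DL_DIXON,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Paired t-tests of absolute bias vs the reference, BH-adjusted.

    For every (roi, condition) and every non-reference method, a two-sided
    paired t-test compares per-subject absolute bias of that method against
    the reference method.  All p-values produced in one call form a single
    BH family.  Zero-variance difference vectors get p = 1.0 by convention
    (flagged with a warning).
    """
    df = records_frame(records)
    if df.empty:
        return []
    wide = df.pivot_table(
        index=["roi_id", "condition", "subject_id"],
        columns="method",
        values="absolute_bias_pct",
    )
    results: list[tuple] = []
    for (roi_id, condition), grp in wide.groupby(level=["roi_id", "condition"]):
        if reference_method not in grp.columns:
            raise InsufficientDataError(
                f"no records for reference method {reference_method!r}"
            )
        ref = grp[reference_method]
        for method in grp.columns:
            if method == reference_method:
                continue
            pair = pd.concat([ref, grp[method]], axis=1).dropna()
            n = len(pair)
            if n < 3:
                raise InsufficientDataError(
                    f"paired t-test needs >= 3 pairs, got {n} for "
                    f"{method} vs {reference_method} in roi {roi_id}"
                )
            diff = pair.iloc[:, 0].to_numpy() - pair.iloc[:, 1].to_numpy()
            if np.allclose(diff.std(ddof=1), 0.0):
                warnings.warn(
                    f"zero-variance differences for {method} vs {reference_method} "
                    f"(roi {roi_id}, {condition}); p set to 1.0",
                    stacklevel=2,
                )
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(pair.iloc[:, 0], pair.iloc[:, 1])
            results.append(
                (roi_id, condition, f"{reference_method}_vs_{method}", float(t), float(p), n)
            )
    if not results:
        return []
    pvals = np.array([r[4] for r in results])
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        StatResult(
            roi_id=r[0],
            condition=r[1],
            comparison=r[2],
            t_statistic=r[3],
            p_value=r[4],
            p_adjusted=float(min(1.0, max(pa, r[4]))),
            n_pairs=r[5],
        )
        for r, pa in zip(results, p_adj)
    ]


def build_report(
    records: Sequence[BiasRecord],
    summaries: Sequence[CohortSummary],
    stats_results: Sequence[StatResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the tidy CSV, the JSON summary, and boxplot-ready group lists.

    Output is deterministically ordered so reruns are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = records_frame(records).sort_values(CSV_COLUMNS[:5]).reset_index(drop=True)
    csv_path = out / "bias_records.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g", lineterminator="\n")

    groups: dict[str, list[float]] = {}
    for r in sorted(records, key=lambda r: (r.condition, r.roi_id, r.method, r.subject_id)):
        key = f"{r.condition}|{r.roi_id}|{r.method}"
        groups.setdefault(key, []).append(round(r.relative_bias_pct, 10))
    payload = {
        "summaries": [asdict(s) for s in sorted(
            summaries, key=lambda s: (s.condition, s.roi_id, s.method))],
        "stats": [asdict(s) for s in sorted(
            stats_results, key=lambda s: (s.condition, s.roi_id, s.comparison))],
        "boxplot_groups": groups,
    }
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"csv": csv_path, "json": json_path}
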
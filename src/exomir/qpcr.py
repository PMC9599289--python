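"""Censored ΔΔCq relative quantification for RT-qPCR of exosomal miRNA.

The quantification cycle Cq is the PCR cycle at which a well's fluorescence
crosses the calling threshold; lower Cq means more template.  Exosomal miRNA
is scarce, so wells frequently read "Undetermined" (non-detect) or land in the
Cq > 35 background-noise zone.  Discarding those wells would erase exactly the
biology of interest (absence in one cell line), so this module follows the
censoring scheme common in miRNA work:

* wells with Cq strictly above the ceiling (default 35) or with no Cq at all
  are imputed to an arbitrary low-detection value (default 36) and flagged
  censored — they participate in downstream means;
* an assay is called *detectable* in a (cell line, assay) group only when at
  least 20% of its wells sit at Cq ≤ 35; undetectable groups are excluded
  from fold-change estimates but reported;
* samples with no numeric Cq on any assay are dropped outright.

Normalization uses two controls measured in every sample — an endogenous
miRNA (miR-16-5p) and an exogenous spike-in added before RNA extraction
(cel-miR-2-3p) — averaged into a single stable control value, so

    ΔCq(sample, m)  = mean tech-rep Cq of m − mean of the two control means
    ΔΔCq(line, m)   = mean ΔCq in line − mean ΔCq in the reference line
    log2 fold change = −ΔΔCq

Significance is a two-sided Student's t-test (equal variance by default,
Welch optional) on per-biological-sample ΔCq values, with star tiers
* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001.

Arm preference compares the 5p and 3p mature products of one precursor
within a cell line: relative 3p expression = 2^(mean ΔCq_5p − mean ΔCq_3p),
the preferred arm being the one with lower mean ΔCq when the t-test is
significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import mature_family
from .errors import (
    ControlFailedError,
    UnknownSampleError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ENDOGENOUS_CONTROL = "miR-16-5p"
EXOGENOUS_CONTROL = "cel-miR-2-3p"
CONTROL_ASSAYS = (ENDOGENOUS_CONTROL, EXOGENOUS_CONTROL)

CQ_CEILING = 35.0
CQ_IMPUTED = 36.0
MIN_DETECTED_FRACTION = 0.20

TIERS = ("ns", "*", "**", "***")

_REQUIRED_COLUMNS = (
    "sample_id",
    "cell_line",
    "biological_replicate",
    "technical_replicate",
    "assay",
    "cq",
)


@dataclass(frozen=True)
class CqTable:
    """Long-format replicate-level Cq measurements.

    One row per well: (sample_id, cell_line, biological_replicate,
    technical_replicate, assay, cq).  Non-detect wells carry ``cq = NaN`` and
    ``non_detect = True``; the ``censored`` flag records imputation by
    :func:`censor_cq`.  The instrument fluorescence threshold used for Cq
    calling is carried as metadata only — it never enters computation.
    """

    data: pd.DataFrame
    fluorescence_threshold: float = 0.1
    controls: tuple[str, str] = CONTROL_ASSAYS

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"Cq table missing columns: {missing}")
        df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
        if "non_detect" not in df.columns:
            df["non_detect"] = df["cq"].isna()
        if "censored" not in df.columns:
            df["censored"] = False
        numeric = df["cq"].dropna()
        if ((numeric <= 0) | ~np.isfinite(numeric)).any():
            raise ValidationError("numeric Cq values must be finite and > 0")
        if df.duplicated(["sample_id", "assay", "technical_replicate"]).any():
            dupes = df[df.duplicated(["sample_id", "assay", "technical_replicate"])]
            raise ValidationError(
                "duplicate (sample_id, assay, technical_replicate) rows, first: "
                f"{dupes.iloc[0][['sample_id', 'assay', 'technical_replicate']].tolist()}"
            )
        df = df.reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @property
    def assays(self) -> list[str]:
        return sorted(self.data["assay"].unique())

    @property
    def target_assays(self) -> list[str]:
        return [a for a in self.assays if a not in self.controls]

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())


@dataclass(frozen=True)
class DetectabilityReport:
    """Outcome of the detection filter.

    ``detectable`` maps (cell_line, assay) to True/False, or None for groups
    with zero wells (not evaluable).  ``dropped_samples`` lists samples with
    no numeric Cq on any assay.
    """

    detectable: dict[tuple[str, str], bool | None]
    detected_fraction: dict[tuple[str, str], float]
    dropped_samples: tuple[str, ...]

    def is_detectable(self, cell_line: str, assay: str) -> bool:
        return bool(self.detectable.get((cell_line, assay)) or False)


@dataclass(frozen=True)
class QuantResult:
    """Per-(cell line, mature miR) relative quantification outcome."""

    cell_line: str
    mir: str
    mean_delta_cq: float
    log2_fc: float
    p_value: float
    tier: str
    detectable: bool
    one_sided_detection: bool = False
    n_replicates_used: int = 0


@dataclass(frozen=True)
class QuantResults:
    """Collection of :class:`QuantResult` rows for one reference cell line."""

    results: tuple[QuantResult, ...]
    control_cell_line: str

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_line": r.cell_line,
                "mir": r.mir,
                "mean_delta_cq": r.mean_delta_cq,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "tier": r.tier,
                "detectable": r.detectable,
                "one_sided_detection": r.one_sided_detection,
                "n_replicates_used": r.n_replicates_used,
            }
            for r in self.results
        ]
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.sort_values(["cell_line", "mir"]).reset_index(drop=True)
        return frame

    def with_adjusted_pvalues(self, method: str = "fdr_bh") -> pd.DataFrame:
        """Return the result frame with a multiplicity-adjusted p-value column.

        Off by default everywhere else: the headline analysis reports raw
        p-values with star tiers.
        """
        from statsmodels.stats.multitest import multipletests

        frame = self.to_frame()
        mask = frame["p_value"].notna() & (frame["cell_line"] != self.control_cell_line)
        adjusted = pd.Series(np.nan, index=frame.index)
        if mask.any():
            adjusted[mask] = multipletests(frame.loc[mask, "p_value"], method=method)[1]
        frame["p_adjusted"] = adjusted
        return frame


@dataclass(frozen=True)
class ArmComparison:
    """5p-vs-3p preference for one precursor family in one cell line."""

    family: str
    cell_line: str
    rel_expr_3p_vs_5p: float
    p_value: float
    preferred_arm: str  # "5p" | "3p" | "none"
    one_arm_undetected: bool = False
    applicable: bool = True
    n_samples: int = 0


@dataclass(frozen=True)
class SignificanceCollation:
    """Mature miRs significant in ≥1 non-reference cell line."""

    significant: tuple[str, ...]
    membership: dict[str, tuple[str, ...]]


def censor_cq(
    table: CqTable, ceiling: float = CQ_CEILING, imputed: float = CQ_IMPUTED
) -> CqTable:
    """Impute non-detect and above-ceiling wells to ``imputed`` and flag them.

    The ceiling is strict: a well at exactly ``ceiling`` counts as detected and
    is left unchanged, keeping the replacement rule consistent with the
    detection rule (Cq ≤ ceiling).  Idempotent.
    """
    if not ceiling < imputed:
        raise ValidationError(
            f"ceiling ({ceiling}) must be below the imputed value ({imputed})"
        )
    df = table.data.copy()
    mask = df["non_detect"] | (df["cq"] > ceiling)
    df.loc[mask, "cq"] = imputed
    df.loc[mask, "censored"] = True
    return replace(table, data=df)


def detectability_filter(
    table: CqTable,
    min_detected_fraction: float = MIN_DETECTED_FRACTION,
    ceiling: float = CQ_CEILING,
) -> DetectabilityReport:
    """Drop empty samples, then flag (cell line, assay) groups by detection rate.

    A well is *detected* when its Cq is numeric and ≤ ``ceiling`` (censored
    wells sit above the ceiling by construction).  A sample with no numeric Cq
    anywhere (controls included) is dropped.  A group is detectable when its
    detected-well fraction reaches ``min_detected_fraction`` (inclusive).
    """
    if not 0.0 <= min_detected_fraction <= 1.0:
        raise ValidationError(
            f"min_detected_fraction must be in [0, 1], got {min_detected_fraction}"
        )
    df = table.data
    any_numeric = (~df["non_detect"]).groupby(df["sample_id"]).any()
    dropped = tuple(sorted(any_numeric.index[~any_numeric]))
    kept = df[~df["sample_id"].isin(dropped)]

    detected = kept["cq"].notna() & (kept["cq"] <= ceiling)
    grouped = detected.groupby([kept["cell_line"], kept["assay"]])
    fractions = grouped.mean()
    flags: dict[tuple[str, str], bool | None] = {}
    fracs: dict[tuple[str, str], float] = {}
    for key, frac in fractions.items():
        flags[key] = bool(frac >= min_detected_fraction)
        fracs[key] = float(frac)
    return DetectabilityReport(
        detectable=flags, detected_fraction=fracs, dropped_samples=dropped
    )


def control_cq(table: CqTable, sample_id: str) -> float:
    """Stable control value for a sample: mean of the two control-assay means.

    Each control assay is first averaged over its technical replicates
    (censored values participate; uncensored non-detect wells are ignored).  A
    control assay entirely non-detect raises :class:`ControlFailedError`.
    """
    sub = table.data[table.data["sample_id"] == sample_id]
    if sub.empty:
        raise UnknownSampleError(f"sample {sample_id!r} not in Cq table")
    means = []
    for assay in table.controls:
        wells = sub[sub["assay"] == assay]
        if wells.empty or wells["non_detect"].all():
            raise ControlFailedError(sample_id, assay)
        means.append(float(wells["cq"].mean()))
    return float(np.mean(means))


def delta_cq(table: CqTable, sample_id: str, assay: str) -> float:
    """ΔCq of one assay in one sample: mean technical-replicate Cq − control value."""
    sub = table.data[
        (table.data["sample_id"] == sample_id) & (table.data["assay"] == assay)
    ]
    numeric = sub["cq"].dropna()
    if numeric.empty:
        raise ValidationError(
            f"assay {assay!r} has no numeric Cq in sample {sample_id!r}; "
            "censor the table first or check detectability"
        )
    return float(numeric.mean()) - control_cq(table, sample_id)


def significance_tier(p: float) -> str:
    """Star tier for a p-value: *** ≤0.001, ** ≤0.01, * ≤0.05, else ns.

    Boundaries are inclusive and the strongest tier wins.
    """
    if not isinstance(p, (int, float)) or math.isnan(p) or not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value must be in [0, 1], got {p!r}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def students_t_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided t-test returning (t, p); degenerate zero-variance cases are exact.

    With zero variance in both groups the statistic is taken as 0 (p = 1) for
    equal means and ±inf (p = 0) otherwise, matching the limit of the pooled
    formula.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(float("inf"), a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def trim_outliers(values: np.ndarray, min_size: int = 2) -> np.ndarray:
    """Drop values outside median ± 1.5·IQR, never shrinking below ``min_size``.

    Candidates are removed farthest-from-median first (stable order), so the
    result is deterministic.  Distribution-free and symmetric between groups.
    """
    values = np.asarray(values, dtype=float)
    if len(values) <= min_size:
        return values
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    span = 1.5 * (q3 - q1)
    outlier = (values < med - span) | (values > med + span)
    n_removable = min(int(outlier.sum()), len(values) - min_size)
    if n_removable == 0:
        return values
    distance = np.where(outlier, np.abs(values - med), -np.inf)
    order = np.argsort(-distance, kind="stable")
    drop = set(order[:n_removable].tolist())
    keep = np.array([i for i in range(len(values)) if i not in drop])
    return values[keep]


def _sample_delta_frame(
    table: CqTable, dropped_samples: Iterable[str]
) -> pd.DataFrame:
    """Per-(sample, target assay) ΔCq values; control-failed samples excluded."""
    df = table.data[~table.data["sample_id"].isin(set(dropped_samples))]
    df = df.sort_values(
        ["cell_line", "sample_id", "assay", "technical_replicate"]
    )

    ctrl_rows = df[df["assay"].isin(table.controls)]
    failed: set[str] = set()
    all_samples = set(df["sample_id"].unique())
    for assay in table.controls:
        rows = ctrl_rows[ctrl_rows["assay"] == assay]
        nd = rows.groupby("sample_id")["non_detect"].all()
        failed |= set(nd.index[nd])
        failed |= all_samples - set(rows["sample_id"].unique())
    for sample in sorted(failed):
        logger.warning(
            "sample %r excluded: a control assay is missing or entirely non-detect",
            sample,
        )

    ok = df[~df["sample_id"].isin(failed)]
    tech = (
        ok.groupby(["cell_line", "sample_id", "assay"], sort=True)["cq"]
        .mean()
        .reset_index()
    )
    ctrl_means = tech[tech["assay"].isin(table.controls)]
    ctrl_value = ctrl_means.groupby("sample_id")["cq"].mean()
    targets = tech[~tech["assay"].isin(table.controls)].copy()
    targets["delta_cq"] = targets["cq"] - targets["sample_id"].map(ctrl_value)
    return targets.dropna(subset=["delta_cq"]).reset_index(drop=True)


def quantify(
    table: CqTable,
    control_cell_line: str,
    *,
    ceiling: float = CQ_CEILING,
    imputed: float = CQ_IMPUTED,
    min_detected_fraction: float = MIN_DETECTED_FRACTION,
    equal_var: bool = True,
    remove_outliers: bool = True,
) -> QuantResults:
    """Relative quantification of every (cell line, mature miR) vs a reference line.

    Applies censoring and the detectability filter, averages technical
    replicates into per-biological-sample ΔCq, optionally trims outliers per
    (cell line, miR) group, and computes ΔΔCq / log2 fold change with a
    two-sided t-test against the reference line.  A miR undetectable in both
    the target and reference line yields ``detectable=False`` with NaN
    estimates; a miR detectable on exactly one side is quantified using the
    censored (imputed) values on the silent side and flagged
    ``one_sided_detection``.
    """
    censored = censor_cq(table, ceiling=ceiling, imputed=imputed)
    report = detectability_filter(
        censored, min_detected_fraction=min_detected_fraction, ceiling=ceiling
    )
    if control_cell_line not in censored.data["cell_line"].unique():
        raise ValidationError(
            f"control cell line {control_cell_line!r} absent from Cq table"
        )
    deltas = _sample_delta_frame(censored, report.dropped_samples)
    if deltas.empty:
        logger.warning("no target assays with usable ΔCq values; empty result")
        return QuantResults(results=(), control_cell_line=control_cell_line)

    groups = {
        (line, assay): np.asarray(sub["delta_cq"], dtype=float)
        for (line, assay), sub in deltas.groupby(["cell_line", "assay"], sort=True)
    }
    lines = sorted(deltas["cell_line"].unique())
    assays = sorted(deltas["assay"].unique())

    results: list[QuantResult] = []
    for line in lines:
        for assay in assays:
            det_line = report.is_detectable(line, assay)
            det_ctrl = report.is_detectable(control_cell_line, assay)
            line_vals = groups.get((line, assay), np.array([]))
            ctrl_vals = groups.get((control_cell_line, assay), np.array([]))
            if remove_outliers:
                line_vals = trim_outliers(line_vals)
                ctrl_vals = trim_outliers(ctrl_vals)

            if line == control_cell_line:
                if det_ctrl and len(ctrl_vals):
                    results.append(
                        QuantResult(
                            cell_line=line,
                            mir=assay,
                            mean_delta_cq=float(ctrl_vals.mean()),
                            log2_fc=0.0,
                            p_value=1.0,
                            tier="ns",
                            detectable=True,
                            n_replicates_used=len(ctrl_vals),
                        )
                    )
                else:
                    results.append(_not_detectable(line, assay))
                continue

            if (not det_line and not det_ctrl) or not len(line_vals) or not len(ctrl_vals):
                results.append(_not_detectable(line, assay))
                continue

            ddcq = float(line_vals.mean()) - float(ctrl_vals.mean())
            _, p = students_t_test(line_vals, ctrl_vals, equal_var=equal_var)
            tier = significance_tier(p) if not math.isnan(p) else "ns"
            results.append(
                QuantResult(
                    cell_line=line,
                    mir=assay,
                    mean_delta_cq=float(line_vals.mean()),
                    log2_fc=-ddcq,
                    p_value=p,
                    tier=tier,
                    detectable=True,
                    one_sided_detection=det_line != det_ctrl,
                    n_replicates_used=len(line_vals),
                )
            )
    return QuantResults(results=tuple(results), control_cell_line=control_cell_line)


def _not_detectable(line: str, assay: str) -> QuantResult:
    return QuantResult(
        cell_line=line,
        mir=assay,
        mean_delta_cq=float("nan"),
        log2_fc=float("nan"),
        p_value=float("nan"),
        tier="ns",
        detectable=False,
        n_replicates_used=0,
    )


def collate_significant(
    results: QuantResults | Iterable[QuantResult],
    alpha: float = 0.05,
    control_cell_line: str | None = None,
) -> SignificanceCollation:
    """Mature miRs with p ≤ alpha in at least one non-reference cell line.

    Returns the sorted miR list together with a membership map naming the cell
    lines each miR passed in.
    """
    if isinstance(results, QuantResults):
        control_cell_line = control_cell_line or results.control_cell_line
        rows: Iterable[QuantResult] = results.results
    else:
        rows = tuple(results)
    membership: dict[str, set[str]] = {}
    for r in rows:
        if control_cell_line is not None and r.cell_line == control_cell_line:
            continue
        if r.detectable and not math.isnan(r.p_value) and r.p_value <= alpha:
            membership.setdefault(r.mir, set()).add(r.cell_line)
    ordered = {m: tuple(sorted(lines)) for m, lines in sorted(membership.items())}
    return SignificanceCollation(
        significant=tuple(sorted(ordered)), membership=ordered
    )


def arm_preference(
    table: CqTable,
    family: str,
    cell_line: str,
    *,
    ceiling: float = CQ_CEILING,
    imputed: float = CQ_IMPUTED,
    min_detected_fraction: float = MIN_DETECTED_FRACTION,
    alpha: float = 0.05,
    equal_var: bool = True,
    paired: bool = False,
) -> ArmComparison:
    """Compare 5p vs 3p mature-arm expression of one precursor in one cell line.

    Relative 3p expression is 2^(mean ΔCq_5p − mean ΔCq_3p) (5p ≡ 1).  An arm
    entirely non-detect enters through its censored (imputed) ΔCq values and
    the comparison is flagged ``one_arm_undetected``.  Families lacking a 5p
    or 3p assay in the table (single-arm miRs such as miR-429) return an
    explicit not-applicable result.
    """
    assay_5p, assay_3p = f"{family}-5p", f"{family}-3p"
    present = set(table.data["assay"].unique())
    if assay_5p not in present or assay_3p not in present:
        return ArmComparison(
            family=family,
            cell_line=cell_line,
            rel_expr_3p_vs_5p=float("nan"),
            p_value=float("nan"),
            preferred_arm="none",
            applicable=False,
        )

    censored = censor_cq(table, ceiling=ceiling, imputed=imputed)
    report = detectability_filter(
        censored, min_detected_fraction=min_detected_fraction, ceiling=ceiling
    )
    det5 = report.is_detectable(cell_line, assay_5p)
    det3 = report.is_detectable(cell_line, assay_3p)
    deltas = _sample_delta_frame(censored, report.dropped_samples)
    sub = deltas[deltas["cell_line"] == cell_line].set_index(["assay", "sample_id"])

    def arm_values(assay: str) -> pd.Series:
        if assay in sub.index.get_level_values(0):
            return sub.loc[assay]["delta_cq"].sort_index()
        return pd.Series(dtype=float)

    v5, v3 = arm_values(assay_5p), arm_values(assay_3p)
    if (not det5 and not det3) or v5.empty or v3.empty:
        return ArmComparison(
            family=family,
            cell_line=cell_line,
            rel_expr_3p_vs_5p=float("nan"),
            p_value=float("nan"),
            preferred_arm="none",
            one_arm_undetected=True,
            applicable=True,
        )

    mean5, mean3 = float(v5.mean()), float(v3.mean())
    rel = 2.0 ** (mean5 - mean3)
    if paired:
        common = v5.index.intersection(v3.index)
        if len(common) < 2:
            p = float("nan")
        else:
            a, b = v5.loc[common].to_numpy(), v3.loc[common].to_numpy()
            if np.array_equal(a, b):
                p = 1.0
            else:
                p = float(stats.ttest_rel(a, b).pvalue)
    else:
        _, p = students_t_test(v5.to_numpy(), v3.to_numpy(), equal_var=equal_var)
    if not math.isnan(p) and p <= alpha:
        preferred = "5p" if mean5 < mean3 else "3p"
    else:
        preferred = "none"
    return ArmComparison(
        family=family,
        cell_line=cell_line,
        rel_expr_3p_vs_5p=rel,
        p_value=p,
        preferred_arm=preferred,
        one_arm_undetected=det5 != det3,
        applicable=True,
        n_samples=min(len(v5), len(v3)),
    )


def arm_preferences(
    table: CqTable,
    cell_lines: Sequence[str] | None = None,
    families: Sequence[str] | None = None,
    **kwargs,
) -> list[ArmComparison]:
    """Arm comparisons for every two-arm family × cell line in the table."""
    if families is None:
        fams: dict[str, set[str]] = {}
        for assay in table.target_assays:
            fam, arm = mature_family(assay)
            if arm is not None:
                fams.setdefault(fam, set()).add(arm)
        families = sorted(f for f, arms in fams.items() if arms == {"5p", "3p"})
    if cell_lines is None:
        cell_lines = table.cell_lines
    return [
        arm_preference(table, family, line, **kwargs)
        for line in cell_lines
        for family in families
    ]


def collate_arm_preferences(
    comparisons: Iterable[ArmComparison], alpha: float = 0.05
) -> dict[str, tuple[str, ...]]:
    """Families with a significant arm preference in ≥1 cell line."""
    hits: dict[str, set[str]] = {}
    for c in comparisons:
        if c.applicable and not math.isnan(c.p_value) and c.p_value <= alpha:
            hits.setdefault(c.family, set()).add(c.cell_line)
    return {fam: tuple(sorted(lines)) for fam, lines in sorted(hits.items())}
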
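"""End-to-end orchestration: lead identification funnel and quantification run.

The lead-identification funnel mirrors the discovery workflow: start from all
candidate miRNA genes, keep those altered in ≥10% of patients, keep those
with exosomal evidence, optimize a fixed-size panel for patient coverage,
keep panel members with a known disease-differential signal, and expand the
survivors to their mature miRs.  Each stage's input/output counts are
recorded so a run is self-describing; a stage that empties the candidate list
raises :class:`~exomir.errors.EmptyResultError`.

The funnel order is configurable (``funnel_order``) because the differential
filter can equally be read as preceding panel optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .annotation import (
    AnnotationTable,
    expand_to_mature,
    filter_disease_differential,
    filter_exosomal,
)
from .errors import EmptyResultError, ValidationError
from .panel import (
    AlterationMatrix,
    PanelEvaluation,
    filter_genes_by_frequency,
    panel_coverage,
    select_panel,
)
from .qpcr import (
    ArmComparison,
    CqTable,
    QuantResults,
    SignificanceCollation,
    arm_preferences,
    collate_arm_preferences,
    collate_significant,
    quantify,
)

logger = logging.getLogger(__name__)

DEFAULT_FUNNEL_ORDER = ("frequency", "exosomal", "panel", "differential", "mature")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and paths for a full run; defaults are the study constants."""

    matrix_path: str | None = None
    annotation_path: str | None = None
    cq_path: str | None = None
    min_alteration_fraction: float = 0.10
    cq_ceiling: float = 35.0
    cq_imputed: float = 36.0
    min_detected_fraction: float = 0.20
    alpha: float = 0.05
    control_cell_line: str = "HPNE"
    panel_size: int = 18
    exhaustive_limit: int = 100_000
    funnel_order: tuple[str, ...] = DEFAULT_FUNNEL_ORDER
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("min_alteration_fraction", self.min_alteration_fraction, 0.0, 1.0),
            ("min_detected_fraction", self.min_detected_fraction, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ValidationError(f"{name}={value} outside [{lo}, {hi}]")
        if not self.cq_ceiling < self.cq_imputed:
            raise ValidationError("cq_ceiling must be below cq_imputed")
        if self.panel_size < 1:
            raise ValidationError("panel_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "funnel_order" in raw:
            raw["funnel_order"] = tuple(raw["funnel_order"])
        return cls(**raw)

    def header(self) -> dict:
        """All thresholds, for embedding in every report."""
        return {
            "min_alteration_fraction": self.min_alteration_fraction,
            "cq_ceiling": self.cq_ceiling,
            "cq_imputed": self.cq_imputed,
            "min_detected_fraction": self.min_detected_fraction,
            "alpha": self.alpha,
            "control_cell_line": self.control_cell_line,
            "panel_size": self.panel_size,
            "funnel_order": list(self.funnel_order),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    items: tuple[str, ...]


@dataclass(frozen=True)
class LeadReport:
    """Staged candidate funnel with the final panel and mature miR list."""

    stages: tuple[FunnelStage, ...]
    panel: PanelEvaluation
    mature: tuple[str, ...]
    config: PipelineConfig

    @property
    def counts(self) -> list[int]:
        """Funnel sizes: initial candidate count followed by each stage's output."""
        return [self.stages[0].n_in] + [s.n_out for s in self.stages]

    def to_json(self) -> dict:
        return {
            "thresholds": self.config.header(),
            "stages": [
                {"name": s.name, "n_in": s.n_in, "n_out": s.n_out, "items": list(s.items)}
                for s in self.stages
            ],
            "panel": self.panel.to_json(),
            "mature": list(self.mature),
        }


def run_lead_identification(
    matrix: AlterationMatrix,
    annotations: AnnotationTable,
    config: PipelineConfig | None = None,
) -> LeadReport:
    """Run the candidate funnel on an alteration matrix + annotation table."""
    cfg = config or PipelineConfig()
    candidates: list[str] = list(matrix.gene_symbols)
    stages: list[FunnelStage] = []
    panel_eval: PanelEvaluation | None = None
    mature: list[str] = []

    for stage_name in cfg.funnel_order:
        n_in = len(candidates)
        if stage_name == "frequency":
            candidates = filter_genes_by_frequency(matrix, cfg.min_alteration_fraction)
        elif stage_name == "exosomal":
            candidates = filter_exosomal(candidates, annotations)
        elif stage_name == "panel":
            panel_eval = select_panel(
                matrix, cfg.panel_size, candidates, cfg.exhaustive_limit
            )
            candidates = list(panel_eval.panel)
        elif stage_name == "differential":
            candidates = filter_disease_differential(candidates, annotations)
        elif stage_name == "mature":
            mature = expand_to_mature(candidates, annotations)
            candidates = mature
        else:
            raise ValidationError(f"unknown funnel stage {stage_name!r}")
        stages.append(
            FunnelStage(
                name=stage_name,
                n_in=n_in,
                n_out=len(candidates),
                items=tuple(candidates),
            )
        )
        logger.info("funnel stage %s: %d -> %d", stage_name, n_in, len(candidates))
        if not candidates:
            raise EmptyResultError(stage_name)

    if panel_eval is None:
        # funnel order without an optimization stage: score the survivors
        genes = [g for g in stages[-1].items if g in matrix.data.columns] or list(
            stages[-2].items
        )
        panel_eval = panel_coverage(matrix, genes)
    return LeadReport(
        stages=tuple(stages), panel=panel_eval, mature=tuple(mature), config=cfg
    )


@dataclass(frozen=True)
class QuantReport:
    """Quantification + significance collation + arm preferences for one run."""

    results: QuantResults
    collation: SignificanceCollation
    arms: tuple[ArmComparison, ...]
    arm_families: dict[str, tuple[str, ...]]
    config: PipelineConfig

    def to_json(self) -> dict:
        frame = self.results.to_frame()
        return {
            "thresholds": self.config.header(),
            "results": frame.to_dict(orient="records"),
            "significant": list(self.collation.significant),
            "membership": {m: list(v) for m, v in self.collation.membership.items()},
            "arm_families": {f: list(v) for f, v in self.arm_families.items()},
        }


def run_quantification(
    table: CqTable, config: PipelineConfig | None = None
) -> QuantReport:
    """Censor, filter, quantify vs the control line, collate, compare arms."""
    cfg = config or PipelineConfig()
    results = quantify(
        table,
        cfg.control_cell_line,
        ceiling=cfg.cq_ceiling,
        imputed=cfg.cq_imputed,
        min_detected_fraction=cfg.min_detected_fraction,
    )
    collation = collate_significant(results, alpha=cfg.alpha)
    arms = tuple(
        arm_preferences(
            table,
            cell_lines=[l for l in table.cell_lines if l != cfg.control_cell_line],
            ceiling=cfg.cq_ceiling,
            imputed=cfg.cq_imputed,
            min_detected_fraction=cfg.min_detected_fraction,
            alpha=cfg.alpha,
        )
    )
    families = collate_arm_preferences(arms, alpha=cfg.alpha)
    return QuantReport(
        results=results,
        collation=collation,
        arms=arms,
        arm_families=families,
        config=cfg,
    )
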
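"""Reference data from the PDAC exosomal-miRNA biomarker study this package models.

The study screened copy-number alterations of miRNA genes in the UTSW
pancreatic ductal adenocarcinoma cohort (109 patients, staged I–IV), arrived
at an 18-gene panel covering 90% of patients, narrowed it to a 10-gene
diagnostic panel (86/109 patients) whose genes encode 18 mature miRs, and
verified those mature miRs by RT-qPCR of exosomal RNA from three PDAC cell
lines (PANC1, BXPC3, CAPAN2) against the immortalized pancreatic duct line
hTERT-HPNE E6/E7/st ("HPNE").

This module ships those published facts as offline fixtures: the panels, the
per-stage alteration sets of the cohort, the per-gene annotation table
(exosomal evidence, disease-contrast expression directions, mature arms), and
the reported per-cell-line significance calls.  Where the study printed a
p-value only as a tier bound (e.g. "p ≤ 0.05") the fixture stores the bound
itself, marked by ``p_is_bound``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import AnnotationTable, GeneAnnotation
from .qpcr import ArmComparison, QuantResult, significance_tier

#: The 18-gene copy-number panel (altered in ≥10% of patients, exosomal).
PANEL_18 = (
    "MIR27A",
    "MIR31",
    "MIR93",
    "MIR96",
    "MIR122",
    "MIR130B",
    "MIR133A1",
    "MIR203A",
    "MIR210",
    "MIR330",
    "MIR339",
    "MIR425",
    "MIR429",
    "MIR522",
    "MIR590",
    "MIR664A",
    "MIR1208",
    "MIR3620",
)

#: The final 10-gene diagnostic panel.
PANEL_10 = (
    "MIR31",
    "MIR93",
    "MIR133A1",
    "MIR210",
    "MIR330",
    "MIR339",
    "MIR425",
    "MIR429",
    "MIR1208",
    "MIR3620",
)

#: Patients per tumor stage in the UTSW cohort (109 total; all staged).
STAGE_PATIENT_COUNTS = {"I": 7, "II": 94, "III": 6, "IV": 2}

#: Panel genes altered in ≥1 patient of each stage.
STAGE_ALTERED = {
    "I": (
        "MIR27A",
        "MIR31",
        "MIR93",
        "MIR96",
        "MIR122",
        "MIR130B",
        "MIR203A",
        "MIR210",
        "MIR330",
        "MIR339",
        "MIR425",
        "MIR429",
        "MIR3620",
    ),
    "II": PANEL_18,
    "III": (
        "MIR31",
        "MIR93",
        "MIR96",
        "MIR130B",
        "MIR133A1",
        "MIR210",
        "MIR330",
        "MIR429",
        "MIR522",
        "MIR590",
        "MIR1208",
    ),
    "IV": ("MIR27A", "MIR203A", "MIR210", "MIR429", "MIR664A", "MIR1208"),
}

#: The 18 mature miRs encoded by the 10-gene panel.
MATURE_18 = (
    "miR-31-5p",
    "miR-31-3p",
    "miR-93-5p",
    "miR-93-3p",
    "miR-133a-5p",
    "miR-133a-3p",
    "miR-210-5p",
    "miR-210-3p",
    "miR-330-5p",
    "miR-330-3p",
    "miR-339-5p",
    "miR-339-3p",
    "miR-425-5p",
    "miR-425-3p",
    "miR-429",
    "miR-1208",
    "miR-3620-5p",
    "miR-3620-3p",
)

#: Genes down-regulated in chronic pancreatitis vs healthy tissue.
PANCREATITIS_DOWN = (
    "MIR31",
    "MIR96",
    "MIR130B",
    "MIR210",
    "MIR339",
    "MIR429",
    "MIR590",
    "MIR1208",
)

#: Genes up-regulated in PDAC vs chronic pancreatitis.
PDAC_UP = ("MIR27A", "MIR31", "MIR93", "MIR130B", "MIR330")

CELL_LINES = ("HPNE", "PANC1", "BXPC3", "CAPAN2")
CONTROL_CELL_LINE = "HPNE"
PDAC_CELL_LINES = ("PANC1", "BXPC3", "CAPAN2")


def _data_path(name: str):
    return resources.files("exomir.data").joinpath(name)


def load_panel_annotations() -> AnnotationTable:
    """Annotation table for the 18-gene panel, encoding the published evidence."""
    with resources.as_file(_data_path("panel_annotations.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    records = [
        GeneAnnotation(
            symbol=row["symbol"],
            exosomal=bool(int(row["exosomal"])),
            dir_pancreatitis_vs_healthy=row["dir_pancreatitis_vs_healthy"],
            dir_pdac_vs_pancreatitis=row["dir_pdac_vs_pancreatitis"],
            mature_arms=tuple(row["mature_arms"].split(",")),
        )
        for _, row in frame.iterrows()
    ]
    return AnnotationTable(records)


def load_reported_significance() -> list[QuantResult]:
    """Published per-(cell line, mature miR) p-values from the qPCR screen.

    Entries absent from the table were not detected in that cell line.
    ``p_is_bound`` marks values the study reported only as tier bounds.
    """
    with resources.as_file(_data_path("reported_significance.csv")) as path:
        frame = pd.read_csv(path)
    results = []
    for _, row in frame.iterrows():
        p = float(row["p_value"])
        results.append(
            QuantResult(
                cell_line=row["cell_line"],
                mir=row["mir"],
                mean_delta_cq=float("nan"),
                log2_fc=float(row["log2_fc"]) if pd.notna(row["log2_fc"]) else float("nan"),
                p_value=p,
                tier=significance_tier(p),
                detectable=True,
                n_replicates_used=3,
            )
        )
    return results


def load_reported_arm_preferences() -> list[ArmComparison]:
    """Published 5p/3p arm-preference calls per (family, PDAC cell line).

    A blank p-value encodes a comparison reported non-significant without a
    printed number; it never counts as a preference.
    """
    with resources.as_file(_data_path("reported_arm_preferences.csv")) as path:
        frame = pd.read_csv(path)
    comparisons = []
    for _, row in frame.iterrows():
        p = float(row["p_value"]) if pd.notna(row["p_value"]) else float("nan")
        comparisons.append(
            ArmComparison(
                family=row["family"],
                cell_line=row["cell_line"],
                rel_expr_3p_vs_5p=float("nan"),
                p_value=p,
                preferred_arm=row["preferred_arm"],
                one_arm_undetected=bool(int(row["one_arm_undetected"])),
            )
        )
    return comparisons
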
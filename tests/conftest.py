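import numpy as np
import pandas as pd
import pytest

from exomir import AlterationMatrix, AnnotationTable, CqTable, GeneAnnotation
from exomir.qpcr import CONTROL_ASSAYS


@pytest.fixture
def toy_matrix() -> AlterationMatrix:
    """4 patients, 3 genes: g1 alters {p1,p2}, g2 {p3,p4}, g3 {p2,p3}."""
    altered = np.array(
        [
            [1, 0, 0],
            [1, 0, 1],
            [0, 1, 1],
            [0, 1, 0],
        ]
    )
    return AlterationMatrix.from_arrays(
        ["p1", "p2", "p3", "p4"], ["g1", "g2", "g3"], altered, ["I", "II", "II", "unknown"]
    )


@pytest.fixture
def small_annotations() -> AnnotationTable:
    return AnnotationTable(
        [
            GeneAnnotation("MIR31", True, "down", "up", ("miR-31-5p", "miR-31-3p")),
            GeneAnnotation("MIR429", True, "down", "unknown", ("miR-429",)),
            GeneAnnotation("MIR122", True, "none", "none", ("miR-122-5p", "miR-122-3p")),
            GeneAnnotation("MIR522", False, "unknown", "unknown", ("miR-522-5p",)),
            GeneAnnotation("MIR999", True, "unknown", "unknown", ()),
        ]
    )


def make_cq_table(rows) -> CqTable:
    """Rows of (sample_id, cell_line, bio, tech, assay, cq); cq None = non-detect."""
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cell_line",
            "biological_replicate",
            "technical_replicate",
            "assay",
            "cq",
        ],
    )
    return CqTable(data=frame)


def sample_wells(sample_id, line, bio, assay_cqs, n_tech=3):
    """Expand {assay: level} to n_tech identical wells, plus both controls at 20/22."""
    rows = []
    wells = dict(assay_cqs)
    wells.setdefault(CONTROL_ASSAYS[0], 20.0)
    wells.setdefault(CONTROL_ASSAYS[1], 22.0)
    for assay, cq in wells.items():
        for tech in range(1, n_tech + 1):
            rows.append((sample_id, line, bio, tech, assay, cq))
    return rows
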
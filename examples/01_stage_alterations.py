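"""Stage-wise copy-number alteration sets of the reference PDAC cohort.

Rebuilds the 109-patient incidence matrix (stages I-IV), computes which panel
genes are altered in each stage and how stages overlap.  The per-stage counts
show how alteration breadth varies with stage prevalence, and the overlaps
identify genes informative across early and late disease.
"""

from exomir import stage_alteration_sets, stage_overlap, study
from exomir.simulate import table1_matrix

matrix = table1_matrix()
sets = stage_alteration_sets(matrix, list(study.PANEL_18))

for stage in ("I", "II", "III", "IV"):
    genes = sorted(sets.sets[stage])
    print(f"stage {stage:3} ({sets.n_patients[stage]:3d} patients): "
          f"{len(genes):2d} altered genes")

shared_i_iv = sorted(stage_overlap(sets, "I", "IV"))
shared_iii_iv = sorted(stage_overlap(sets, "III", "IV"))
print(f"shared between I and IV  ({len(shared_i_iv)}): {', '.join(shared_i_iv)}")
print(f"shared between III and IV ({len(shared_iii_iv)}): {', '.join(shared_iii_iv)}")
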
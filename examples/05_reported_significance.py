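"""Collating the reference study's published qPCR significance calls.

Loads the shipped fixtures of per-(cell line, mature miR) p-values and
arm-preference calls from the PDAC cell-line screen and collates them:
which mature miRs were significant in at least one PDAC line, which lines
share them, and which precursor families showed a significant arm preference.
"""

from exomir import collate_arm_preferences, collate_significant, study

collation = collate_significant(
    study.load_reported_significance(), control_cell_line=study.CONTROL_CELL_LINE
)
print(f"{len(collation.significant)} significant mature miRs:")
for mir, lines in collation.membership.items():
    print(f"  {mir:12s} in {', '.join(lines)}")

families = collate_arm_preferences(study.load_reported_arm_preferences())
print(f"\n{len(families)} families with a significant arm preference:")
for family, lines in families.items():
    print(f"  {family:9s} in {', '.join(lines)}")
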
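"""Sign-consistency classification of the seven bundled axes.

Rule 1: methylation-expression correlation negative and tumor methylation/
expression calls opposite (the negative-regulation model).  Rule 2: the
allele's predicted risk direction (toward the tumor-like methylation level
=> risk) must match the observed odds-ratio side.
"""

from meqaxis import classify_table, load_reported_axes

verdicts, counts = classify_table(load_reported_axes())
for v in verdicts:
    flag = "PASS" if v.overall else "fail"
    print(f"[{flag}] {v.narrative}")
print(f"\n{counts['pass']} of {len(verdicts)} axes are coherent "
      f"({counts['fail']} fail at least one rule)")
# Only the axes whose allele->methylation->expression->risk signs chain
# consistently survive; the rest are flagged with the rule they break.
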
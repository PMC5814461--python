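"""ADME/T rule filtering of a small ingredient set.

Builds a six-compound descriptor table (one per herb), applies the four
removal rules (solubility < -8, BBB level 3, CYP2D6 inhibition, absorption
level 3) and prints the per-herb retention summary.
"""
from herbnet import DescriptorRecord, FormulaTable, apply_admet_rules, filter_summary

records = [
    DescriptorRecord("SC001", -4.1, 2, False, 1),   # passes every rule
    DescriptorRecord("RS001", -9.3, 1, False, 0),   # extremely low solubility
    DescriptorRecord("SW001", -3.0, 3, False, 1),   # low BBB penetration
    DescriptorRecord("MD001", -2.5, 0, True, 2),    # CYP2D6 inhibitor
    DescriptorRecord("NZ001", -5.0, 2, False, 3),   # very low absorption
    DescriptorRecord("GQ001", -8.0, 2, False, 2),   # exactly -8: retained (strict rule)
]
formula = FormulaTable({r.compound_id[:2]: [r.compound_id] for r in records})

result = apply_admet_rules(records)
print("retained:", result.retained)
print("removed (with reasons):")
for cid, codes in result.removed:
    print(f"  {cid}: {', '.join(codes)}")
print()
print(filter_summary(result, formula))
print()
print("Two of six survive: the filter keeps only compounds violating none of the")
print("four pharmacokinetic red-flag rules; boundary value -8 is kept (strict <).")
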
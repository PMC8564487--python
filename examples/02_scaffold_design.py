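"""Graft the H-2Db scaffold onto two tumor-antigen epitopes and build variants.

Shows the three design moves: anchor grafting, heteroclitic point
substitution at the TCR-facing p4 (including the non-natural residue NAL),
and the 20-member p4 saturation (MIX) library.
"""

from pepscaffold import (
    E7_WT,
    H2DB_ANCHORS,
    TRP2_WT,
    default_registry,
    flag_conservative,
    graft,
    motif_from_display,
    parse_peptide,
    point_substitute,
    saturation_library,
    scaffold_with_point,
)

motif = motif_from_display("xALxNxxxL")
registry = default_registry()

for name, seq in (("E7", E7_WT), ("Trp2", TRP2_WT)):
    wt = parse_peptide(seq)
    result = graft(wt, motif, H2DB_ANCHORS)
    flags = [
        "conservative" if flag_conservative(s) else "non-conservative"
        for s in result.substitutions
    ]
    print(f"{name}: {wt} -> {result.designed}")
    print(f"  anchor substitutions: {', '.join(result.notation)}"
          f"  (BLOSUM62>0 flags: {', '.join(flags)})")

# Heteroclitic p4 variants on the E7 wild type
e7 = parse_peptide(E7_WT)
print("E7 Y4W:", point_substitute(e7, 4, "W").designed)
nal = registry.resolve("1")  # token '1' displays the NAL residue
composite = scaffold_with_point(e7, motif, H2DB_ANCHORS, 4, nal)
print(f"E7-scaff + p4 NAL: {composite.designed} ({','.join(composite.notation)})")

# The MIX library: every natural residue at p4, one member identical to wt
mix = saturation_library(e7, 4)
print(f"MIX library: {len(mix)} members, "
      f"{sum(1 for m in mix.members if not m.substitutions)} identical to wt")
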
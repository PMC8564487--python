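"""Assay arithmetic: ELISpot cross-reactivity, tumor volume, IHC immunoscore.

Builds small synthetic assay tables and runs the standard readout formulas:
spot-forming counts (duplicate mean minus negative control), reactivity
relative to the self-immunogen (=100), caliper volume A*B^2/2, the
(GrzB-FOXP3)/CD3 immunoscore, and specific lysis.
"""

import pandas as pd

from pepscaffold import (
    IhcCounts,
    TumorMeasurement,
    cytotoxicity_percent,
    elispot_report,
    group_summary,
    immunoscore_ratio,
    simulate_elispot,
    tumor_volume,
)

# ELISpot: a group immunized with the E7 wild type, challenged with itself
# and the Y4V heteroclitic variant (intended reactivity 90%).
cross = pd.DataFrame({"E7wt": [90.0], "Y4V": [81.0]}, index=["E7wt"])
records = simulate_elispot(cross, dispersion=0.05, negative_mean=5.0,
                           n_mice=6, seed=1)
report = elispot_report(records)
summary = group_summary(report, grouping=["group", "challenge"], value="reactivity_pct")
print("ELISpot cross-reactivity (mean % of self response +/- SEM):")
for _, row in summary.iterrows():
    print(f"  {row['group']} vs {row['challenge']}: "
          f"{row['mean']:.1f} +/- {row['sem']:.1f} (n={row['n']})")

# Caliper tumor volume
m = TumorMeasurement(A=10.0, B=8.0, day=14)
print(f"tumor volume day {m.day}: {tumor_volume(m):.0f} mm^3 (A=10, B=8)")

# IHC immunoscore on group-mean densities (cells/mm^2)
ratio, label = immunoscore_ratio(IhcCounts("group-mean", "IM",
                                           cd3=103.1, grzb=7.2, foxp3=18.8))
print(f"immunoscore: {ratio:+.4f} -> {label} microenvironment")

# Cytotoxicity with spontaneous-death correction
lysis = cytotoxicity_percent(30, 100, spontaneous_fraction=0.1)
print(f"specific lysis at one E:T ratio: {lysis:.1f}%")
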
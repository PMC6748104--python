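"""Viability normalization and the multi-color competition index.

Two small validation-assay readouts: luminescence viability values are
expressed as fractions of the mean untreated control, and a 1:1
GFP+/mCherry+ co-culture yields a competition index — the treated
GFP/mCherry ratio over the untreated one, where 1.0 means no selective
advantage and 'n.d.' marks wells without mCherry+ outgrowth.
"""

from screenforge import (
    CompetitionMeasurement,
    competition_index,
    normalize_viability,
)

untreated_wells = [10500.0, 9800.0, 10150.0]
treated_wells = [2300.0, 2150.0, 2600.0]
fractions = normalize_viability(treated_wells, untreated_wells)
print("viability fractions after treatment:",
      [round(float(v), 3) for v in fractions])

untreated = CompetitionMeasurement("untreated", pct_gfp=49.0,
                                   pct_mcherry=51.0, is_reference=True)
treated = CompetitionMeasurement("treated", pct_gfp=88.0, pct_mcherry=12.0)
no_outgrowth = CompetitionMeasurement("treated-high-dose", pct_gfp=97.0,
                                      pct_mcherry=0.0)

idx = competition_index(treated, untreated)
print(f"competition index under treatment: {idx:.2f} "
      "(knockout population outgrows control ~7-fold)")
nd = competition_index(no_outgrowth, untreated)
print("high-dose well:", "n.d." if nd is None else f"{nd:.2f}",
      "(no mCherry+ outgrowth)")
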
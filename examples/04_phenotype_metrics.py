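"""Derived clinical quantities: stratification, indices, panel ratios.

All inputs here are plain numbers a study database would hold; the
printed values illustrate each formula once.
"""

from aminoflux import (body_indices, endurance_decline, gold_stage,
                       homa_index, lnaa_ratio, prevalence,
                       stratify_depression)
import pandas as pd

labels = [stratify_depression(s) for s in
          [3, 5, 9, 7, 12, 8, 2, 10, 6, 4]]
print(f"groups from HADS-D (threshold 8): {labels}")
print(f"depression prevalence: {prevalence(labels)}%")

idx = body_indices(80.0, 1.60, fat_mass_kg=32.0, ffm_kg=48.0,
                   alm_kg=21.0)
print(f"BMI {idx['bmi']:.2f}, FMI {idx['fmi']:.2f}, "
      f"FFMI {idx['ffmi']:.2f}, ASMI {idx['asmi']:.2f} kg/m^2")

print(f"HOMA-IR (glucose 5.0 mmol/L, insulin 9.0 uIU/mL): "
      f"{homa_index(5.0, 9.0):.2f}")
print(f"GOLD stage at FEV1 44.6 %pred: {gold_stage(44.6)}")

forces = [100.0] * 3 + [88.0] * 24 + [70.0] * 3
print(f"leg endurance decline over 30 reps: "
      f"{endurance_decline(forces):.2f}")

panel = pd.Series({"conc_Leu": 110.5, "conc_Ile": 65.8, "conc_Val": 177.6,
                   "conc_Tyr": 54.2, "conc_Phe": 48.5, "conc_Trp": 35.8})
print(f"Trp / competitor-LNAA ratio: {lnaa_ratio(panel, 'Trp'):.4f}")
# The ratio proxies tryptophan's access to the blood-brain-barrier
# transporter it shares with the other large neutral amino acids.
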
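"""Score one vessel: tortuosity profile, CSI, SFAR and the two-step rule.

Draws a high-risk-anatomy synthetic centerline (several sharp bends, a
stenotic dip in the lumen), measures it with the geometry pipeline and
classifies the patient for a 6 mm-outer-diameter sheath.
"""

import numpy as np

from iliorisk import Centerline, assess_patient
from iliorisk.simulate import SimulationConfig, patient_rng, simulate_vessel

cfg = SimulationConfig(seed=42)
centerline, plaques, planted = simulate_vessel(
    cfg, patient_rng(cfg, 0), stratum=cfg.high_risk)

assessment = assess_patient(centerline, plaques, sheath_outer_diameter=6.0)
prof, lum = assessment.profile, assessment.lumen

print(f"curves (NOC):          {prof.n_curves}")
print(f"sum of angles (SOA):   {prof.sum_of_angles:.1f} deg")
print(f"max single angle:      {prof.max_angle:.1f} deg")
print(f"minimal lumen (MLD):   {lum.mld:.2f} mm")
print(f"tortuosity index IFT:  {prof.ift:.1f} %")
print(f"CSI = SOA*NOC/MLD:     {assessment.csi:.1f}")
print(f"SFAR = sheath/MLD:     {assessment.sfar:.2f}")
print(f"prediction:            {assessment.predicted} "
      f"(via {assessment.triggering_step}, quadrant {assessment.quadrant})")
print()
print("CSI > 100 or SFAR > 1.00 marks the vessel high risk for an")
print("iliofemoral vascular complication during transfemoral TAVR.")
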
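# iliorisk

Risk assessment of **iliofemoral vascular complications (IVC)** for
transfemoral transcatheter aortic valve replacement (TF-TAVR).

Advancing a large-bore sheath through a calcified, narrow and tortuous
iliofemoral artery is the classic failure mode of transfemoral access.
Current practice screens mainly on the minimal lumen diameter and
eyeballs tortuosity.  `iliorisk` implements a quantitative alternative
for structural-heart teams and methods researchers: it measures vessel
tortuosity and calcification from a 3D centerline, condenses them into
the **Cedars-Sinai Index (CSI)**, applies a two-step classification
rule, and ships the full statistical toolbox used to derive and
validate such a model on patient cohorts — plus a synthetic vessel and
cohort simulator, because no patient CT data can be distributed.

## The model

For a vessel centerline with detected curves,

```
CSI  = SOA × NOC / MLD          high risk when CSI  > 100
SFAR = sheath OD / MLD          high risk when SFAR > 1.00
```

where **SOA** is the sum of curve turn angles (degrees, 0° = straight),
**NOC** the number of curves, **MLD** the minimal lumen diameter (mm)
and *sheath OD* the sheath's outer diameter (mm).  The prediction model
is an ordered rule list — SFAR > 1.00 first, CSI > 100 second, both
strict — and the (SFAR, CSI) plane is split into quadrants QI–QIV to
attribute the anatomical cause of a complication.  Supporting
quantities include the tortuosity index `IFT = (true/ideal length − 1) ×
100`, the calcification categories I–IV from a plaque's perimeter and
lumen occupation fractions (≥ III is the high-risk indicator), and the
plaque-on-a-curve (POC) effect: re-aligning the centerline to the free
lumen shifts a bend's measured angle by up to ~10%, with the sign
determined by which wall the plaque sits on.

## Worked example

```python
from iliorisk import assess_patient
from iliorisk.simulate import SimulationConfig, patient_rng, simulate_vessel

cfg = SimulationConfig(seed=42)
vessel, plaques, _ = simulate_vessel(cfg, patient_rng(cfg, 0),
                                     stratum=cfg.high_risk)
a = assess_patient(vessel, plaques, sheath_outer_diameter=6.0)
print(a.profile.n_curves, round(a.profile.sum_of_angles, 1),
      round(a.lumen.mld, 2), round(a.csi, 1), round(a.sfar, 2),
      a.predicted, a.triggering_step)
```

prints

```
6 168.3 6.2 162.8 0.97 high_risk csi_step
```

six bends summing to 168.3° on a 6.20 mm minimal lumen give CSI 162.8 —
over the 100 cutoff, so the vessel is flagged high risk by the CSI step
even though the 6 mm sheath itself would fit (SFAR 0.97).  The
`examples/` directory has one short script per capability (scoring,
plaque-on-curve, cohort simulation, model derivation/validation), and
the same pipeline is available from the shell:

```
iliorisk score --centerline vessel.csv --sheath-od-mm 6.0
iliorisk simulate --n 2000 --seed 1 --out sim/
iliorisk derive   --cohort sim/cohort.csv --out model.json
iliorisk evaluate --cohort sim/cohort.csv --model model.json
```

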
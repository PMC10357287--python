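"""Plaque-on-a-curve: how a calcified lesion moves the measured angle.

A 45° bend in a 6 mm vessel carries a 1 mm-thick plaque in three
positions.  Re-aligning the centerline to the free lumen (instead of the
outer wall) shifts the bend apex and hence the measured turning angle.
"""

import math

import numpy as np

from iliorisk import Centerline, Plaque, PlaquePosition, poc_angle_effect
from iliorisk.centerline_geometry import detect_curves, turning_angle

# sharp 45° elbow: two 40 mm arms sampled every 1 mm
th = math.radians(45.0)
arm1 = np.outer(np.arange(41.0), [0.0, 0.0, 1.0])
d2 = np.array([math.sin(th), 0.0, math.cos(th)])
arm2 = arm1[-1] + np.outer(np.arange(1.0, 41.0), d2)
vessel = Centerline.from_arrays(np.vstack([arm1, arm2]),
                                np.full(81, 6.0))

curve = detect_curves(vessel)[0]
apex = vessel.arc_lengths()[curve.peak_index]
original = turning_angle(vessel, curve.peak_index)
print(f"wall-aligned bend angle: {original:.2f} deg")

for position in (PlaquePosition.OUTER_WALL, PlaquePosition.INNER_WALL,
                 PlaquePosition.CIRCUMFERENTIAL):
    plaque = Plaque(span=(apex - 8, apex + 8), position=position,
                    perimeter_fraction=0.4, lumen_fraction=0.3,
                    thickness=1.0)
    adjusted, delta = poc_angle_effect(vessel, [plaque], curve)
    print(f"{position.value:16s} free-lumen angle {adjusted:6.2f} deg "
          f"(delta {delta:+.2f} deg)")

print()
print("A plaque opposite the bend sharpens the free-lumen angle, one on")
print("the bend's tip smooths it, and a circumferential ring leaves it")
print("unchanged; the shift stays within ~10% for plaques under 30% of")
print("the lumen radius, and is larger in smaller vessels.")
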
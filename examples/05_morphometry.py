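"""Muscle-shape quantification from traced polygon outlines.

Computes polygon areas (shoelace), the vm2/vm1 relative size, and the
intersection angle between a muscle axis and the vulval slit axis.
"""

import numpy as np

import vmsync as v

vm1 = v.MusclePolygon(
    vertices=np.array([(0, 0), (8, 0), (9, 4), (1, 5)], float),
    muscle_id="vm1_left",
    pixel_size_um=0.26,
)
vm2 = v.MusclePolygon(
    vertices=np.array([(0, 0), (10, 0), (12, 5), (2, 7)], float),
    muscle_id="vm2_left",
    pixel_size_um=0.26,
    attachment_midpoint=(1.0, 0.0),
    tip=(11.0, 6.0),
    slit_axis=(1.0, 0.0),
)

a1, a2 = v.polygon_area(vm1), v.polygon_area(vm2)
print(f"vm1 area: {a1:.2f} um^2")
print(f"vm2 area: {a2:.2f} um^2")
print(f"relative size S_vm2/S_vm1: {v.size_ratio(a2, a1):.2f}")
print(f"vm2 intersection angle with the vulval slit: "
      f"{v.intersection_angle(vm2):.1f} deg")

# Angles are folded into [0, 90] degrees: an intersection of two lines has
# no orientation, so 135 deg and 45 deg describe the same geometry.
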
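"""The AOS sequence and its symbolic alphabet on a focally narrowed angle.

A wedge that looks open (28 degrees) carries a focal anterior iris bump
inside the measurement window.  The distance sequence from the recess
shows a dip that point measurements miss; the run-length alphabet
(/ = increasing, ^ = local minimum, v = local maximum, _ = constant)
summarizes its shape.
"""

import math
from dataclasses import replace

from octangle.angle_metrics import compute_aod, compute_aom, compute_aos, encode_aos
from octangle.phantom import contours_from_truth, render_phantom, wedge_spec

base = wedge_spec(28.0)
slope = math.tan(math.radians(base.cornea_profile.angle_deg)) + math.tan(
    math.radians(base.iris_profile.angle_deg)
)
spec = replace(base, iris_bump=(1000.0, slope * 1000.0 - 120.0, 90.0))
_, truth = render_phantom(spec)
contours = contours_from_truth(truth, spec.scale_um_per_px)

aos = compute_aos(contours)
enc = encode_aos(aos.sequence, scale_um_per_px=spec.scale_um_per_px)
aod = compute_aod(contours)
aom = compute_aom(contours)

print(f"true minimum separation: {truth.min_separation_um:.0f} um -> label {truth.label}")
dips = [v for v, prev, nxt in zip(aos.sequence[1:-1], aos.sequence, aos.sequence[2:])
        if v < prev and v < nxt]
print(f"AOS sequence: {len(aos.sequence)} samples from the apex outward, "
      f"interior dip at {min(dips):.0f} um" if dips else "no interior dip")
print(f"alphabet: {enc.symbols}")
for t in enc.tokens:
    print(f"  {t.symbol}  value {t.value:7.1f} um  indices [{t.start}, {t.end}]")
print(f"AOD = {aod.value:.0f} um (misses the dip), AOM = {aom.value:.0f} um (finds it)")
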
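"""Eligibility screening and the AOD-AOM plausibility partition.

Frames whose traced iris is shorter than 16 px (the 500 um window) or
longer than 70 px (~2.5 mm, anatomically impossible) are excluded before
any population comparison; among the rest, an AOD-AOM difference above
22 px flags an algorithm error rather than anatomy.
"""

from octangle.qc_filters import partition_delta, qc_decision, summarize_cohort

decisions = [
    qc_decision("frame-a", iris_len_px=12),                       # too short
    qc_decision("frame-b", iris_len_px=40, aod_px=13.0, aom_px=6.0),
    qc_decision("frame-c", iris_len_px=55, aod_px=30.0, aom_px=4.0),
    qc_decision("frame-d", iris_len_px=88),                       # too long
    qc_decision("frame-e", iris_len_px=30, aod_px=9.0, aom_px=8.0),
]
for d in decisions:
    extra = ""
    if d.delta_aod_aom_px is not None:
        extra = f"  delta = {d.delta_aod_aom_px:4.1f} px -> {d.delta_class}"
    print(f"{d.frame_id}: iris {d.iris_len_px:2d} px -> {d.status}{extra}")

summary = summarize_cohort(decisions)
print(f"\nremaining after screening: {summary['remaining']} of {summary['total']}")
print(f"excluded: {summary['percent']['too_short']}% too short, "
      f"{summary['percent']['too_long']}% too long")
print("\nboundary check: delta of exactly 22 px is still definitional:",
      partition_delta(22.0, 0.0))
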
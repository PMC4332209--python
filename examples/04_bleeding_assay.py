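"""Tail-bleeding endpoints from start/stop episode records.

Bleeding after tail-tip amputation occurs in start/stop cycles; the
endpoint is the cumulative bleeding time capped at the 20-min
observation window, plus blood loss from the pre/post body-weight
difference.
"""

from thromboflux.bleeding import (BleedEpisode, BleedingRecord, blood_loss,
                                  compare_bleeding, total_bleeding_time)

ko = [
    BleedingRecord("k1", "ko", (BleedEpisode(0, 700), BleedEpisode(760, 1160)),
                   pre_weight_g=23.90, post_weight_g=23.44),
    BleedingRecord("k2", "ko", (BleedEpisode(5, 1040),),
                   pre_weight_g=24.10, post_weight_g=23.72),
    BleedingRecord("k3", "ko", (BleedEpisode(0, 650), BleedEpisode(700, 1060)),
                   pre_weight_g=23.50, post_weight_g=22.96),
]
wt = [
    BleedingRecord("w1", "wt", (BleedEpisode(0, 310),),
                   pre_weight_g=22.90, post_weight_g=22.85),
    BleedingRecord("w2", "wt", (BleedEpisode(0, 420),),
                   pre_weight_g=23.20, post_weight_g=23.08),
    BleedingRecord("w3", "wt", (BleedEpisode(10, 590),),
                   pre_weight_g=24.00, post_weight_g=23.89),
]

for rec in ko + wt:
    print(f"{rec.subject}: bleeding {total_bleeding_time(rec):6.0f} s "
          f"(cap 1200), loss {blood_loss(rec):.2f} g")

report = compare_bleeding(ko, wt)
for endpoint, cmp in report.items():
    print(f"\n{endpoint}: KO {cmp.group_a} vs WT {cmp.group_b}")
    print(f"  t = {cmp.t_test.t_stat:.2f}, p = {cmp.t_test.p_two_sided:.4f}, "
          f"fold = {cmp.effect.fold_ratio_1dp}x")
# A fold-ratio near 2-3x in bleeding time with greater weight loss is
# the hemostasis phenotype expected when platelet adhesion is delayed.
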
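"""Score a listener session with the three nested metrics.

Simulates one synthetic middle-to-older normal-hearing listener and
scores the ten trials.  LC credits a label anywhere in its sequence, OC
requires the right label at the right serial position, SC requires the
whole sequence in order — so SC% <= OC% <= LC% within each condition.
"""

import fest

battery = fest.load_battery()
session = fest.simulate_cohort(fest.default_cohort("MON", 1, seed=5), battery)[0]
report = fest.score_session(session, battery)

print(f"listener {report.listener_id} ({report.group})")
print(f"{'metric':<4} {'coherent':>10} {'incoherent':>12}")
for metric, vals in (("LC", report.lc_pct), ("OC", report.oc_pct), ("SC", report.sc_pct)):
    print(f"{metric:<4} {vals['coherent']:>9.1f}% {vals['incoherent']:>11.1f}%")
# the coherent-sequence advantage is the context effect the test measures

print("\nserial-position OC accuracy (positions 1-5):")
for cond, row in report.serial_position.items():
    print(f"  {cond:<11}", " ".join(f"{v:.2f}" for v in row))

print(f"\nmean coherence rating: coherent {report.mean_rating['coherent']:.2f}, "
      f"incoherent {report.mean_rating['incoherent']:.2f}")
print(f"arcsine-transformed OC (radians): coherent {report.oc_asin['coherent']:.4f}, "
      f"incoherent {report.oc_asin['incoherent']:.4f}")
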
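"""The benefit rules engine: hours, qualitative criteria, dementia premium.

Classifies a handful of assessed care needs into the seven allowance levels
and prints the monthly payout for each. Levels 1-4 depend on assessed hours
alone; levels 5-7 additionally require a qualitative criterion; dementia
adds an automatic 40 h/month to the assessed need before classification.
"""

from ltcsim import CareNeed, classify_need, payout, total_hours

cases = [
    CareNeed(50.0),
    CareNeed(80.0),
    CareNeed(60.0, dementia=True),
    CareNeed(165.0),
    CareNeed(200.0),
    CareNeed(200.0, flags=frozenset({"extraordinary_care"})),
    CareNeed(200.0, flags=frozenset({"no_purposeful_movements"})),
]

print(f"{'base h':>7} {'dementia':>8} {'flags':>28} {'total h':>8} "
      f"{'level':>5} {'EUR/month':>10}")
for need in cases:
    level = classify_need(need)
    print(
        f"{need.base_hours:7.0f} {str(need.dementia):>8} "
        f"{','.join(sorted(need.flags)) or '-':>28} {total_hours(need):8.0f} "
        f"{level:5d} {payout(level):10.2f}"
    )

# A person with 60 base hours and dementia is assessed at 100 h and lands in
# level 2 (370.30 EUR/month); 200 h without any qualitative criterion stays
# at level 4 even though the level 5-7 hour bound is met.
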
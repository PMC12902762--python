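"""One adaptive screening session, answered item by item.

The respondent is distressed and anxious but has no other symptoms: the
gateway screener is positive, only the anxiety gate opens, and Tier 3
presents just the five remaining GAD-7 items (the two gate items carry
over into the full score).
"""

import tierscreen as ts

battery = ts.default_battery()
session = ts.start_session(battery, session_id="example")

# Tier 1: moderate distress on every RHS-13 item -> score 26, above cutoff 11
session.submit_responses({i: 2 for i in session.pending_items()})

# Tier 2: all four short gates at zero except GAD-2 = 3 + 3
answers = {i: 0 for i in session.pending_items()}
for iid in battery.short_form_maps["gad2"].item_ids:
    answers[iid] = 3
session.submit_responses(answers)

print("Tier-3 items presented:", ", ".join(session.pending_items()))

# Tier 3: the remaining five GAD-7 items, all 1 -> full score 3+3+5 = 11
session.submit_responses({i: 1 for i in session.pending_items()})

result = session.finalize()
for d in ts.DISORDERS:
    o = result.outcomes[d]
    print(f"{d:<12} screen_positive={o.screen_positive!s:<5} "
          f"gate={o.gate_score} full={o.full_score}")
print(f"items administered: {result.items_administered} "
      f"(burden reduction {ts.burden_reduction(result, battery)}% "
      f"vs the 43-item full-scale baseline)")

# Expected: anxiety positive (full score 11 >= cutoff 10), everything else
# negative; 27 of 56 items administered, a 37.2% reduction in item burden.
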
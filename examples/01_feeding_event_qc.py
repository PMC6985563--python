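"""Screen electronic-feeder events and build adjusted test intake.

Generates feeder records with a known 15% aberrant fraction, applies the
event-level QC rules (1 s < duration < 3600 s, 20 g < amount < 3 kg,
rate < 2 kg/min, all strict), sums daily intakes and prints per-animal
adjusted totals.
"""

import pandas as pd

from mwgwas import (
    adjusted_test_intake,
    daily_intake,
    filter_events,
    pen_day_flags,
    simulate_feeding_events,
)

events, truth = simulate_feeding_events(
    n_animals=12, n_days=10, aberrant_fraction=0.15, seed=42
)
retained, rejections = filter_events(events)
print(f"{len(events)} events, {len(retained)} retained, {len(rejections)} rejected")
print("rejection reasons:", rejections["reasons"].value_counts().to_dict())

flags = pen_day_flags(events)
print(f"pen x day cells flagged: {int(flags['flagged'].sum())} of {len(flags)}")

daily = daily_intake(retained)
meta = pd.DataFrame(
    {
        "animal_id": sorted(events["animal_id"].unique()),
        "gender": ["barrow", "gilt"] * 6,
        "group_pen": "p1",
    }
)
adjusted = adjusted_test_intake(daily, meta, n_days=10)
print(adjusted.totals.head().to_string(index=False))
# adjusted_intake_kg is each animal's 10-day feed intake with fixed effects
# removed and any missing days imputed from its own trajectory
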
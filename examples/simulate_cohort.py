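"""Generate a synthetic march cohort and inspect its structure.

Builds the default study conditions — 55 soldiers, a 475-minute loaded march
starting at 15:11 with four 19-24 minute breaks — and prints the roster
summary plus one soldier's first minutes of sensor data.
"""

import marchphys as mp

dataset = mp.generate_dataset(seed=1)
roster = dataset.roster

print(f"soldiers: {len(roster)}, timeline: {dataset.config.total_minutes} min")
print("\nVO2peak (mL/kg/min) by fitness tertile:")
print(roster.groupby("tertile")["vo2peak"].agg(["count", "mean", "min", "max"]).round(1))

sid = roster["id"].iloc[0]
print(f"\nfirst minutes of soldier {sid}:")
print(dataset.minutes[sid].head(5).round(2).to_string(index=False))
print("\nDropouts (pain-coupled):", sum(dataset.truth.dropout.values()))
# The tertile means should bracket ~54 mL/kg/min and the per-minute rows show
# HR ~130 bpm, BCT rising from ~37.3 degC, and step frequency above 1 Hz.
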
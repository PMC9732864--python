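"""From event logs to biomarker rates, summary table and D_max.

Feeds a small hand-made event log (spike/ripple timestamps within 60 s
epochs) through rate normalization with an artifact exclusion, prints the
per-pathology summary (means over channels that recorded the biomarker,
the descriptive-table convention), and the per-patient maximal-rate
channel with its lesion distance (D_max).
"""

import pandas as pd

from ecogdist import compute_rates, dmax, summarize_rates

events = pd.DataFrame(
    [
        ("P1", "R1", "c1", "spike", t, 60.0) for t in (2.0, 9.5, 14.0, 30.0)
    ]
    + [("P1", "R1", "c2", "spike", 5.0, 60.0)]
    + [("P1", "R1", "c2", "ripple", t, 60.0) for t in (1.0, 8.0)]
    + [("P1", "R1", "c3", "spike", 12.0, 60.0)],
    columns=["patient_id", "recording_id", "channel_id", "event_type", "time_s", "epoch_length_s"],
)
montage = pd.DataFrame(
    {"patient_id": "P1", "recording_id": "R1", "channel_id": ["c1", "c2", "c3", "c4"]}
)
artifacts = montage.iloc[[3]]  # c4 was artefactual and is excluded

rates = compute_rates(events, montage, artifacts=artifacts)
rates["pathology"] = "FCD"
rates["d_edge_mm"] = [4.0, 11.0, 19.0]
print("per-channel rates (events/min):")
print(rates[["channel_id", "spike_rate", "ripple_rate", "d_edge_mm"]].to_string(index=False))

print("\nsummary (means over channels with >=1 event):")
summary = summarize_rates(rates)
print(summary[["pathology", "n_channels", "total_spikes", "mean_spike_rate"]].to_string(index=False))

print("\nD_max (channel with the highest rate per patient):")
print(dmax(rates).to_string(index=False))
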
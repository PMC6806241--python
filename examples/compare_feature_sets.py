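"""Raw 6-axis features vs quaternion attitude features on stair recognition.

Runs the identical leave-one-subject-out pipeline twice — once on raw
accelerometer+gyroscope readings, once on the four estimated quaternion
components — and prints overall accuracy and the stair-class recalls.
Stair ascent/descent share their acceleration statistics but differ in
mean pitch, so attitude features carry the information raw features lose.
"""

from quathar import ClassifierConfig, compare_feature_sets, generate_dataset

recordings = generate_dataset(subjects=4, location="LB", seed=0, time_scale=0.05)
summary, reports = compare_feature_sets(
    recordings,
    ["raw6", "quat4"],
    ClassifierConfig(k=5, n_learners=10, n_rows=1500, seed=0),
    beta=0.1,
    stride=4,
)

cols = ["tag", "n_features", "overall_accuracy_pct",
        "upstairs_recall_pct", "downstairs_recall_pct"]
print(summary[cols].round(1).to_string(index=False))
# Expected direction: quat4 trades a little overall accuracy on the
# standing/walking boundary for a large gain in stair recall — the same
# qualitative picture as on real lower-back recordings.
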
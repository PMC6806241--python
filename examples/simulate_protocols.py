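"""Simulate one subject's scripted activity protocols and look at the data.

Generates the stairs protocol at 50 Hz for one subject, prints how many
samples each activity contributes and the first rows of the 9-axis stream.
Marker activities (wait, turn) exist only to delimit segments and are
removed before classification.
"""

from quathar import generate_protocol_dataset, protocol_3, strip_marker_segments

recordings = generate_protocol_dataset(protocol_3(), subjects=1, location="LB", seed=42)
rec = recordings[0]

print(f"subject {rec.subject}, location {rec.location}, {len(rec)} samples at 50 Hz")
print("\nsamples per label (marker segments included):")
print(rec.data["label"].value_counts().to_string())

clean = strip_marker_segments(rec)
print(f"\nafter stripping markers: {len(clean)} samples, labels "
      f"{sorted(clean.data['label'].unique())}")
print("\nfirst three samples (m/s², rad/s, normalized field):")
print(clean.data[["time", "acc_x", "acc_y", "acc_z", "gyr_z", "mag_x", "label"]]
      .head(3).to_string(index=False))
# Each 'Go up the stairs' segment is ~8 s => ~400 upstairs samples per loop;
# five loops give ~2000 upstairs samples, and the same for downstairs.
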
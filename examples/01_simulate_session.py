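"""Generate a synthetic propofol-anesthesia session with known ground truth.

Builds the default stage timeline (awake -> injection transient ->
suppression -> anesthetized -> recovery) for four channels, writes the
recording in the columnar text format plus the ground-truth coupling table,
and prints the timeline. Every number in the ground truth is exactly what
the generator embedded, so downstream recovery can be scored against it.
"""

from taumod import default_anesthesia_session, generate_session
from taumod import io as tio

spec = default_anesthesia_session(n_channels=4, seed=0, depth=0.8, mod_freq_hz=1.0)
recording, ground_truth = generate_session(spec)

tio.write_recording(recording, "session.tsv")
tio.write_ground_truth(ground_truth, "session_ground_truth.tsv")

print(f"{recording.n_channels} channels x {recording.duration_s:.0f} s at {recording.fs_hz:.0f} Hz")
print("stage timeline (label, start s, end s, true coupling depth):")
for label, (lo, hi) in recording.condition_intervals.items():
    depth = ground_truth.query("channel == 'ch000' and interval == @label")["depth"].iloc[0]
    print(f"  {label:<20s} {lo:6.0f} {hi:6.0f}   depth={depth:.1f}")
print(f"injection marker at {recording.marker_time('injection'):.0f} s")
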
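"""Generate a synthetic scenario and recover its activity from the pose track.

A 10-minute Markov schedule of resting / stationary activity / locomotion
bouts drives both the cage-vibration stream and the camera pose track. The
reference labeler turns the pose track into per-15-s mean head velocities and
class labels; away from bout boundaries they should match the schedule.
"""

from cagevib import SimConfig, label_windows, sample_schedule, synth_pose

config = SimConfig(duration=600.0)
schedule = sample_schedule(config, seed=5)
track = synth_pose(schedule, config, seed=6)
labels = label_windows(track)

print("schedule:")
for bout in schedule.bouts:
    print(f"  {bout.start:6.1f}-{bout.end:6.1f} s  {bout.cls.value}")

print("\nwindow  mean velocity [px/s]  label (true class at window centre)")
for lab in labels:
    true = schedule.class_at(lab.start_time + 7.5).value
    mark = "" if lab.label.value == true else "  <- boundary window"
    print(f"  {lab.index:3d}   {lab.mean_velocity:10.2f}        "
          f"{lab.label.value:<10s} ({true}){mark}")
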
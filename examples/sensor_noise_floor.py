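"""Sensor noise model: simulate a silent cage and verify the closed form.

With no activity at all, the accelerometer still reports white noise of RMS
``noise_density × √bandwidth`` = 190 µg/√Hz × √1248 Hz ≈ 6.7 mg, and the
gyroscope 15 mdps/√Hz × √12106 Hz ≈ 1.65 dps. Every activity-induced
vibration has to be detected against this floor.
"""

import numpy as np

from cagevib import SensorSpec, SimConfig, synth_vibration
from cagevib.sim import ActivityClass, ActivitySchedule, Bout

spec = SensorSpec()
config = SimConfig(duration=60.0, amplitude_scale=0.0, gyro=True)
schedule = ActivitySchedule([Bout(ActivityClass.RESTING, 0.0, 60.0)])
stream = synth_vibration(schedule, config, seed=1)

print(f"closed-form accel noise RMS: {spec.accel_noise_rms * 1e3:.2f} mg")
for axis in ("x", "y", "z"):
    rms = np.sqrt(np.mean(stream.accel(axis) ** 2))
    print(f"  simulated {axis}-axis RMS:  {rms * 1e3:.2f} mg")
print(f"closed-form gyro noise RMS:  {spec.gyro_noise_rms:.3f} dps")
print(f"  simulated x-axis RMS:      {np.sqrt(np.mean(stream.gyro_x**2)):.3f} dps")
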
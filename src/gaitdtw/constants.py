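"""Canonical axis and activity vocabularies shared across the package.

Axis convention for a lower-back (L5) sensor: z = vertical, y = mediolateral,
x = anterior-posterior. Accelerometer channels are in m/s^2, gyroscope
channels in deg/s, sampled at 100 Hz.
"""

ACC_AXES = ("AccX", "AccY", "AccZ")
GYRO_AXES = ("GyroX", "GyroY", "GyroZ")
AXES = ACC_AXES + GYRO_AXES

#: Locomotion classes the recognizer distinguishes, in fixed priority order
#: (used to break exact probability ties during classification).
ACTIVITIES = ("walking", "ascending_stairs", "descending_stairs")

#: Label emitted when no locomotion class reaches a positive probability.
NO_ACTIVITY = "no_selected_activity"

#: Nominal gravity on the vertical accelerometer axis during quiet standing.
GRAVITY_MS2 = 9.81

DEFAULT_SAMPLING_RATE_HZ = 100.0
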
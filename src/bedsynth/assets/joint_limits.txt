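# bedsynth joint rotation limits, version 1
# One joint per line: name limit
# Symmetric per-component bound (radians) on the axis-angle rotation vector,
# used by the joint-limited random-walk pose generator. Values are coarse
# anthropometric ranges; edit freely. Face markers are rigid (0).
pelvis          0.30
left_hip        0.80
right_hip       0.80
spine1          0.25
left_knee       1.20
right_knee      1.20
spine2          0.25
left_ankle      0.50
right_ankle     0.50
spine3          0.25
left_foot       0.30
right_foot      0.30
neck            0.45
left_collar     0.20
right_collar    0.20
head            0.45
left_shoulder   1.00
right_shoulder  1.00
left_elbow      1.20
right_elbow     1.20
left_wrist      0.60
right_wrist     0.60
nose            0.00
left_eye        0.00
right_eye       0.00
left_ear        0.00
right_ear       0.00
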
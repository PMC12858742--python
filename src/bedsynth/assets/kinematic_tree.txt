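# bedsynth kinematic tree, version 1
# One joint per line: name parent offset_x offset_y offset_z
# Offsets in metres, child position relative to parent in the rest pose.
# World frame: right-handed, +z up, pelvis at origin, supine along +x
# (head towards +x, feet towards -x), left side of the body towards +y.
# 22 SMPL-X-compatible body joints plus 5 face marker joints so that the
# 17 COCO person keypoints are a subset of the tree.
pelvis          -               0.00    0.00    0.00
left_hip        pelvis          -0.05   0.09    0.00
right_hip       pelvis          -0.05   -0.09   0.00
spine1          pelvis          0.11    0.00    0.01
left_knee       left_hip        -0.40   0.01    0.00
right_knee      right_hip       -0.40   -0.01   0.00
spine2          spine1          0.12    0.00    0.00
left_ankle      left_knee       -0.42   0.01    0.00
right_ankle     right_knee      -0.42   -0.01   0.00
spine3          spine2          0.12    0.00    0.00
left_foot       left_ankle      -0.06   0.00    0.10
right_foot      right_ankle     -0.06   0.00    0.10
neck            spine3          0.10    0.00    0.01
left_collar     spine3          0.05    0.07    0.01
right_collar    spine3          0.05    -0.07   0.01
head            neck            0.11    0.00    0.02
left_shoulder   left_collar     0.02    0.10    0.00
right_shoulder  right_collar    0.02    -0.10   0.00
left_elbow      left_shoulder   -0.27   0.02    0.00
right_elbow     right_shoulder  -0.27   -0.02   0.00
left_wrist      left_elbow      -0.25   0.01    0.00
right_wrist     right_elbow     -0.25   -0.01   0.00
nose            head            0.03    0.00    0.10
left_eye        head            0.05    0.03    0.09
right_eye       head            0.05    -0.03   0.09
left_ear        head            0.00    0.07    0.04
right_ear       head            0.00    -0.07   0.04
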
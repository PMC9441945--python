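# Baseline small one-stage detector (P5 family, v5.0-style layout).
# Layer rows are [from, repeats, block, args]; channels are scaled by
# width_multiple (rounded to multiples of 8), repeats by depth_multiple.
variant: yolov5s
nc: 4
depth_multiple: 0.33
width_multiple: 0.50
activation: silu

anchors:
  - [10, 13, 16, 30, 33, 23]        # P3/8
  - [30, 61, 62, 45, 59, 119]       # P4/16
  - [116, 90, 156, 198, 373, 326]   # P5/32

backbone:
  - [-1, 1, Focus, [64, 3]]         # 0-P1/2
  - [-1, 1, Conv, [128, 3, 2]]      # 1-P2/4
  - [-1, 3, C3, [128]]
  - [-1, 1, Conv, [256, 3, 2]]      # 3-P3/8
  - [-1, 9, C3, [256]]
  - [-1, 1, Conv, [512, 3, 2]]      # 5-P4/16
  - [-1, 9, C3, [512]]
  - [-1, 1, Conv, [1024, 3, 2]]     # 7-P5/32
  - [-1, 1, SPP, [1024, [5, 9, 13]]]
  - [-1, 3, C3, [1024, false]]      # 9

head:
  - [-1, 1, Conv, [512, 1, 1]]
  - [-1, 1, Upsample, [2]]
  - [[-1, 6], 1, Concat, [1]]
  - [-1, 3, C3, [512, false]]       # 13

  - [-1, 1, Conv, [256, 1, 1]]
  - [-1, 1, Upsample, [2]]
  - [[-1, 4], 1, Concat, [1]]
  - [-1, 3, C3, [256, false]]       # 17 (P3/8)

  - [-1, 1, Conv, [256, 3, 2]]
  - [[-1, 14], 1, Concat, [1]]
  - [-1, 3, C3, [512, false]]       # 20 (P4/16)

  - [-1, 1, Conv, [512, 3, 2]]
  - [[-1, 10], 1, Concat, [1]]
  - [-1, 3, C3, [1024, false]]      # 23 (P5/32)

  - [[17, 20, 23], 1, Detect, [nc, anchors]]
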
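# Four-head lightweight detector: ghost backbone, C3MB+CBAM neck, and an
# extra stride-64 (P6) head formed by a single stride-2 Ghost module
# appended after the P5 output -- PANet depth is unchanged.
variant: yolov5s-ghost-c3mb-cbam-head
nc: 4
depth_multiple: 0.33
width_multiple: 0.50
activation: silu
mb_expansion: 6
mb_attention: cbam

anchors:
  - [19, 27, 44, 40, 38, 94]          # P3/8
  - [96, 68, 86, 152, 180, 137]       # P4/16
  - [140, 301, 303, 264, 238, 542]    # P5/32
  - [436, 615, 739, 380, 925, 792]    # P6/64

backbone:
  - [-1, 1, Focus, [64, 3]]             # 0-P1/2
  - [-1, 1, GhostConv, [128, 3, 2]]     # 1-P2/4
  - [-1, 3, C3Ghost, [128]]
  - [-1, 1, GhostConv, [256, 3, 2]]     # 3-P3/8
  - [-1, 9, C3Ghost, [256]]
  - [-1, 1, GhostConv, [512, 3, 2]]     # 5-P4/16
  - [-1, 9, C3Ghost, [512]]
  - [-1, 1, GhostConv, [1024, 3, 2]]    # 7-P5/32
  - [-1, 1, SPP, [1024, [5, 9, 13]]]
  - [-1, 3, C3MB, [1024, false]]        # 9

head:
  - [-1, 1, GhostConv, [512, 1, 1]]
  - [-1, 1, Upsample, [2]]
  - [[-1, 6], 1, Concat, [1]]
  - [-1, 3, C3MB, [512, false]]         # 13

  - [-1, 1, GhostConv, [256, 1, 1]]
  - [-1, 1, Upsample, [2]]
  - [[-1, 4], 1, Concat, [1]]
  - [-1, 3, C3MB, [256, false]]         # 17 (P3/8)

  - [-1, 1, GhostConv, [256, 3, 2]]
  - [[-1, 14], 1, Concat, [1]]
  - [-1, 3, C3MB, [512, false]]         # 20 (P4/16)

  - [-1, 1, GhostConv, [512, 3, 2]]
  - [[-1, 10], 1, Concat, [1]]
  - [-1, 3, C3MB, [1024, false]]        # 23 (P5/32)

  - [-1, 1, GhostConv, [1024, 3, 2]]    # 24 (P6/64)

  - [[17, 20, 23, 24], 1, Detect, [nc, anchors]]
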
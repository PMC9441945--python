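# Ghost backbone with inverted-residual (MBConvA) CSP stages in the neck.
# The CSP stage following SPP and the four PANet stages are C3MB; the
# attention slot inside each MBConvA is set by mb_attention.
variant: yolov5s-ghost-c3mb-se
nc: 4
depth_multiple: 0.33
width_multiple: 0.50
activation: silu
mb_expansion: 6
mb_attention: se

anchors:
  - [10, 13, 16, 30, 33, 23]
  - [30, 61, 62, 45, 59, 119]
  - [116, 90, 156, 198, 373, 326]

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

  - [[17, 20, 23], 1, Detect, [nc, anchors]]
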
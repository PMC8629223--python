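# Frozen default architecture for 13-individual identification.
#
# Channel widths were fixed once by the deterministic width-calibration
# search (spotid.model_zoo.calibrate_width_config) against a total
# trainable-parameter budget of exactly 1,707,592 (6.51 MB at 4 bytes per
# parameter), under the documented constraints: stem width in [32, 96],
# branch widths in [8, 128], SE reduction ratio in {16, 8, 4}, stage widths
# non-decreasing along the network. Do not edit widths by hand; re-run the
# calibration if the budget changes.
n_classes: 13
input_size: [224, 224]
stem:
  kernel: 11
  out_channels: 72
  stride: 4
  padding: 2
ms1:
  branch_widths: [32, 32, 32, 32]   # kernels 7x7, 5x5, 3x3, 1x1 -> 128 channels
se_reduction_ratio: 16
basic_block: true                   # residual block + SE at 128 channels
ms2:
  branch_widths: [104, 112, 114, 114]  # -> 444 channels into the GAP head
downsample_schedule:
  - {after: stem, kernel: 3, stride: 2, padding: 1}
  - {after: se2, kernel: 3, stride: 2, padding: 1}
  - {after: se3, kernel: 3, stride: 2, padding: 1}
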
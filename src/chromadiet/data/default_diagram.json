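{
  "comment": "Shipped diagram defaults. White points are (l, s) MacLeod-Boynton coordinates; axis scales default to 1.0 (the contrast-equating constants for the stimulus space are device/fundamental-specific and belong to the study configuration).",
  "diagrams": {
    "discrimination": {
      "white_point": [0.699, 0.0233],
      "axis_scale_x": 1.0,
      "axis_scale_y": 1.0,
      "cone_fundamental_tag": "stockman-macleod-johnson-equal-energy"
    },
    "mondrian": {
      "white_point": [0.657, 0.0184],
      "axis_scale_x": 1.0,
      "axis_scale_y": 1.0,
      "cone_fundamental_tag": "smith-pokorny-illuminant-C"
    }
  }
}
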
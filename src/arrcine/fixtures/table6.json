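{
  "name": "subjective_overall_quality",
  "description": "Paired subjective overall image quality (4-point Likert: 1 non-diagnostic .. 4 excellent); rows = reference segmented cine score, columns = real-time compressed-sensing cine score.",
  "n_patients": 71,
  "scale_values": [1, 2, 3, 4],
  "scale_labels": ["1", "2", "3", "4"],
  "better": "higher",
  "counts": [
    [5, 3, 15, 0],
    [5, 6, 21, 0],
    [0, 2, 13, 0],
    [0, 0, 1, 0]
  ]
}
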
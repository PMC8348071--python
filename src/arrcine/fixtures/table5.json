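{
  "name": "eurocmr_artifact_score_bands",
  "description": "Paired modified EuroCMR artifact scores in published bands (0, 1-3, 4-6, 7-10; lower band = fewer artifacts = better); rows = reference segmented cine band, columns = real-time compressed-sensing cine band. Band indices 0..3 are used as the ordinal values since per-patient raw scores are not published.",
  "n_patients": 71,
  "scale_values": [0, 1, 2, 3],
  "scale_labels": ["0", "1-3", "4-6", "7-10"],
  "better": "lower",
  "counts": [
    [1, 1, 0, 0],
    [25, 42, 2, 0],
    [0, 0, 0, 0],
    [0, 0, 0, 0]
  ]
}
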
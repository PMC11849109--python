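{
  "_comment": "Synthetic default vein->territory atlas for phantom work. Label integers are arbitrary parcellation labels, not an anatomical Destrieux assignment; supply a study-specific atlas JSON for real data.",
  "exclusive": {
    "SSS V": [11, 12, 13, 14],
    "SSS H": [21, 22, 23],
    "SS": [31, 32],
    "BVs": [41, 42],
    "ICVs": [51, 52]
  },
  "upstream": {
    "SSS V": ["SSS H"],
    "SS": ["ICVs", "BVs"]
  }
}
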
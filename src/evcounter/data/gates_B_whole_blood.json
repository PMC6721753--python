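[
 {
  "class": "leukocyte",
  "library": "B_whole_blood",
  "criteria": [
   {"channel_role": "nuclear", "feature": "mean_intensity", "cmp": ">", "threshold": 30},
   {"channel_role": "nuclear", "feature": "max_intensity", "cmp": ">", "threshold": 50},
   {"channel_role": "nuclear", "feature": "size_um2", "cmp": ">", "threshold": 16},
   {"channel_role": "CD45", "feature": "mean_intensity", "cmp": ">", "threshold": 30},
   {"channel_role": "CD45", "feature": "max_intensity", "cmp": ">", "threshold": 50},
   {"channel_role": "CD45", "feature": "size_um2", "cmp": "<=", "threshold": 400},
   {"channel_role": "CD61", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD235a", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "extra", "feature": "std_intensity", "cmp": "<=", "threshold": 5}
  ]
 },
 {
  "class": "ldEV",
  "library": "B_whole_blood",
  "criteria": [
   {"channel_role": "nuclear", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD45", "feature": "mean_intensity", "cmp": ">", "threshold": 30},
   {"channel_role": "CD45", "feature": "max_intensity", "cmp": ">", "threshold": 50},
   {"channel_role": "CD45", "feature": "perimeter_px", "cmp": ">", "threshold": 5},
   {"channel_role": "CD45", "feature": "size_um2", "cmp": "<=", "threshold": 150},
   {"channel_role": "CD45", "feature": "eccentricity", "cmp": "<=", "threshold": 0.85},
   {"channel_role": "CD61", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD235a", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "extra", "feature": "std_intensity", "cmp": "<=", "threshold": 5}
  ]
 },
 {
  "class": "platelet",
  "library": "B_whole_blood",
  "criteria": [
   {"channel_role": "CD45", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD61", "feature": "mean_intensity", "cmp": ">", "threshold": 30},
   {"channel_role": "CD61", "feature": "max_intensity", "cmp": ">", "threshold": 50},
   {"channel_role": "CD61", "feature": "perimeter_px", "cmp": ">", "threshold": 5},
   {"channel_role": "CD61", "feature": "size_um2", "cmp": "<=", "threshold": 150},
   {"channel_role": "CD61", "feature": "eccentricity", "cmp": "<=", "threshold": 0.85},
   {"channel_role": "CD235a", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "extra", "feature": "std_intensity", "cmp": "<=", "threshold": 5}
  ]
 },
 {
  "class": "RBC",
  "library": "B_whole_blood",
  "criteria": [
   {"channel_role": "nuclear", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD45", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD61", "feature": "std_intensity", "cmp": "<=", "threshold": 5},
   {"channel_role": "CD235a", "feature": "mean_intensity", "cmp": ">", "threshold": 30},
   {"channel_role": "CD235a", "feature": "max_intensity", "cmp": ">", "threshold": 50},
   {"channel_role": "CD235a", "feature": "perimeter_px", "cmp": ">", "threshold": 5},
   {"channel_role": "extra", "feature": "std_intensity", "cmp": "<=", "threshold": 5}
  ]
 }
]
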
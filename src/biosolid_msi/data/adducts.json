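{
  "positive": [
    {"label": "[M+H]+", "add": {"H": 1}, "charge": 1, "primary": true},
    {"label": "[M+Na]+", "add": {"Na": 1}, "charge": 1, "primary": false},
    {"label": "[M+K]+", "add": {"K": 1}, "charge": 1, "primary": false},
    {"label": "[M+NH4]+", "add": {"N": 1, "H": 4}, "charge": 1, "primary": false}
  ],
  "negative": [
    {"label": "[MCl2]-", "add": {"Cl": 2}, "charge": -1, "primary": true},
    {"label": "[MCl3]-", "add": {"Cl": 3}, "charge": -1, "primary": false}
  ]
}
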
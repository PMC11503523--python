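{
  "notes": "Ca2+-GMT speciation model with overall formation constants (M + L + H = MLH convention; hydroxo species release a proton, r = -1). hydrolysis constants (MOH species) are flagged literature defaults at 25 C, I = 0.1 mol/L, reused at all temperatures; edit to taste. pKw values are literature defaults at I = 0.1 mol/L NaCl (13.97 at 25 C, 13.38 at 37 C, 13.02 at 45 C; 14.49 at 15 C extrapolated van't Hoff-style from the other three), editable inputs.",
  "components": [
    {
      "name": "H",
      "charge": 1
    },
    {
      "name": "GMT",
      "charge": 0
    },
    {
      "name": "Ca",
      "charge": 2
    }
  ],
  "species": [
    {
      "label": "(GMT)H",
      "stoichiometry": {
        "GMT": 1,
        "H": 1
      },
      "log_beta": 3.6
    },
    {
      "label": "Ca(GMT)H",
      "stoichiometry": {
        "Ca": 1,
        "GMT": 1,
        "H": 1
      },
      "log_beta": 6.79
    },
    {
      "label": "CaOH",
      "stoichiometry": {
        "Ca": 1,
        "H": -1
      },
      "log_beta": -12.78
    }
  ],
  "pKw": 13.97,
  "temperature_K": 298.15,
  "ionic_strength_M": 0.1
}
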
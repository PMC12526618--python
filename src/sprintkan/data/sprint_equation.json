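{
  "comment": "Reference closed-form model mapping the nine neuromuscular features (x1-x3: alpha/beta/gamma RA-BF coherence; x4-x6: alpha/beta/gamma TA-GL coherence; x7-x9: iEMG, RMS, MF of rectus femoris) to sprint phase velocity in m/s.",
  "widths": [9, 1],
  "scaler_min": null,
  "scaler_max": null,
  "terms": [
    {"family": "const", "layer": 0, "i": null, "j": 0, "a": 0.0, "b": 0.0, "c": 0.0, "d": 11.085},
    {"family": "x",     "layer": 0, "i": 0,    "j": 0, "a": 1.0, "b": 0.0, "c": -0.0017,   "d": 0.0},
    {"family": "exp",   "layer": 0, "i": 1,    "j": 0, "a": 2.6409, "b": 0.0, "c": 1.168e-05, "d": 0.0},
    {"family": "x",     "layer": 0, "i": 2,    "j": 0, "a": 1.0, "b": 0.0, "c": -0.0002,   "d": 0.0},
    {"family": "exp",   "layer": 0, "i": 3,    "j": 0, "a": 2.6896, "b": 0.0, "c": 3.561e-06, "d": 0.0},
    {"family": "x",     "layer": 0, "i": 4,    "j": 0, "a": 1.0, "b": 0.0, "c": -0.0016,   "d": 0.0},
    {"family": "x",     "layer": 0, "i": 5,    "j": 0, "a": 1.0, "b": 0.0, "c": -0.0036,   "d": 0.0},
    {"family": "x",     "layer": 0, "i": 6,    "j": 0, "a": 1.0, "b": 0.0, "c": 0.2996,    "d": 0.0},
    {"family": "x",     "layer": 0, "i": 7,    "j": 0, "a": 1.0, "b": 0.0, "c": 0.0005,    "d": 0.0},
    {"family": "x",     "layer": 0, "i": 8,    "j": 0, "a": 1.0, "b": 0.0, "c": -0.0006,   "d": 0.0}
  ]
}
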
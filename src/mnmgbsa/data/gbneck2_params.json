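{
  "version": "gbneck2-1",
  "offset": 0.195141,
  "neck_scale": 0.826836,
  "probe_radius": 1.4,
  "elements": {
    "H": {"alpha": 0.788440, "beta": 0.798699, "gamma": 0.437334, "screen": 1.425952},
    "C": {"alpha": 0.733756, "beta": 0.506378, "gamma": 0.205844, "screen": 1.058554},
    "N": {"alpha": 0.503364, "beta": 0.316828, "gamma": 0.192915, "screen": 0.733599},
    "O": {"alpha": 0.867814, "beta": 0.876635, "gamma": 0.387882, "screen": 1.061039},
    "S": {"alpha": 0.867814, "beta": 0.876635, "gamma": 0.387882, "screen": -0.703469},
    "default": {"alpha": 1.0, "beta": 0.8, "gamma": 4.85, "screen": 0.5}
  },
  "mbondi3": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.5,
    "S": 1.8,
    "P": 1.85,
    "default": 1.5
  }
}
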
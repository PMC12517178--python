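{
  "comment": "Nearest-neighbour electrode pairs on the 19-channel 10-20 layout, used for bad-channel interpolation. Symmetric by construction.",
  "neighbors": {
    "FP1": ["F7", "F3", "Fz", "FP2"],
    "FP2": ["F8", "F4", "Fz", "FP1"],
    "F7": ["FP1", "F3", "T3"],
    "F3": ["FP1", "F7", "Fz", "C3"],
    "Fz": ["FP1", "FP2", "F3", "F4", "Cz"],
    "F4": ["FP2", "F8", "Fz", "C4"],
    "F8": ["FP2", "F4", "T4"],
    "T3": ["F7", "C3", "T5"],
    "C3": ["F3", "T3", "Cz", "P3"],
    "Cz": ["Fz", "C3", "C4", "Pz"],
    "C4": ["F4", "T4", "Cz", "P4"],
    "T4": ["F8", "C4", "T6"],
    "T5": ["T3", "P3", "O1"],
    "P3": ["C3", "T5", "Pz", "O1"],
    "Pz": ["Cz", "P3", "P4", "O1", "O2"],
    "P4": ["C4", "T6", "Pz", "O2"],
    "T6": ["T4", "P4", "O2"],
    "O1": ["T5", "P3", "Pz", "O2"],
    "O2": ["T6", "P4", "Pz", "O1"]
  }
}
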
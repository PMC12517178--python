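{
  "comment": "Modern (10-10 style) to legacy 10-20 channel names. Applied after uppercasing; idempotent because legacy names map to themselves implicitly.",
  "aliases": {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
    "FP1": "FP1",
    "FP2": "FP2"
  }
}
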
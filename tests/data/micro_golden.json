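{
  "lamp": {
    "lexicality": "word",
    "gla": 0.6852203939933708
  },
  "desk": {
    "lexicality": "word",
    "gla": 0.4652497211125776
  },
  "lanp": {
    "lexicality": "nonword",
    "gla": 0.6892242956220428
  },
  "gost": {
    "lexicality": "nonword",
    "gla": 0.0
  }
}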
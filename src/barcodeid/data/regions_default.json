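[
  {"name": "COI", "start": 1, "end": 1495},
  {"name": "tRNA-leu", "start": 1496, "end": 1561},
  {"name": "spacer", "start": 1562, "end": 1568},
  {"name": "COII", "start": 1569, "end": 2218}
]
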
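{
  "central.tsv": "d9159ff73162103a12c1baa2e6c743d338cf4993d5429e2efb2b65203072802e",
  "north.tsv": "c9fb6db653c0f0a1c2d3bcd623ed239904138aeffefab5cdb93883a76d265ed5",
  "south.tsv": "b0020704d04ae4e6c2d42f1686dcfbdbc7441fc701859d21c597e83e654ead09"
}
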
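{
  "fig2a": {"E1": "1.1.1"},
  "fig2b": {"S1": "1.2.1"},
  "fig2c": {"E1": "1.1.1"},
  "fig2d": {"S1": "1.2.1"},
  "fig3a": {"E1": "1.1.2"},
  "fig3b": {"E2": "1.1.2"},
  "fig3c": {"S1": "1.2.2"},
  "fig3d": {"D1": "1.2.2"},
  "fig4a": {"E1": "1.1.3"},
  "fig4b": {"S1": "1.2.3"},
  "table1": {"E1": "1.1.1"}
}
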
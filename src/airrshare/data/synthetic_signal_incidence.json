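{
 "version": 1,
 "component_label": "signal",
 "pgen_log10_edges": [-12.0, -9.0, -6.0],
 "incidence_edges": [0.0, 0.02, 0.05, 0.1, 0.2, 0.3, 1.0],
 "rows": [
  [0.30, 0.25, 0.20, 0.15, 0.10, 0.0],
  [0.35, 0.25, 0.18, 0.12, 0.10, 0.0],
  [0.40, 0.25, 0.15, 0.12, 0.08, 0.0],
  [0.30, 0.20, 0.20, 0.18, 0.12, 0.0]
 ]
}
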
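{
  "schema_version": "1",
  "description": "Published fold-back anchored DNA/AgNC probe set. excitation_nm / readout_nm in nanometers; readout_nominal marks emission readouts assigned from the reported emission color rather than a printed wavelength.",
  "probes": [
    {"name": "6C-miR-21-22bp", "target": "miR-21", "anchor_len": 22, "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-21-11bp", "target": "miR-21", "anchor_len": 11, "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-21-10bp", "target": "miR-21", "anchor_len": 10, "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-21-9bp",  "target": "miR-21", "anchor_len": 9,  "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-21-8bp",  "target": "miR-21", "anchor_len": 8,  "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-21-7bp",  "target": "miR-21", "anchor_len": 7,  "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-21-6bp",  "target": "miR-21", "anchor_len": 6,  "loop_len": 6, "excitation_nm": 480, "readout_nm": 580, "readout_nominal": false},
    {"name": "6C-miR-18a-11bp", "target": "miR-18a", "anchor_len": 11, "loop_len": 6, "excitation_nm": 520, "excitation_nm_variants": [510, 520, 560], "readout_nm": 600, "readout_nominal": true},
    {"name": "6C-miR-27b-4bp", "target": "miR-27b", "anchor_len": 4, "loop_len": 6, "excitation_nm": 560, "readout_nm": 630, "readout_nominal": true}
  ]
}
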
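# format: rasta-photons
# version: 1
# wavelength: 2.5
# i0_eff: 1.6e-06
# kmax: 3.0
# n_images: 3
# n_records: 4
# provenance: {"generator": "handcrafted-conformance-vector"}
# columns: image_id k_x k_y
0 0.25 -0.5
0 1 0.75
2 -0.125 0.0625
2 2 0
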
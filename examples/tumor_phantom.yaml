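# Tumor-inclusion phantom at one mean free path below the surface.
phantom:
  kind: tumor
  depth_ls: 1.0
  mus_tumor: 400.0
  host:
    mus: 400.0
    delta_n: -1.0e-4
    eta_deg: 90.0
experiment:
  photons: 1000000
  batches: 10
  seed: 1
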
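# Default traffic network: serum hub joined to each sampled tissue.
compartments:
  - serum
  - liver
  - brain
  - heart atria
  - heart ventricles
  - spleen
  - renal medulla
  - renal cortex
axes:
  - [serum, liver]
  - [serum, brain]
  - [serum, heart atria]
  - [serum, heart ventricles]
  - [serum, spleen]
  - [serum, renal medulla]
  - [serum, renal cortex]
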
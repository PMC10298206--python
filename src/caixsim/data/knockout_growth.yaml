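# CAIX-knockout tumor, no treatment, knockout-cohort inoculation fraction.
base: fitted
parameters:
  q: 0.0
inoculation:
  inoc_cells: 0.336
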
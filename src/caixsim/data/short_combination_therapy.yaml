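# Two-week anti-CAIX + anti-PD-1 + anti-CTLA-4 combination on the
# standardized tumor (treatment days 20-34); growth rate recalibrated.
base: fitted
inoculation:
  inoc_cells: 0.1
schedule:
  - {t_start: 20.0, t_end: 34.0, d1: 0.4, d2: 4.0, d3: 1.0}
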
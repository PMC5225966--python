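# Baseline healthy activation sequence: 7 roots, calibrated speeds, unit
# conductivity scale factors.  All values shown are the package defaults.
scenario:
  name: baseline
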
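# +/-50% variability sweep template: run with `qrsim sweep <parameter>`;
# the factor grid defaults to 0.5, 0.75, 1.0, 1.25, 1.5.
scenario:
  name: sweep
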
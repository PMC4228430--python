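# Parallel batch cultures; the named scenario is the 37 degC reference.
seed: 0
duration_h: 8
reactors:
  - id: batch_37C
    scenario: three_temperatures
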
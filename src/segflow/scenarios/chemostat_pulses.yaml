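# Batch -> chemostat (D = 0.14 1/h) -> chemostat with glucose pulses.
seed: 0
duration_h: 14
reactors:
  - id: chemostat_pulses
    scenario: chemostat_pulses
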
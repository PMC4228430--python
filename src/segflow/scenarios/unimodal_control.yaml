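# Substrate-replete, segregation pinned off: single tight subpopulation.
seed: 0
duration_h: 2
reactors:
  - id: unimodal_control
    scenario: unimodal_control
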
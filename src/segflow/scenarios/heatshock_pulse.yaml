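# Batch at 30 degC, upshift to 42 degC at 4.5 h with a glucose pulse.
seed: 0
duration_h: 8
reactors:
  - id: heatshock_pulse
    scenario: heatshock_pulse
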
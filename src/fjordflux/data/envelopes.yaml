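# Default water-mass envelope table for Svalbard fjord transects.
# Bounds transcribed from the Cottier et al. fjord water-mass convention.
# Edges: lower bounds closed, upper bounds open unless overridden per edge
# with a `closed:` map.  sigma_max applies only to the Atlantic classes.
sigma_threshold: 27.92
precedence: [WCW, ArW, LW, SW, IW, TAW, AW]
envelopes:
  SW:
    t_min: 1.0
    s_max: 34.0
  IW:
    t_min: 1.0
    s_min: 34.0
    s_max: 34.65
  AW:
    t_min: 3.0
    s_min: 34.9
    sigma_max: 27.92
  TAW:
    t_min: 1.0
    t_max: 3.0
    s_min: 34.7
    sigma_max: 27.92
  ArW:
    t_min: -1.5
    t_max: 1.0
    s_min: 34.3
    s_max: 34.8
  LW:
    t_min: -0.5
    t_max: 1.0
    s_min: 34.3
    s_max: 34.85
  WCW:
    t_max: -0.5
    s_min: 34.4
    s_max: 35.0
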
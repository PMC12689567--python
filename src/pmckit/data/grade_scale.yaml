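# Six-band consistency grade scale over the PMC range [0, 9].
# Bands are lower-inclusive / upper-exclusive except the top band,
# which includes its upper endpoint.
bands:
  - {label: Poor,       lower: 0, upper: 4}
  - {label: Acceptable, lower: 4, upper: 5}
  - {label: Good,       lower: 5, upper: 6}
  - {label: Excellent,  lower: 6, upper: 7}
  - {label: Superb,     lower: 7, upper: 8}
  - {label: Perfect,    lower: 8, upper: 9}
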
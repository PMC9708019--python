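# Transcatheter valve catalogue: the eight device sizes used in the cohort.
# CV = CoreValve, ER/EPRO = Evolut R / Evolut PRO (self-expanding, force
# controlled); LT = Lotus (mechanically expanding, displacement controlled).
# frame_length / crimped_diameter are nominal manufacturer-scale values (mm);
# peak_pressure (MPa) is the package's default radial-pressure-curve anchor at
# the crimped diameter and is configuration-overridable.
devices:
  - id: "CV 26"
    family: self-expanding
    frame_length: 55.0
    nominal_diameter: 26.0
    crimped_diameter: 6.0
    peak_pressure: 2.0
    deployment: force
  - id: "CV 29"
    family: self-expanding
    frame_length: 53.0
    nominal_diameter: 29.0
    crimped_diameter: 6.0
    peak_pressure: 2.0
    deployment: force
  - id: "CV 31"
    family: self-expanding
    frame_length: 52.0
    nominal_diameter: 31.0
    crimped_diameter: 6.0
    peak_pressure: 2.0
    deployment: force
  - id: "ER/EPRO 26"
    family: self-expanding
    frame_length: 45.0
    nominal_diameter: 26.0
    crimped_diameter: 6.0
    peak_pressure: 2.0
    deployment: force
  - id: "ER/EPRO 29"
    family: self-expanding
    frame_length: 45.0
    nominal_diameter: 29.0
    crimped_diameter: 6.0
    peak_pressure: 2.0
    deployment: force
  - id: "LT 23"
    family: mechanically-expanding
    frame_length: 19.0
    nominal_diameter: 23.0
    crimped_diameter: 7.0
    peak_pressure: 2.0
    deployment: displacement
  - id: "LT 25"
    family: mechanically-expanding
    frame_length: 19.0
    nominal_diameter: 25.0
    crimped_diameter: 7.0
    peak_pressure: 2.0
    deployment: displacement
  - id: "LT 27"
    family: mechanically-expanding
    frame_length: 19.0
    nominal_diameter: 27.0
    crimped_diameter: 7.0
    peak_pressure: 2.0
    deployment: displacement
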
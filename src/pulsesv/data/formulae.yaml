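# Stroke-volume prediction formula registry, v1.
#
# Forms:
#   pressure_linear : SV = scale·(a + b·PP − c·(DAP + k·PP) − d·age) + offset
#                     (scale/offset default 1/0, k default 0; pressures mmHg,
#                      age years, SV mL)
#   power_anthro    : SV = coef · input^exponent
#   linear_anthro   : SV = slope · input + intercept
#   lu_co           : CO [L/min] = a0 + orphan − age_coef·age + weight_coef·weight;
#                     SV [mL] = 1000·CO/HR. The orphan constant's multiplicand is
#                     not recoverable from the printed source string; it is kept
#                     as an additive constant (configurable at predict time).
#   remington_table : SV = (VF(SAP) − VF(DAP)) · BSA with VF a user-supplied
#                     monotone pressure → volume-factor table (linear
#                     interpolation); no default table is shipped, so this
#                     entry is skipped unless a table is provided.
#
# `equation` is the source string exactly as printed; `params` is this
# package's interpretation of it. Anthropometric inputs: weight kg,
# height_m metres, height_cm centimetres, bsa m².
version: 1
formulae:
  - id: starr54_eq72
    label: "Starr 1954 (equation 72)"
    equation: "SV=100+0.5PP-0.6DP-0.6age"
    form: pressure_linear
    params: {a: 100.0, b: 0.5, c: 0.6, d: 0.6}
  - id: starr54_eq71
    label: "Starr 1954 (equation 71)"
    equation: "SV=101+0.5PP-0.59DP-0.61age"
    form: pressure_linear
    params: {a: 101.0, b: 0.5, c: 0.59, d: 0.61}
  - id: jackson55
    label: "Jackson 1955"
    equation: "SV=101+0.5SP-1.09DP-0.61age"
    # 0.5·SAP − 1.09·DAP ≡ 0.5·PP − 0.59·DAP, so this is algebraically
    # identical to Starr equation 71.
    form: pressure_linear
    params: {a: 101.0, b: 0.5, c: 1.09, d: 0.61, uses_sap: true}
  - id: grollman30
    label: "Starr 1954: data from Grollman 1930 (acetylene method)"
    equation: "SV=0.4593+0.54PP-0.47DP-0.61age+43"
    # Read as 0.45·(93 + 0.54PP − 0.47DP − 0.61age) + 43: the printed string
    # concatenates the scale factor 0.45 with the base-equation intercept 93.
    form: pressure_linear
    params: {a: 93.0, b: 0.54, c: 0.47, d: 0.61, scale: 0.45, offset: 43.0}
  - id: desimone97_weight
    label: "de Simone 1997 (weight)"
    equation: "SV=3.59weight^0.71"
    form: power_anthro
    params: {coef: 3.59, exponent: 0.71, input: weight}
    applicability: [{var: bmi, max: 25.25}]
  - id: desimone97_bsa
    label: "de Simone 1997 (BSA)"
    equation: "SV=35.38BSA^1.19"
    form: power_anthro
    params: {coef: 35.38, exponent: 1.19, input: bsa}
    applicability: [{var: bmi, max: 25.25}]
  - id: starr54_eq59a
    label: "Starr 1954 (equation 59a)"
    equation: "SV=91+0.54PP-0.57DP-0.61age"
    form: pressure_linear
    params: {a: 91.0, b: 0.54, c: 0.57, d: 0.61}
  - id: desimone97_height
    label: "de Simone 1997 (height)"
    equation: "SV=23.99height^2.04"
    form: power_anthro
    params: {coef: 23.99, exponent: 2.04, input: height_m}
    applicability: [{var: bmi, max: 25.25}]
  - id: starr54_eq68
    label: "Starr 1954 (equation 68)"
    equation: "SV=93+0.54PP-0.47DP-0.61age"
    form: pressure_linear
    params: {a: 93.0, b: 0.54, c: 0.47, d: 0.61}
  - id: starr54_eq59b
    label: "Starr 1954 (equation 59b)"
    equation: "SV=90.97+0.54PP-0.57DP-0.61age"
    form: pressure_linear
    params: {a: 90.97, b: 0.54, c: 0.57, d: 0.61}
  - id: starr54_eq62
    label: "Starr 1954 (equation 62)"
    equation: "SV=90.97+0.73PP-0.57DBP+1/3PP-0.61age"
    # Bracket reading: −0.57·(DAP + PP/3); flattens to 0.73 − 0.57/3 = 0.54
    # on PP, i.e. identical to equation 59b.
    form: pressure_linear
    params: {a: 90.97, b: 0.73, c: 0.57, d: 0.61, k: 0.3333333333333333}
  - id: starr54_eq76
    label: "Starr 1954 (equation 76)"
    equation: "SV=93+0.62PP-0.45DP-0.61age"
    form: pressure_linear
    params: {a: 93.0, b: 0.62, c: 0.45, d: 0.61}
  - id: bridwell56
    label: "Bridwell 1956"
    equation: "SV=66+0.34PP-0.11DP-0.36age"
    form: pressure_linear
    params: {a: 66.0, b: 0.34, c: 0.11, d: 0.36}
  - id: starr54_eq64
    label: "Starr 1954 (equation 64)"
    equation: "SV=90.96+0.92PP-0.57DP+2/3PP-0.61age"
    # −0.57·(DAP + 2PP/3); flattens to 0.92 − 0.38 = 0.54 on PP: differs
    # from equation 59b by the constant −0.01 only.
    form: pressure_linear
    params: {a: 90.96, b: 0.92, c: 0.57, d: 0.61, k: 0.6666666666666666}
  - id: starr54_eq63
    label: "Starr 1954 (equation 63)"
    equation: "SV=90.97+0.82PP-0.57DP+12PP-0.61age"
    # "12PP" read as 1/2·PP inside the −0.57 bracket.
    form: pressure_linear
    params: {a: 90.97, b: 0.82, c: 0.57, d: 0.61, k: 0.5}
  - id: lu15
    label: "Lu 2015"
    equation: "SV=6.963+0.446-0.037age+0.013weight/HR"
    form: lu_co
    params: {a0: 6.963, orphan: 0.446, age_coef: 0.037, weight_coef: 0.013}
  - id: skrabal05_weight
    label: "Skrabal 2005 (weight)"
    equation: "SV=0.77weight+29"
    form: linear_anthro
    params: {slope: 0.77, intercept: 29.0, input: weight}
  - id: remington48
    label: "Remington 1948"
    equation: "SV=Volume factor for SBP - Volume factor for DBP x BSA"
    form: remington_table
    params: {}
  - id: warren45
    label: "Starr 1954: data from Warren 1945 (Fick method)"
    equation: "SV=1.591+0.54PP-0.57DP-0.61age+8.9"
    # 1.5·(91 + 0.54PP − 0.57DP − 0.61age) + 8.9
    form: pressure_linear
    params: {a: 91.0, b: 0.54, c: 0.57, d: 0.61, scale: 1.5, offset: 8.9}
  - id: liljestrand28
    label: "Starr 1954: data from Liljestrand and Zander 1928 (N2O method)"
    equation: "SV=1.81 93+0.54PP-0.47DP-0.61age-25.9"
    # 1.81·(93 + 0.54PP − 0.47DP − 0.61age) − 25.9
    form: pressure_linear
    params: {a: 93.0, b: 0.54, c: 0.47, d: 0.61, scale: 1.81, offset: -25.9}
  - id: skrabal05_height
    label: "Skrabal 2005 (height)"
    equation: "SV=1.19height-112"
    # Height in centimetres (1.19·180 − 112 ≈ 102 mL at 1.80 m).
    form: linear_anthro
    params: {slope: 1.19, intercept: -112.0, input: height_cm}
  - id: cathcart53
    label: "Starr 1954: data from Cathcart 1953 (Fick method)"
    equation: "SV=1.0293+0.54PP-0.47DP-0.61age+39.6"
    # 1.02·(93 + 0.54PP − 0.47DP − 0.61age) + 39.6
    form: pressure_linear
    params: {a: 93.0, b: 0.54, c: 0.47, d: 0.61, scale: 1.02, offset: 39.6}
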
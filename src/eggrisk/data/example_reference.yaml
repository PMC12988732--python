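# EXAMPLE reference tables for egg heavy-metal risk assessment.
#
# These are illustrative, USEPA-style defaults — NOT measured survey
# parameters. Edit body weights, intake rates and limits to match the
# population and jurisdiction you are assessing.
#
# Units: bw kg; fir g/person/day (edible portion, same mass basis as the
# concentration data); ef days/year; ed years; at days; rfd mg/kg/day;
# sf (mg/kg/day)^-1; limits mg/kg.
#
# With ef*ed == at (as below), THQ reduces to EDI/RfD.

exposure_profiles:
  male:   {bw: 65.0, fir: 40.0, ef: 365, ed: 70, at: 25550}
  female: {bw: 56.0, fir: 40.0, ef: 365, ed: 70, at: 25550}
  child:  {bw: 15.9, fir: 20.0, ef: 365, ed: 70, at: 25550}

# Oral reference doses (USEPA IRIS / RAIS conventions); slope factors only
# for the carcinogens Cr, Cd, Pb.
toxicity:
  Cr: {rfd: 0.003,  sf: 0.5}
  Mn: {rfd: 0.14}
  Co: {rfd: 0.0003}
  Ni: {rfd: 0.02}
  Cu: {rfd: 0.04}
  Zn: {rfd: 0.3}
  As: {rfd: 0.0003}
  Se: {rfd: 0.005}
  Cd: {rfd: 0.001,  sf: 6.1}
  Pb: {rfd: 0.0035, sf: 0.0085}

# Maximum permitted levels in eggs (examples; verify against the current
# edition of each standard before regulatory use).
limits:
  GB2762:
    Pb: 0.2
    Cd: 0.05
    As: 0.5
    Cr: 1.0
  FAO_WHO:
    Pb: 0.1
    Cd: 0.05
  EC:
    Pb: 0.1
    Cd: 0.05
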
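{
  "_notes": [
    "pkCSM/SwissADME-predicted ADME/Tox panel for blumeatin, as reported in the source study's narrative.",
    "mrtd_log is a SYNTHETIC stand-in: the narrative states only the categorical call (maximum recommended tolerated dose in the low bin, log(mg/kg/day) <= 0.477); the numeric prediction appears only in a figure and could not be transcribed. Any value <= 0.477 reproduces the stated call."
  ],
  "log_s": -3.53,
  "caco2": 0.48,
  "hia": 81.93,
  "pgp_substrate": true,
  "pgp_i_inhibitor": false,
  "pgp_ii_inhibitor": false,
  "vdss_log": 0.17,
  "fu": 0.05,
  "cyp_inhibition": {
    "CYP1A2": true,
    "CYP2C19": true,
    "CYP2C9": false,
    "CYP2D6": false,
    "CYP3A4": false
  },
  "total_clearance": 0.52,
  "oct2_substrate": false,
  "ames": false,
  "mrtd_log": 0.40,
  "herg1": false,
  "herg2": false,
  "oral_rat_ld50": 2.56,
  "hepatotoxic": false,
  "skin_sensitising": false
}
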
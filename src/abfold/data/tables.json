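{
 "version": "1",
 "fibonacci": [
  {
   "label": "fib13",
   "n": 13,
   "sequence": "ABBABBABABBAB",
   "reference_energies": {
    "SA": -4.9746,
    "ELP": -4.967,
    "CSA": -4.9746,
    "TS": -6.5687,
    "GATS": -6.9539
   },
   "bond_angles": [
    0.11611,
    -1.44697,
    0.32017,
    0.01576,
    0.50275,
    -0.86862,
    0.12051,
    -0.58378,
    -0.4515,
    -0.89987,
    -0.00446
   ],
   "torsion_angles": [
    0.00102,
    -0.67737,
    -2.1438,
    2.65948,
    -0.12802,
    2.11709,
    0.2498,
    1.8258,
    -2.99295,
    1.46672
   ]
  },
  {
   "label": "fib21",
   "n": 21,
   "sequence": "BABABBABABBABBABABBAB",
   "reference_energies": {
    "SA": -12.0617,
    "ELP": -12.316,
    "CSA": -12.3266,
    "TS": -13.4151,
    "GATS": -14.7974
   },
   "bond_angles": [
    -0.08637,
    -1.24407,
    -0.02388,
    0.7156,
    0.20713,
    1.77167,
    0.25962,
    -0.31786,
    1.57686,
    -0.95041,
    0.04461,
    0.03119,
    0.54498,
    -0.8286,
    0.37745,
    -0.62814,
    -0.98493,
    -0.38993,
    -0.2365
   ],
   "torsion_angles": [
    2.97004,
    0.58008,
    2.15906,
    -2.64461,
    0.40657,
    -2.00601,
    2.47012,
    2.63691,
    -1.09615,
    3.11625,
    -1.56743,
    -0.03975,
    -2.9652,
    0.06719,
    -1.86684,
    -0.32537,
    1.10542,
    -0.70935
   ]
  },
  {
   "label": "fib34",
   "n": 34,
   "sequence": "ABBABBABABBABBABABBABABBABBABABBAB",
   "reference_energies": {
    "SA": -23.0441,
    "ELP": -25.476,
    "CSA": -25.5113,
    "TS": -27.9903,
    "GATS": -27.9897
   },
   "bond_angles": [
    0.23573,
    -1.43459,
    0.29165,
    -1.84341,
    0.14631,
    -1.61093,
    -0.35038,
    1.67799,
    0.17042,
    1.60574,
    -0.40332,
    -1.26662,
    -0.27629,
    1.2098,
    0.21014,
    1.29636,
    0.00999,
    -1.69196,
    -0.35294,
    0.72788,
    -0.62924,
    0.17575,
    -0.34728,
    -0.97787,
    -0.16688,
    -0.91012,
    -0.07292,
    1.03188,
    2.4873,
    -0.16685,
    -0.69786,
    0.68108
   ],
   "torsion_angles": [
    -0.14964,
    0.63562,
    0.75934,
    -2.74033,
    0.28633,
    -2.61899,
    -2.91781,
    -0.44565,
    -0.12498,
    -0.84551,
    -2.50502,
    2.53977,
    -2.54137,
    1.87607,
    -2.82187,
    2.4753,
    2.87212,
    -2.10783,
    0.15378,
    -2.88144,
    1.9304,
    0.43629,
    2.41795,
    0.72296,
    -0.58509,
    1.13745,
    -2.92674,
    0.68888,
    -2.3715,
    -0.79336,
    2.98078
   ]
  },
  {
   "label": "fib55",
   "n": 55,
   "sequence": "BABABBABABBABBABABBABABBABBABABBABBABABBABABBABBABABBAB",
   "reference_energies": {
    "SA": -38.1977,
    "ELP": -42.428,
    "CSA": -42.3418,
    "TS": -41.5098,
    "GATS": -42.4746
   },
   "bond_angles": [
    0.57994,
    -0.54747,
    -1.63058,
    0.32512,
    1.29499,
    0.94198,
    0.15639,
    0.54547,
    0.51204,
    2.4205,
    0.42994,
    0.04798,
    0.53466,
    0.72372,
    -2.84018,
    -0.25987,
    -0.8842,
    0.50741,
    0.31571,
    -0.38491,
    -0.36698,
    -0.85173,
    0.13171,
    -0.28528,
    1.24401,
    -0.44344,
    0.32826,
    -0.71533,
    -0.52747,
    -0.08801,
    -0.44238,
    -0.05707,
    -0.08495,
    -0.62277,
    0.0757,
    -0.90285,
    -0.24254,
    0.16364,
    -0.47504,
    -0.50923,
    -0.37872,
    0.5732,
    1.66339,
    0.32637,
    -0.74187,
    0.43684,
    -0.15112,
    1.46664,
    0.34051,
    -0.72797,
    -0.0762,
    -0.73615,
    -0.79086
   ],
   "torsion_angles": [
    -2.62178,
    2.15436,
    2.79679,
    -2.21273,
    -2.62632,
    -0.37956,
    -2.18578,
    -1.26221,
    -0.51001,
    2.21957,
    -2.55211,
    -1.00242,
    -2.74164,
    -2.4627,
    -2.53201,
    2.51849,
    0.55237,
    -1.22255,
    0.70861,
    -1.09153,
    0.34246,
    2.12777,
    0.25911,
    0.39082,
    -2.89463,
    -0.9397,
    3.02711,
    -1.82971,
    -1.76602,
    -2.81629,
    1.66725,
    1.7781,
    0.81533,
    2.01598,
    -0.19887,
    1.65355,
    1.11533,
    0.46418,
    -1.38864,
    0.55938,
    -1.12062,
    0.29809,
    1.89867,
    -2.71331,
    -2.06007,
    -1.76112,
    0.24818,
    -1.9157,
    -2.01395,
    -0.43327,
    0.97151,
    -0.82385
   ]
  }
 ],
 "proteins": [
  {
   "label": "1BXL",
   "aa_sequence": "GQVGRQLAIIGDDINR",
   "reference_energies": {
    "TS": -15.7164,
    "GATS": -15.8246
   }
  },
  {
   "label": "1EDP",
   "aa_sequence": "CSCSSLMDKECVYFCHL",
   "reference_energies": {
    "TS": -12.8392,
    "GATS": -13.7769
   }
  },
  {
   "label": "1AGT",
   "aa_sequence": "GVPINVSCTGSPQCIKPCKDQGMRFGKCMNRKCHCTPK",
   "reference_energies": {
    "TS": -44.2656,
    "GATS": -46.0842
   }
  }
 ]
}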
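{
  "comment": "Turner-style nearest-neighbor parameters at 37C, kcal/mol. Stacks keyed by outer pair then inner pair, 5'->3' on the top strand. Loop initiation tables by unpaired size; sizes beyond the table are extrapolated as dG(n) = dG(max) + lxc*ln(n/max).",
  "temperature_c": 37.0,
  "lxc": 1.079,
  "min_hairpin_loop": 3,
  "max_interior": 30,
  "terminal_au_gu": 0.5,
  "stack": {
    "AU": {"AU": -0.93, "CG": -2.24, "GC": -2.08, "UA": -1.10, "GU": -0.55, "UG": -1.36},
    "CG": {"AU": -2.11, "CG": -3.26, "GC": -2.36, "UA": -2.08, "GU": -1.41, "UG": -2.11},
    "GC": {"AU": -2.24, "CG": -3.42, "GC": -3.26, "UA": -2.24, "GU": -1.53, "UG": -2.51},
    "UA": {"AU": -1.33, "CG": -2.35, "GC": -2.11, "UA": -0.93, "GU": -1.00, "UG": -1.27},
    "GU": {"AU": -1.27, "CG": -2.51, "GC": -2.11, "UA": -1.36, "GU": -0.50, "UG": 1.29},
    "UG": {"AU": -1.00, "CG": -1.53, "GC": -1.41, "UA": -0.55, "GU": 0.30, "UG": -0.50}
  },
  "hairpin_loop": {"3": 5.7, "4": 5.6, "5": 5.6, "6": 5.4, "7": 5.9, "8": 5.6, "9": 6.4},
  "bulge_loop": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal_loop": {"2": 1.7, "3": 1.8, "4": 2.0, "5": 2.2, "6": 2.5, "7": 2.6, "8": 2.8, "9": 3.1}
}
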
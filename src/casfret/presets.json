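{
  "comment": "Per-target kinetic presets for the SpCas9 smFRET mismatch series. Rates in 1/s, or M^-1 s^-1 where per_molar. Pinned to reported kinetics: total association rate constant 6e6 M^-1 s^-1 (reduced to 3e6 without PAM), sampling-state lifetime ~0.1 s, amplitude-weighted bound lifetimes 0.5 / 8 / 16 s for 5-20_mm / 8-20_mm / 9-20_mm, photobleach-limited cognate dissociation (true lifetime 1800 s), photobleach lifetime 180 s. Roadblock targets 9-12_mm and 5-8_mm share the kinetics of 9-20_mm and 5-20_mm. Free choices (branching ratios, 1-2_mm sampling dwell) are justified in docs/methods.md.",
  "reference_concentration_molar": 2e-8,
  "fret_means": [0.0, 0.42, 0.92],
  "photobleach_rate": 0.005555555555555556,
  "presets": {
    "cognate": {
      "mismatch_interval": null,
      "rates": {
        "U->H": {"value": 6e6, "per_molar": true},
        "H->U": {"value": 0.0005555555555555556}
      }
    },
    "17-20_mm": {
      "mismatch_interval": [17, 20],
      "rates": {
        "U->H": {"value": 6e6, "per_molar": true},
        "H->U": {"value": 0.0005555555555555556}
      }
    },
    "13-20_mm": {
      "mismatch_interval": [13, 20],
      "rates": {
        "U->H": {"value": 6e6, "per_molar": true},
        "H->U": {"value": 0.0005555555555555556}
      }
    },
    "9-20_mm": {
      "mismatch_interval": [9, 20],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 1.0},
        "S->H": {"value": 9.0},
        "H->U": {"value": 0.05660377358490566}
      }
    },
    "9-12_mm": {
      "mismatch_interval": [9, 12],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 1.0},
        "S->H": {"value": 9.0},
        "H->U": {"value": 0.05660377358490566}
      }
    },
    "8-20_mm": {
      "mismatch_interval": [8, 20],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 1.5},
        "S->H": {"value": 8.5},
        "H->U": {"value": 0.10759493670886076}
      }
    },
    "5-20_mm": {
      "mismatch_interval": [5, 20],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 2.5},
        "S->H": {"value": 7.5},
        "H->U": {"value": 1.875}
      }
    },
    "5-8_mm": {
      "mismatch_interval": [5, 8],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 2.5},
        "S->H": {"value": 7.5},
        "H->U": {"value": 1.875}
      }
    },
    "1-2_mm": {
      "mismatch_interval": [1, 2],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 2.3333333333333335},
        "S->H": {"value": 1.0},
        "H->U": {"value": 2.5}
      }
    },
    "1-4_mm": {
      "mismatch_interval": [1, 4],
      "rates": {
        "U->S": {"value": 6e6, "per_molar": true},
        "S->U": {"value": 10.0}
      }
    },
    "no_pam": {
      "mismatch_interval": null,
      "rates": {
        "U->S": {"value": 3e6, "per_molar": true},
        "S->U": {"value": 10.0}
      }
    }
  }
}
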
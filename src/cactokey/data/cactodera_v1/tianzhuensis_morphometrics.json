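{
  "taxon": "C. tianzhuensis",
  "units": "um",
  "convention": "mean +/- sd (min-max); holotype is a single cyst",
  "stages": {
    "cyst": {
      "n": 20,
      "holotype": {
        "cyst_length": 531.0,
        "cyst_width": 429.0,
        "cyst_lw_ratio": 1.23,
        "fenestral_diam": 22.8
      },
      "holotype_notes": {
        "cyst_lw_ratio": "printed value 1.23; 531/429 = 1.2378 rounds to 1.24 at two decimals — the printed value is kept as-is"
      },
      "paratypes": {
        "cyst_length": {"mean": 571.2, "sd": 79.1, "min": 511.0, "max": 761.0},
        "cyst_width": {"mean": 454.3, "sd": 56.8, "min": 360.5, "max": 558.0},
        "cyst_lw_ratio": {"mean": 1.3, "sd": 0.1, "min": 1.1, "max": 1.6},
        "fenestral_diam": {"mean": 23.4, "sd": 3.8, "min": 20.0, "max": 31.5}
      }
    },
    "J2": {
      "n": 20,
      "paratypes": {
        "body_length": {"mean": 538.5, "sd": 25.0, "min": 494.5, "max": 591.5},
        "body_width": {"mean": 23.2, "sd": 1.4, "min": 20.0, "max": 25.0},
        "a": {"mean": 23.4, "sd": 2.0, "min": 20.6, "max": 27.2},
        "b": {"mean": 3.7, "sd": 0.3, "min": 3.1, "max": 4.2},
        "c": {"mean": 10.0, "sd": 0.8, "min": 8.4, "max": 11.6},
        "c_prime": {"mean": 3.9, "sd": 0.3, "min": 3.5, "max": 4.5},
        "lip_region_height": {"mean": 4.8, "sd": 0.4, "min": 4.0, "max": 5.0},
        "lip_region_diam": {"mean": 10.7, "sd": 0.8, "min": 9.0, "max": 12.0},
        "stylet_length": {"mean": 24.9, "sd": 0.8, "min": 22.5, "max": 26.0},
        "stylet_base_height": {"mean": 2.5, "sd": 0.3, "min": 2.0, "max": 3.0},
        "stylet_base_width": {"mean": 5.1, "sd": 0.54, "min": 4.0, "max": 5.5},
        "median_bulb_distance": {"mean": 77.8, "sd": 4.2, "min": 69.5, "max": 85.0},
        "dgo": {"mean": 4.9, "sd": 0.5, "min": 4.0, "max": 6.5},
        "excretory_pore_distance": {"mean": 111.2, "sd": 6.2, "min": 97.5, "max": 124.0},
        "median_bulb_width": {"mean": 11.8, "sd": 1.1, "min": 9.5, "max": 13.5},
        "anal_body_diam": {"mean": 13.8, "sd": 0.5, "min": 11.5, "max": 15.0},
        "tail_length": {"mean": 54.1, "sd": 3.6, "min": 46.5, "max": 59.0},
        "hyaline_length": {"mean": 25.8, "sd": 2.1, "min": 21.5, "max": 28.5},
        "L_over_MB": {"mean": 6.9, "sd": 0.5, "min": 6.1, "max": 8.0},
        "TL_over_H": {"mean": 2.1, "sd": 0.2, "min": 1.8, "max": 2.4}
      }
    },
    "egg": {
      "n": 20,
      "paratypes": {
        "egg_length": {"mean": 117.9, "sd": 11.6, "min": 101.5, "max": 144.0},
        "egg_width": {"mean": 51.3, "sd": 4.1, "min": 41.0, "max": 61.5},
        "egg_lw_ratio": {"mean": 2.3, "sd": 0.3, "min": 1.9, "max": 2.9}
      }
    }
  }
}
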
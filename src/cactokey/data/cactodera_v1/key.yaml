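# Machine-readable dichotomous key to Cactodera species (17 taxa).
# Transcribed from the printed genus key; couplet targets repaired per
# key_errata.yaml. Predicates within one lead are conjunctive.
# relation: lt | le | gt | ge | eq-category | in-range
# basis:    mean  -> test the profile mean (interval midpoint as proxy)
#           range -> test whether the whole profile interval satisfies it
version: cactodera_v1
root: 1
couplets:
  - id: 1
    leads:
      - predicates:
          - {character: cyst_lw_ratio, relation: ge, threshold: 2.0, basis: mean}
        taxon: C. estonica
      - predicates:
          - {character: cyst_lw_ratio, relation: lt, threshold: 2.0, basis: mean}
        goto: 2
  - id: 2
    leads:
      - predicates:
          - {character: eggshell_surface, relation: eq-category, threshold: punctate}
        goto: 3
      - predicates:
          - {character: eggshell_surface, relation: eq-category, threshold: smooth}
        goto: 11
  - id: 3
    leads:
      - predicates:
          - {character: stylet_length, relation: ge, threshold: 26.0, basis: mean}
        goto: 4
      - predicates:
          - {character: stylet_length, relation: lt, threshold: 26.0, basis: mean}
        goto: 5
  - id: 4
    leads:
      - predicates:
          - {character: tail_length, relation: in-range, threshold: [48.0, 64.0], basis: range}
          - {character: hyaline_tail_length, relation: in-range, threshold: [23.0, 28.0], basis: range}
          - {character: fenestral_diam, relation: in-range, threshold: [23.0, 41.0], basis: range}
        taxon: C. thornei
      - predicates:
          - {character: tail_length, relation: in-range, threshold: [37.0, 48.0], basis: range}
          - {character: hyaline_tail_length, relation: in-range, threshold: [17.0, 24.0], basis: range}
          - {character: fenestral_diam, relation: in-range, threshold: [14.0, 25.0], basis: range}
        taxon: C. eremica
  - id: 5
    leads:
      - predicates:
          - {character: j2_body_length, relation: ge, threshold: 411.0, basis: mean}
        goto: 6
      - predicates:
          - {character: j2_body_length, relation: lt, threshold: 411.0, basis: mean}
        goto: 9
  - id: 6
    leads:
      - predicates:
          - {character: tail_length, relation: gt, threshold: 40.0, basis: mean}
          - {character: cyst_length, relation: gt, threshold: 440.0, basis: mean}
          - {character: cyst_width, relation: gt, threshold: 325.0, basis: mean}
        goto: 7
      - predicates:
          - {character: tail_length, relation: le, threshold: 40.0, basis: mean}
          - {character: cyst_length, relation: le, threshold: 440.0, basis: mean}
          - {character: cyst_width, relation: le, threshold: 325.0, basis: mean}
        taxon: C. solani
  - id: 7
    leads:
      - predicates:
          - {character: b_ratio, relation: lt, threshold: 3.5, basis: mean}
          - {character: fenestral_diam, relation: lt, threshold: 20.0, basis: range}
        taxon: C. milleri
      - predicates:
          - {character: b_ratio, relation: gt, threshold: 3.5, basis: mean}
          - {character: fenestral_diam, relation: gt, threshold: 20.0, basis: range}
        goto: 8
  - id: 8
    leads:
      - predicates:
          - {character: cyst_lw_ratio, relation: lt, threshold: 1.4, basis: range}
          - {character: hyaline_tail_length, relation: lt, threshold: 22.0, basis: mean}
        taxon: C. cacti
      - predicates:
          - {character: cyst_lw_ratio, relation: ge, threshold: 1.4, basis: range}
          - {character: hyaline_tail_length, relation: ge, threshold: 22.0, basis: mean}
        taxon: C. chenopodiae
  - id: 9
    leads:
      - predicates:
          - {character: fenestral_diam, relation: lt, threshold: 25.0, basis: range}
        goto: 10
      - predicates:
          - {character: fenestral_diam, relation: ge, threshold: 25.0, basis: range}
        taxon: C. galinsogae
  - id: 10
    leads:
      - predicates:
          - {character: hyaline_tail_length, relation: in-range, threshold: [4.0, 8.0], basis: range}
        taxon: C. rosae
      - predicates:
          - {character: hyaline_tail_length, relation: in-range, threshold: [16.0, 23.0], basis: range}
        taxon: C. evansi
  - id: 11
    leads:
      - predicates:
          - {character: tail_length, relation: lt, threshold: 40.0, basis: mean}
        goto: 12
      - predicates:
          - {character: tail_length, relation: ge, threshold: 40.0, basis: mean}
        goto: 14
  - id: 12
    leads:
      - predicates:
          - {character: j2_body_length, relation: lt, threshold: 406.0, basis: mean}
          - {character: hyaline_tail_length, relation: lt, threshold: 16.0, basis: mean}
        taxon: C. amaranthi
      - predicates:
          - {character: j2_body_length, relation: ge, threshold: 406.0, basis: mean}
          - {character: hyaline_tail_length, relation: ge, threshold: 16.0, basis: mean}
        goto: 13
  - id: 13
    leads:
      - predicates:
          - {character: vulval_cone, relation: eq-category, threshold: distinct}
          - {character: stylet_length, relation: in-range, threshold: [21.0, 23.0], basis: range}
        taxon: C. torreyanae
      - predicates:
          - {character: vulval_cone, relation: eq-category, threshold: indistinct}
          - {character: stylet_length, relation: in-range, threshold: [23.4, 25.0], basis: range}
        taxon: C. salina
  - id: 14
    leads:
      - predicates:
          - {character: stylet_knob_anterior, relation: eq-category, threshold: concave}
          - {character: dgo, relation: in-range, threshold: [4.5, 5.6], basis: range}
        goto: 15
      - predicates:
          - {character: stylet_knob_anterior, relation: eq-category, threshold: convex}
          - {character: dgo, relation: in-range, threshold: [2.5, 3.0], basis: range}
        taxon: C. acnidae
  - id: 15
    leads:
      - predicates:
          - {character: vulval_denticles, relation: eq-category, threshold: present}
        goto: 16
      - predicates:
          - {character: vulval_denticles, relation: eq-category, threshold: absent}
        taxon: C. radicale
  - id: 16
    leads:
      - predicates:
          - {character: j2_body_length, relation: lt, threshold: 489.0, basis: mean}
          - {character: stylet_length, relation: in-range, threshold: [20.0, 22.0], basis: range}
        taxon: C. weissi
      - predicates:
          - {character: j2_body_length, relation: ge, threshold: 489.0, basis: mean}
          - {character: stylet_length, relation: in-range, threshold: [23.0, 26.0], basis: range}
        taxon: C. tianzhuensis
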
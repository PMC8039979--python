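{
  "version": "cactodera_v1",
  "characters": [
    {"id": "cyst_length", "label": "Cyst length (excluding neck)", "stage": "cyst", "kind": "numeric", "units": "um"},
    {"id": "cyst_width", "label": "Cyst width", "stage": "cyst", "kind": "numeric", "units": "um"},
    {"id": "cyst_lw_ratio", "label": "Cyst length/width ratio", "stage": "cyst", "kind": "numeric", "units": "", "ratio": true},
    {"id": "vulval_denticles", "label": "Vulval denticles", "stage": "cyst", "kind": "categorical", "categories": ["present", "absent"]},
    {"id": "fenestral_diam", "label": "Fenestral diameter", "stage": "cyst", "kind": "numeric", "units": "um"},
    {"id": "vulval_cone", "label": "Vulval cone prominence", "stage": "cyst", "kind": "categorical", "categories": ["distinct", "indistinct"]},
    {"id": "j2_body_length", "label": "J2 body length", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "j2_body_width", "label": "J2 body width at mid-body", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "dgo", "label": "Dorsal pharyngeal gland opening from stylet base (DGO)", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "stylet_length", "label": "J2 stylet length", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "stylet_knob_anterior", "label": "Anterior surface of J2 stylet knobs", "stage": "J2", "kind": "categorical", "categories": ["concave", "convex"]},
    {"id": "tail_length", "label": "J2 tail length", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "hyaline_tail_length", "label": "J2 hyaline tail length", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "b_ratio", "label": "de Man b ratio (body length / pharynx length)", "stage": "J2", "kind": "numeric", "units": "", "ratio": true},
    {"id": "median_bulb_distance", "label": "Median bulb from anterior end (MB)", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "excretory_pore_distance", "label": "Excretory pore from anterior end (EP)", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "anal_body_diam", "label": "Body diameter at anus", "stage": "J2", "kind": "numeric", "units": "um"},
    {"id": "egg_length", "label": "Egg length", "stage": "egg", "kind": "numeric", "units": "um"},
    {"id": "egg_width", "label": "Egg width", "stage": "egg", "kind": "numeric", "units": "um"},
    {"id": "eggshell_surface", "label": "Eggshell surface", "stage": "egg", "kind": "categorical", "categories": ["smooth", "punctate"]}
  ]
}
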
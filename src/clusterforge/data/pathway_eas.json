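{
  "pathway": "EAS",
  "description": "Ergot alkaloid biosynthesis: dimethylallyltryptophan through clavines to lysergyl amides and ergopeptines.",
  "catalog": ["dmaW", "easF", "easE", "easC", "easD", "easA", "easG", "cloA",
              "easH", "easO", "easP", "lpsA", "lpsB", "lpsC"],
  "products": [
    {"name": "CC", "label": "chanoclavine-I",
     "requires": ["dmaW", "easF", "easE", "easC"], "parent": null},
    {"name": "agroclavine", "label": "agroclavine",
     "requires": ["easD", "easA", "easG"], "parent": "CC"},
    {"name": "EC", "label": "elymoclavine",
     "requires": ["cloA"], "parent": "agroclavine"},
    {"name": "lysergic_acid", "label": "lysergic acid",
     "requires": ["cloA"], "parent": "EC"},
    {"name": "EN", "label": "ergonovine",
     "requires": ["lpsB", "lpsC"], "parent": "lysergic_acid"},
    {"name": "LAH", "label": "lysergic acid alpha-hydroxyethylamide",
     "requires": ["easO", "easP"], "parent": "EN"},
    {"name": "ergopeptine", "label": "ergopeptine",
     "requires": ["lpsA", "lpsB", "easH"], "parent": "lysergic_acid"}
  ],
  "co_required": {}
}
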
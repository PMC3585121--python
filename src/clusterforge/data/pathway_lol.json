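{
  "pathway": "LOL",
  "description": "Loline alkaloid biosynthesis: saturated 1-aminopyrrolizidines; NANL is the first fully cyclized intermediate, NFL a decorated end product.",
  "catalog": ["lolF", "lolC", "lolD", "lolO", "lolA", "lolU", "lolP",
              "lolT", "lolE", "lolN", "lolM"],
  "products": [
    {"name": "AcAP", "label": "1-acetamidopyrrolizidine",
     "requires": ["lolF", "lolC", "lolD", "lolA", "lolU", "lolT", "lolE"],
     "parent": null},
    {"name": "NANL", "label": "N-acetylnorloline",
     "requires": ["lolO"], "parent": "AcAP"},
    {"name": "NML", "label": "N-methylloline",
     "requires": ["lolN", "lolM"], "parent": "NANL"},
    {"name": "NFL", "label": "N-formylloline",
     "requires": ["lolP"], "parent": "NML"}
  ],
  "co_required": {}
}
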
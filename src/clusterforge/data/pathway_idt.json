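{
  "pathway": "IDT",
  "description": "Indole-diterpene biosynthesis: paspaline-derived alkaloids (paxilline, terpendoles, lolitrems). Epichloid gene names use the ltm prefix; idtE/idtJ are normalized to ltmE/ltmJ.",
  "catalog": ["idtG", "idtM", "idtB", "idtC", "idtS", "idtP", "idtQ",
              "idtF", "idtK", "ltmE", "ltmJ"],
  "aliases": {"idtE": "ltmE", "idtJ": "ltmJ", "ltmG": "idtG", "ltmM": "idtM",
              "ltmB": "idtB", "ltmC": "idtC", "ltmS": "idtS", "ltmP": "idtP",
              "ltmQ": "idtQ", "ltmF": "idtF", "ltmK": "idtK"},
  "products": [
    {"name": "paspaline", "label": "paspaline",
     "requires": ["idtG", "idtM", "idtB", "idtC"], "parent": null},
    {"name": "PAX", "label": "paxilline-type",
     "requires": ["idtP", "idtQ"], "parent": "paspaline"},
    {"name": "TDK", "label": "terpendole-type",
     "requires": ["idtF", "idtK"], "parent": "PAX"},
    {"name": "LTM", "label": "lolitrem B",
     "requires": ["ltmE", "ltmJ"], "parent": "TDK"}
  ],
  "co_required": {"paspaline": ["idtS"]}
}
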
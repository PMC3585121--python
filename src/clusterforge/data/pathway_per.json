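{
  "pathway": "PER",
  "description": "Peramine: pyrrolopyrazine feeding deterrent made by the multifunctional perA NRPS. The perA-deltaR* form (terminal reductase domain deleted) yields no peramine but is a distinct genotype state.",
  "catalog": ["perA"],
  "products": [
    {"name": "PER", "label": "peramine", "requires": ["perA"], "parent": null}
  ],
  "co_required": {},
  "variant_blocks": {"perA": {"deltaR": ["PER"]}}
}
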
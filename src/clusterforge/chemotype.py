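"""Rule-based genotype -> chemotype prediction for alkaloid pathways.

Each pathway (EAS ergot alkaloids, IDT indole-diterpenes, LOL lolines, PER
peramine) is a small acyclic dependency chain of product nodes; a node's
effective requirement is the union of its own required genes and those of
all its ancestors.  Pseudogenes and absent genes are treated identically as
non-functional.  The deepest reachable node is reported as the accumulating
end product, and the missing genes of the shallowest unreachable node are
reported as the block.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

PATHWAYS = ("EAS", "IDT", "LOL", "PER")


@dataclass(frozen=True)
class ProductNode:
    name: str
    label: str
    requires: frozenset[str]        # incremental genes for this step
    parent: Optional[str]


@dataclass
class PathwayRuleSet:
    pathway: str
    catalog: frozenset[str]
    products: dict[str, ProductNode]
    co_required: dict[str, frozenset[str]]
    aliases: dict[str, str] = field(default_factory=dict)
    variant_blocks: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.products.values():
            if not node.requires:
                raise ValueError(f"{node.name}: empty required-gene set")
            seen = set()
            cur = node.parent
            while cur is not None:
                if cur in seen or cur not in self.products:
                    raise ValueError(f"cycle or dangling parent at {node.name}")
                seen.add(cur)
                cur = self.products[cur].parent

    def normalize(self, gene: str) -> str:
        return self.aliases.get(gene, gene)

    def depth(self, name: str) -> int:
        d = 0
        cur = self.products[name].parent
        while cur is not None:
            d += 1
            cur = self.products[cur].parent
        return d

    def effective_requires(self, name: str, include_co: bool = True
                           ) -> frozenset[str]:
        req: set[str] = set()
        cur: Optional[str] = name
        while cur is not None:
            node = self.products[cur]
            req |= node.requires
            if include_co:
                req |= self.co_required.get(cur, frozenset())
            cur = node.parent
        return frozenset(req)


def load_ruleset(pathway: str) -> PathwayRuleSet:
    """Load a shipped pathway rule set by id (EAS | IDT | LOL | PER)."""
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    text = (resources.files("clusterforge.data")
            / f"pathway_{pathway.lower()}.json").read_text()
    raw = json.loads(text)
    products = {p["name"]: ProductNode(p["name"], p.get("label", p["name"]),
                                       frozenset(p["requires"]), p["parent"])
                for p in raw["products"]}
    return PathwayRuleSet(
        pathway=raw["pathway"],
        catalog=frozenset(raw["catalog"]),
        products=products,
        co_required={k: frozenset(v) for k, v in raw.get("co_required", {}).items()},
        aliases=raw.get("aliases", {}),
        variant_blocks=raw.get("variant_blocks", {}))


def load_all_rulesets() -> dict[str, PathwayRuleSet]:
    return {p: load_ruleset(p) for p in PATHWAYS}


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

@dataclass
class GenotypeProfile:
    genome_id: str
    status: dict[str, str]                  # gene -> functional|pseudogene|absent
    copies: dict[str, int] = field(default_factory=dict)
    variants: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def functional(self, gene: str) -> bool:
        return self.status.get(gene, "absent") == "functional"

    def validate_against(self, rulesets: Iterable[PathwayRuleSet]) -> None:
        """Reject unknown gene names, collecting them in ``warnings``."""
        known: set[str] = set()
        alias: dict[str, str] = {}
        for rs in rulesets:
            known |= rs.catalog
            alias.update(rs.aliases)
        unknown = [g for g in self.status
                   if g not in known and g not in alias]
        if unknown:
            self.warnings.extend(f"unknown gene name: {g}" for g in sorted(unknown))
            for g in unknown:
                del self.status[g]


def load_genotypes(path=None) -> dict[str, GenotypeProfile]:
    """Load the shipped strain genotype table (or a user TSV of the same
    layout: strain, pathway, gene, status, copies, variant)."""
    if path is None:
        text = (resources.files("clusterforge.data") / "genotypes.tsv").read_text()
    else:
        text = open(path).read()
    profiles: dict[str, GenotypeProfile] = {}
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for rec in reader:
        strain = rec["strain"]
        prof = profiles.setdefault(strain, GenotypeProfile(strain, {}))
        gene = rec["gene"]
        prof.status[gene] = rec["status"]
        prof.copies[gene] = int(rec.get("copies") or 1)
        if rec.get("variant"):
            prof.variants[gene] = rec["variant"]
    return profiles


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

@dataclass
class PathwayPrediction:
    pathway: str
    producible: list[str]                   # all reachable product nodes
    end_products: list[str]                 # reachable nodes with no reachable child
    accumulating: list[str]                 # deepest reachable node(s)
    blocked_at: dict[str, list[str]]        # shallowest unreachable node -> missing genes


@dataclass
class ChemotypePrediction:
    genome_id: str
    pathways: dict[str, PathwayPrediction]
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        parts = []
        for pw, pred in sorted(self.pathways.items()):
            label = ",".join(pred.end_products) if pred.end_products else "none"
            parts.append(f"{pw}:{label}")
        return " ".join(parts)


def predict(genotype: GenotypeProfile,
            rulesets: Optional[dict[str, PathwayRuleSet]] = None,
            require_co: bool = True) -> ChemotypePrediction:
    """Producible products per pathway from gene content alone."""
    if rulesets is None:
        rulesets = load_all_rulesets()
    genotype.validate_against(rulesets.values())
    out: dict[str, PathwayPrediction] = {}
    for pw, rs in sorted(rulesets.items()):
        functional = {rs.normalize(g) for g, s in genotype.status.items()
                      if s == "functional"}
        # variant forms may disable specific products (e.g. perA-deltaR*)
        disabled: set[str] = set()
        for gene, variant in genotype.variants.items():
            gene = rs.normalize(gene)
            blocks = rs.variant_blocks.get(gene, {})
            disabled |= set(blocks.get(variant, []))
        reachable: set[str] = set()
        blocked: dict[str, list[str]] = {}
        for name in rs.products:
            req = rs.effective_requires(name, include_co=require_co)
            missing = sorted(req - functional)
            if not missing and name not in disabled:
                reachable.add(name)
            elif missing:
                blocked[name] = missing
        # a disabled node also blocks its descendants
        changed = True
        while changed:
            changed = False
            for name in list(reachable):
                parent = rs.products[name].parent
                if parent is not None and parent not in reachable:
                    reachable.discard(name)
                    blocked.setdefault(name, [])
                    changed = True
        depth = {n: rs.depth(n) for n in rs.products}
        shallowest = sorted((n for n in blocked),
                            key=lambda n: (depth[n], n))
        blocked_at = ({shallowest[0]: blocked[shallowest[0]]}
                      if shallowest else {})
        children: dict[str, list[str]] = {}
        for n, node in rs.products.items():
            if node.parent:
                children.setdefault(node.parent, []).append(n)
        ends = sorted(n for n in reachable
                      if not any(c in reachable for c in children.get(n, [])))
        maxd = max((depth[n] for n in reachable), default=None)
        accumulating = sorted(n for n in reachable if depth[n] == maxd) \
            if maxd is not None else []
        out[pw] = PathwayPrediction(
            pathway=pw,
            producible=sorted(reachable, key=lambda n: (depth[n], n)),
            end_products=ends,
            accumulating=accumulating,
            blocked_at=blocked_at)
    return ChemotypePrediction(genotype.genome_id, out,
                               warnings=list(genotype.warnings))


def ergopeptine_count(genotype: GenotypeProfile,
                      rulesets: Optional[dict[str, PathwayRuleSet]] = None
                      ) -> int:
    """Number of distinct ergopeptines supported by lpsA copy number.

    One specificity per lpsA copy is assumed; 0 when ergopeptines are not
    producible at all.
    """
    pred = predict(genotype, rulesets)
    eas = pred.pathways.get("EAS")
    if eas is None or "ergopeptine" not in eas.producible:
        return 0
    return genotype.copies.get("lpsA", 1 if genotype.functional("lpsA") else 0)


# --------------------------------------------------------------------------
# concordance with observed chemistry
# --------------------------------------------------------------------------

@dataclass
class ConcordanceRow:
    strain: str
    pathway: str
    assertion: str
    products: list[str]
    status: str
    note: str
    passed: Optional[bool] = None


def check_concordance(genotypes: Optional[dict[str, GenotypeProfile]] = None,
                      rulesets: Optional[dict[str, PathwayRuleSet]] = None
                      ) -> list[ConcordanceRow]:
    """Evaluate every shipped genotype->chemotype statement.

    For "consistent" rows the assertion must hold of the prediction; the
    expected-discordant row asserts what the genes alone predict (the
    chemistry disagreed for reasons outside gene content, and that row is
    flagged, not failed).
    """
    if genotypes is None:
        genotypes = load_genotypes()
    if rulesets is None:
        rulesets = load_all_rulesets()
    text = (resources.files("clusterforge.data") / "concordance.tsv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    out: list[ConcordanceRow] = []
    for rec in csv.DictReader(rows, delimiter="\t"):
        row = ConcordanceRow(rec["strain"], rec["pathway"], rec["assertion"],
                             rec["products"].split(";"), rec["status"],
                             rec.get("note", ""))
        pred = predict(genotypes[row.strain], rulesets)
        pw = pred.pathways[row.pathway]
        if row.assertion == "contains":
            row.passed = all(p in pw.producible for p in row.products)
        elif row.assertion == "excludes":
            row.passed = all(p not in pw.producible for p in row.products)
        elif row.assertion == "accumulating":
            row.passed = sorted(row.products) == pw.accumulating
        else:
            raise ValueError(f"unknown assertion {row.assertion!r}")
        out.append(row)
    return out
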
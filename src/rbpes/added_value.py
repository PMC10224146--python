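"""Added-value decision tree for extemporaneous compounding.

Before any risk scoring, a unit must establish that compounding a preparation
is justified at all — that it brings an "added value" compared with using an
industrial product. The determination follows a small decision tree over the
regulatory context of the preparation: does an industrial equivalent with the
same qualitative/quantitative composition, pharmaceutical form, dosage and
excipients exist; is the a.i. monographed in the Pharmacopoeia; does a product
with marketing authorization (MA) exist in the EU; is there a documented
personalization need (e.g. intolerance to an excipient, swallowing aid,
low-therapeutic-index dosing).

The tree is encoded as *data*, not code: a node table maps predicate names to
true/false successors and leaves carry the outcome (justified or not, and the
legal basis — Italian L. 94/98 Art. 5 c. 1 or c. 2, or the default magistral
pathway). Sites can replace the table via a YAML config without code changes.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict


class PersonalizationNeed(str, enum.Enum):
    excipient_intolerance = "excipient_intolerance"
    swallowing_aid = "swallowing_aid"
    taste = "taste"
    washability = "washability"
    low_therapeutic_index_dose = "low_therapeutic_index_dose"
    other = "other"
    none = "none"


class LegalBasis(str, enum.Enum):
    none = "none"
    art5_c1_L94_98 = "art5_c1_L94_98"
    art5_c2_L94_98 = "art5_c2_L94_98"
    magistral_default = "magistral_default"


class AddedValueContext(BaseModel):
    """Inputs to the tree; every boolean must be set explicitly."""

    model_config = ConfigDict(frozen=True)

    industrial_equivalent_exists: bool
    ma_in_eu: bool
    ai_in_pharmacopoeia: bool
    personalization_need: PersonalizationNeed = PersonalizationNeed.none


class AddedValueDecision(BaseModel):
    model_config = ConfigDict(frozen=True)

    justified: bool
    legal_basis: LegalBasis
    path: tuple[str, ...]
    rationale: str


class TreeError(Exception):
    """Malformed node table: unknown predicate, missing node, or cycle."""


#: Predicates the node table may reference, evaluated on AddedValueContext.
PREDICATES = {
    "industrial_equivalent_exists": lambda ctx: ctx.industrial_equivalent_exists,
    "ai_in_pharmacopoeia": lambda ctx: ctx.ai_in_pharmacopoeia,
    "ma_in_eu": lambda ctx: ctx.ma_in_eu,
    "personalization_need_present": lambda ctx: ctx.personalization_need
    is not PersonalizationNeed.none,
}

# Reconstruction of the published tree: with no industrial equivalent the
# preparation is always justified (the branch only selects the legal basis);
# with an industrial equivalent, only a documented personalization need
# (excipient intolerance, taste, washability, dosing of a low-therapeutic-index
# substance, ...) justifies compounding. The intermediate-node ordering is a
# site-editable reconstruction, not a verbatim transcription.
DEFAULT_TREE: dict = {
    "root": "industrial_equivalent",
    "nodes": {
        "industrial_equivalent": {
            "predicate": "industrial_equivalent_exists",
            "if_true": "personalization",
            "if_false": "pharmacopoeia",
        },
        "personalization": {
            "predicate": "personalization_need_present",
            "if_true": "leaf_personalized",
            "if_false": "leaf_not_justified",
        },
        "pharmacopoeia": {
            "predicate": "ai_in_pharmacopoeia",
            "if_true": "leaf_magistral",
            "if_false": "ma_in_eu",
        },
        "ma_in_eu": {
            "predicate": "ma_in_eu",
            "if_true": "leaf_art5_c1",
            "if_false": "leaf_art5_c2",
        },
    },
    "leaves": {
        "leaf_not_justified": {
            "justified": False,
            "legal_basis": "none",
            "rationale": "An industrial product with the same composition, form, dosage and "
            "excipients exists and no personalization need is documented.",
        },
        "leaf_personalized": {
            "justified": True,
            "legal_basis": "art5_c1_L94_98",
            "rationale": "Industrial equivalent exists but a documented personalization need "
            "(e.g. excipient intolerance) justifies an extemporaneous preparation.",
        },
        "leaf_magistral": {
            "justified": True,
            "legal_basis": "magistral_default",
            "rationale": "No industrial equivalent; the a.i. is monographed in the "
            "Pharmacopoeia, so the magistral pathway applies.",
        },
        "leaf_art5_c1": {
            "justified": True,
            "legal_basis": "art5_c1_L94_98",
            "rationale": "No industrial equivalent and no monograph, but a product with MA "
            "in the EU exists.",
        },
        "leaf_art5_c2": {
            "justified": True,
            "legal_basis": "art5_c2_L94_98",
            "rationale": "No industrial equivalent, no monograph, no MA in the EU.",
        },
    },
}


def load_tree(path: str | Path) -> dict:
    """Load a node table from YAML and validate its shape."""
    tree = yaml.safe_load(Path(path).read_text())
    validate_tree(tree)
    return tree


def validate_tree(tree: dict) -> None:
    nodes = tree.get("nodes", {})
    leaves = tree.get("leaves", {})
    if tree.get("root") not in nodes:
        raise TreeError(f"root {tree.get('root')!r} is not a node")
    for nid, node in nodes.items():
        if node["predicate"] not in PREDICATES:
            raise TreeError(f"node {nid!r}: unknown predicate {node['predicate']!r}")
        for branch in ("if_true", "if_false"):
            succ = node[branch]
            if succ not in nodes and succ not in leaves:
                raise TreeError(f"node {nid!r}: successor {succ!r} undefined")
    for lid, leaf in leaves.items():
        basis = LegalBasis(leaf["legal_basis"])
        if not leaf["justified"] and basis is not LegalBasis.none:
            raise TreeError(f"leaf {lid!r}: unjustified outcome must carry legal_basis none")


def evaluate_added_value(
    ctx: AddedValueContext, tree: Optional[dict] = None
) -> AddedValueDecision:
    """Walk the decision tree; deterministic in ``ctx``, total over all inputs.

    Returns the leaf outcome together with the ordered list of node ids
    traversed, so a report can show *why* a preparation was (not) justified.
    """
    if tree is None:
        tree = DEFAULT_TREE
    nodes, leaves = tree["nodes"], tree["leaves"]
    path: list[str] = []
    current = tree["root"]
    while current in nodes:
        if current in path:
            raise TreeError(f"cycle through node {current!r}")
        path.append(current)
        node = nodes[current]
        current = node["if_true"] if PREDICATES[node["predicate"]](ctx) else node["if_false"]
    if current not in leaves:
        raise TreeError(f"dangling successor {current!r}")
    path.append(current)
    leaf = leaves[current]
    return AddedValueDecision(
        justified=leaf["justified"],
        legal_basis=LegalBasis(leaf["legal_basis"]),
        path=tuple(path),
        rationale=leaf["rationale"],
    )
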
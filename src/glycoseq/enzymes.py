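"""Exoglycosidase digestion as pure specificity rules on glycan trees.

An enzyme removes terminal residues matching its symbol, anomer and
linkage constraints, repeatedly until none remain.  No kinetics or steric
effects are modelled; a ``partial`` mode yields the intermediate products
of an incomplete digest.  Mass-shift verification checks whether an
observed pre/post m/z difference equals an integer number of the target
residue's mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Union

from .glycan import Glycan, MASS_CLASS
from .masses import (IonSpecies, PROTONATED, RESIDUE_MASS)

__all__ = [
    "EnzymeSpec",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "load_enzymes",
    "digest",
    "digest_partial",
    "verify_shift",
    "ShiftCheck",
]


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    removes: tuple          # residue symbols the enzyme releases
    anomer: str             # required anomeric configuration
    linkages: Optional[frozenset] = None  # acceptor positions; None = any
    requires_terminal: bool = True

    @property
    def target_class(self) -> str:
        return MASS_CLASS[self.removes[0]]

    def matches(self, node: Glycan) -> bool:
        if node.symbol not in self.removes:
            return False
        if node.anomer != self.anomer:
            return False
        if self.linkages is not None and node.linkage not in self.linkages:
            return False
        return True


BUILTIN_ENZYMES = {
    "a1-2-fucosidase": EnzymeSpec(
        "a1-2-fucosidase", ("Fuc",), "a", frozenset({"2"})),
    "a1-3/4-fucosidase": EnzymeSpec(
        "a1-3/4-fucosidase", ("Fuc",), "a", frozenset({"3", "4"})),
    "b-galactosidase": EnzymeSpec(
        "b-galactosidase", ("Gal",), "b", None),
    "b-N-acetylhexosaminidase": EnzymeSpec(
        "b-N-acetylhexosaminidase", ("GlcNAc", "GalNAc"), "b", None),
}


def get_enzyme(name_or_spec: Union[str, EnzymeSpec]) -> EnzymeSpec:
    if isinstance(name_or_spec, EnzymeSpec):
        return name_or_spec
    try:
        return BUILTIN_ENZYMES[name_or_spec]
    except KeyError:
        raise KeyError(f"unknown enzyme {name_or_spec!r}; "
                       f"built-ins: {sorted(BUILTIN_ENZYMES)}") from None


def load_enzymes(path) -> dict:
    """User-extensible enzyme table from JSON:
    ``{"name": {"removes": [...], "anomer": "a", "linkages": [...]}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    table = {}
    for name, entry in raw.items():
        linkages = entry.get("linkages")
        table[name] = EnzymeSpec(
            name, tuple(entry["removes"]), entry["anomer"],
            frozenset(str(x) for x in linkages) if linkages else None,
            entry.get("requires_terminal", True))
    return table


def _remove_matching_leaves(tree: Glycan, enzyme: EnzymeSpec) -> int:
    removed = 0
    kept = []
    for child in tree.children:
        if child.is_leaf() and enzyme.matches(child):
            removed += 1
        else:
            removed += _remove_matching_leaves(child, enzyme)
            kept.append(child)
    tree.children = kept
    return removed


def digest(tree: Glycan, enzyme: Union[str, EnzymeSpec]) -> tuple[Glycan, int]:
    """Digest to exhaustion; returns (product tree, residues removed).

    The input tree is not modified.  Residues with unknown anomer or
    linkage (``?``) are treated as non-substrates.
    """
    spec = get_enzyme(enzyme)
    product = tree.copy()
    total = 0
    while True:
        n = _remove_matching_leaves(product, enzyme=spec)
        total += n
        if n == 0:
            break
    return product, total


def digest_partial(tree: Glycan, enzyme: Union[str, EnzymeSpec]) -> list[tuple[Glycan, int]]:
    """All intermediate products of an incomplete digest: one tree per
    number of residues removed (0..k), removing matching leaves in
    deterministic canonical order."""
    spec = get_enzyme(enzyme)
    products = [(tree.copy(), 0)]
    current = tree.copy()
    removed = 0
    while True:
        # the root carries the reducing-end tag and is never released
        leaves = [n for n in current.walk()
                  if n is not current and n.is_leaf() and spec.matches(n)]
        if not leaves:
            break
        target = min(leaves, key=lambda n: (n.to_condensed(_as_chain=True)))
        _remove_one(current, target)
        removed += 1
        products.append((current.copy(), removed))
    return products


def _remove_one(tree: Glycan, target: Glycan) -> bool:
    for child in tree.children:
        if child is target:
            tree.children.remove(child)
            return True
        if _remove_one(child, target):
            return True
    return False


@dataclass(frozen=True)
class ShiftCheck:
    consistent: bool
    inferred_removals: int
    residual: float  # Da left over after k removals

    @property
    def no_digestion(self) -> bool:
        return self.consistent and self.inferred_removals == 0


def verify_shift(pre_mz: float, post_mz: float,
                 enzyme: Union[str, EnzymeSpec],
                 species: IonSpecies = PROTONATED,
                 tolerance: float = 0.5) -> ShiftCheck:
    """Check an observed pre/post-digestion mass shift.

    Consistent iff (pre - post) equals k x (target residue mass) within
    tolerance for an integer k >= 0; k = 0 is reported as "no digestion".
    Both m/z must be of the same ion species, so adduct terms cancel.
    """
    if pre_mz <= 0 or post_mz <= 0:
        raise ValueError("m/z values must be positive")
    spec = get_enzyme(enzyme)
    mass = RESIDUE_MASS[spec.target_class]
    diff = pre_mz - post_mz
    k = int(round(diff / mass))
    if k < 0:
        return ShiftCheck(False, k, diff)
    residual = diff - k * mass
    return ShiftCheck(abs(residual) <= tolerance, k, residual)
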
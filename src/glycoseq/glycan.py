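"""Glycan trees, condensed-notation parsing, compositions and motif matching.

A glycan is modelled as a rooted, ordered-by-canonicalisation tree of
monosaccharide residues.  The root is the reducing-end (or reduced /
tag-bearing) residue; every other residue records the anomeric configuration
and the acceptor position by which it is attached to its parent.

The condensed string dialect is ASCII: ``Fuc(a1-2)Gal(b1-4)GlcNAc`` reads
from the non-reducing end (left) to the reducing end (right); a branch is
written in square brackets immediately before the residue it is attached to,
e.g. ``Gal(b1-4)GlcNAc(b1-6)[Gal(b1-4)GlcNAc(b1-3)]Gal``.  Unicode anomer
letters (α/β) are accepted on input and normalised to ``a``/``b``.
Unknown anomers and acceptor positions are written ``?`` and match anything
during motif matching.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "MASS_CLASS",
    "CLASS_ORDER",
    "Composition",
    "Glycan",
    "GlycanSyntaxError",
    "MotifPattern",
    "PatternNode",
    "parse_condensed",
    "parse_pattern",
    "contains_motif",
]

#: Fixed symbol -> mass-class mapping.
MASS_CLASS = {
    "Fuc": "dHex",
    "Gal": "Hex",
    "Glc": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "GalNAcol": "HexNAcol",
    "NeuAc": "NeuAc",
}

#: Canonical ordering of mass classes for composition strings.
CLASS_ORDER = ("dHex", "Hex", "HexNAc", "HexNAcol", "NeuAc")

#: Donor (anomeric) carbon used in linkage notation, by symbol.
_ANOMERIC_CARBON = {"NeuAc": "2"}

_SYMBOL_RE = r"(GalNAcol|GlcNAc|GalNAc|NeuAc|Fuc|Gal|Glc|\*)"
_LINKAGE_RE = r"\(([ab?])([12])-([1-9?])\)"
_RESIDUE_RE = re.compile(_SYMBOL_RE + r"(!?)" + r"(?:" + _LINKAGE_RE + r")?")


class GlycanSyntaxError(ValueError):
    """Malformed condensed-notation input; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class Composition:
    """Multiset of residue counts over the five mass classes."""

    __slots__ = ("counts",)

    def __init__(self, counts=None, **kwargs):
        merged = dict(counts or {})
        merged.update(kwargs)
        for cls, n in merged.items():
            if cls not in CLASS_ORDER:
                raise ValueError(f"unknown mass class {cls!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {cls} must be a non-negative integer")
        self.counts = {cls: int(merged.get(cls, 0)) for cls in CLASS_ORDER}

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]

    def total(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, Composition) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(self.counts[c] for c in CLASS_ORDER))

    def __repr__(self) -> str:
        return f"Composition({self.to_string()!r})"

    def to_string(self) -> str:
        """Render as e.g. ``dHex1Hex2HexNAc3`` (zero counts omitted)."""
        return "".join(f"{c}{self.counts[c]}" for c in CLASS_ORDER if self.counts[c])

    @classmethod
    def from_string(cls, text: str) -> "Composition":
        counts: dict = {}
        pos = 0
        pat = re.compile(r"(dHex|HexNAcol|HexNAc|Hex|NeuAc)_?(\d+)_?")
        while pos < len(text):
            m = pat.match(text, pos)
            if not m:
                raise ValueError(f"bad composition string {text!r} at {pos}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2))
            pos = m.end()
        return cls(counts)

    def minus(self, cls_name: str, n: int = 1) -> "Composition":
        c = dict(self.counts)
        c[cls_name] -= n
        if c[cls_name] < 0:
            raise ValueError(f"composition has no {cls_name} to remove")
        return Composition(c)

    def as_tuple(self) -> tuple:
        return tuple(self.counts[c] for c in CLASS_ORDER)


class Glycan:
    """A residue node; the node reached from outside is the reducing-end root.

    ``linkage`` is the acceptor position on the parent (``'1'``–``'9'`` or
    ``'?'``); it is ``None`` exactly when the node is a root.
    """

    __slots__ = ("symbol", "anomer", "linkage", "children")

    def __init__(self, symbol: str, anomer: str = "?",
                 linkage: Optional[str] = None, children=None):
        if symbol not in MASS_CLASS:
            raise ValueError(f"unknown residue symbol {symbol!r}")
        if anomer not in ("a", "b", "?"):
            raise ValueError(f"anomer must be a, b or ?, got {anomer!r}")
        self.symbol = symbol
        self.anomer = anomer
        self.linkage = linkage
        self.children: list[Glycan] = list(children or [])

    # -- structure ---------------------------------------------------------

    @property
    def mass_class(self) -> str:
        return MASS_CLASS[self.symbol]

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Glycan"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def n_residues(self) -> int:
        return sum(1 for _ in self.walk())

    def copy(self, linkage="__keep__") -> "Glycan":
        lk = self.linkage if linkage == "__keep__" else linkage
        return Glycan(self.symbol, self.anomer, lk,
                      [c.copy() for c in self.children])

    def add_child(self, child: "Glycan") -> None:
        if child.linkage is None:
            raise ValueError("a child residue must carry a linkage position")
        if child.linkage != "?":
            taken = {c.linkage for c in self.children}
            if child.linkage in taken:
                raise ValueError(
                    f"duplicate acceptor position {child.linkage} on {self.symbol}")
        self.children.append(child)

    def composition(self) -> Composition:
        counts = Counter(node.mass_class for node in self.walk())
        return Composition(counts)

    # -- canonical serialization ------------------------------------------

    def _child_sort_key(self, child: "Glycan") -> tuple:
        pos = 0 if child.linkage in (None, "?") else int(child.linkage)
        return (-pos, child.to_condensed(_as_chain=True))

    def to_condensed(self, _as_chain: bool = False) -> str:
        """Canonical condensed string; branch with the highest acceptor
        position is written in the main chain, lower positions bracketed."""
        ordered = sorted(self.children, key=self._child_sort_key)
        out = ""
        if ordered:
            out += ordered[0].to_condensed(_as_chain=True)
            for br in reversed(ordered[1:]):  # ascending acceptor position
                out += "[" + br.to_condensed(_as_chain=True) + "]"
        out += self.symbol
        if _as_chain:
            carbon = _ANOMERIC_CARBON.get(self.symbol, "1")
            out += f"({self.anomer}{carbon}-{self.linkage})"
        return out

    def __repr__(self) -> str:
        return f"Glycan({self.to_condensed()!r})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, Glycan)
                and self.linkage == other.linkage
                and self.to_condensed() == other.to_condensed())

    def __hash__(self) -> int:
        return hash((self.linkage, self.to_condensed()))


def _normalize(text: str) -> str:
    return (text.strip()
            .replace("α", "a").replace("β", "b")
            .replace(" ", ""))


def _parse_chain(text: str, i: int, node_factory, depth: int) -> tuple:
    """Parse a chain (sequence of residues/branches) ending at ']' or EOS.

    Returns (root-of-chain, next index).  The chain's last residue is the
    sub-root; everything before it hangs off it.
    """
    pending: list = []
    while i < len(text) and text[i] != "]":
        if text[i] == "[":
            sub, i = _parse_chain(text, i + 1, node_factory, depth + 1)
            if i >= len(text) or text[i] != "]":
                raise GlycanSyntaxError("unclosed branch bracket", i)
            i += 1
            if sub.linkage is None:
                raise GlycanSyntaxError(
                    "bracketed branch must end with a linked residue", i)
            pending.append(sub)
            continue
        m = _RESIDUE_RE.match(text, i)
        if not m:
            raise GlycanSyntaxError("expected a residue name", i)
        symbol, bang, anomer, carbon, pos = m.groups()
        node = node_factory(symbol, anomer or "?", pos, bang == "!", i)
        expected_carbon = _ANOMERIC_CARBON.get(symbol, "1")
        if carbon is not None and carbon != expected_carbon:
            raise GlycanSyntaxError(
                f"{symbol} links from carbon {expected_carbon}, not {carbon}", i)
        i = m.end()
        for p in pending:
            try:
                node.add_child(p)
            except ValueError as exc:
                raise GlycanSyntaxError(str(exc), i) from None
        pending = [node]
        if pos is None:  # unlinked residue terminates the chain
            break
    if not pending:
        raise GlycanSyntaxError("empty glycan chain", i)
    if len(pending) != 1:
        raise GlycanSyntaxError("dangling branch with no attachment residue", i)
    return pending[0], i


def _glycan_factory(symbol, anomer, pos, bang, i):
    if symbol == "*":
        raise GlycanSyntaxError("wildcard residues are only valid in patterns", i)
    if bang:
        raise GlycanSyntaxError("'!' markers are only valid in patterns", i)
    try:
        return Glycan(symbol, anomer, pos)
    except ValueError as exc:
        raise GlycanSyntaxError(str(exc), i) from None


def parse_condensed(text: str, max_children: int = 2) -> Glycan:
    """Parse a condensed glycan string into its canonical :class:`Glycan`.

    ``max_children`` bounds branching per Hex/HexNAc residue (the default
    reflects the biosynthetic limit of two substituents on a backbone
    residue beyond its own linkage); pass a larger value to relax it.
    """
    s = _normalize(text)
    tree, i = _parse_chain(s, 0, _glycan_factory, depth=0)
    if i != len(s):
        raise GlycanSyntaxError("trailing input after glycan root", i)
    if tree.linkage is not None:
        raise GlycanSyntaxError("root residue must not carry a linkage", 0)
    for node in tree.walk():
        if node.mass_class in ("Hex", "HexNAc") and len(node.children) > max_children:
            raise GlycanSyntaxError(
                f"{node.symbol} carries more than {max_children} substituents", 0)
    return tree


def canonical(text: str) -> str:
    """Canonical form of a condensed string."""
    return parse_condensed(text).to_condensed()


# ---------------------------------------------------------------------------
# Motif patterns
# ---------------------------------------------------------------------------

@dataclass
class PatternNode:
    """A pattern residue.  ``symbol='*'`` matches any residue; ``'?'`` in
    ``anomer``/``linkage`` matches any value (on either side).  ``closed``
    requires every child of the matched tree residue to be matched by a
    pattern child; open nodes tolerate extra, unmatched substituents."""

    symbol: str = "*"
    anomer: str = "?"
    linkage: Optional[str] = None
    closed: bool = False
    children: list = field(default_factory=list)

    def walk(self) -> Iterator["PatternNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())

    def copy(self) -> "PatternNode":
        return PatternNode(self.symbol, self.anomer, self.linkage, self.closed,
                           [c.copy() for c in self.children])

    def add_child(self, child: "PatternNode") -> None:
        if child.linkage is None:
            raise ValueError("a pattern child must carry a linkage position")
        self.children.append(child)

    def _sort_key(self, child):
        pos = 0 if child.linkage in (None, "?") else int(child.linkage)
        return (-pos, child.to_string(_as_chain=True))

    def to_string(self, _as_chain: bool = False) -> str:
        ordered = sorted(self.children, key=self._sort_key)
        out = ""
        if ordered:
            out += ordered[0].to_string(_as_chain=True)
            for br in reversed(ordered[1:]):
                out += "[" + br.to_string(_as_chain=True) + "]"
        out += self.symbol + ("!" if self.closed else "")
        if _as_chain:
            carbon = _ANOMERIC_CARBON.get(self.symbol, "1")
            out += f"({self.anomer}{carbon}-{self.linkage})"
        return out


class MotifPattern:
    """A glycan fragment with wildcards, used for epitope containment.

    ``anchoring='floating'`` lets the pattern root land on any residue;
    ``'terminal'`` additionally closes every pattern leaf, so matched arms
    may not extend beyond the pattern.
    """

    def __init__(self, root: PatternNode, anchoring: str = "floating"):
        if anchoring not in ("floating", "terminal"):
            raise ValueError("anchoring must be 'floating' or 'terminal'")
        self.root = root
        self.anchoring = anchoring
        if anchoring == "terminal":
            for node in root.walk():
                if not node.children:
                    node.closed = True

    @classmethod
    def from_string(cls, text: str, anchoring: str = "floating") -> "MotifPattern":
        return cls(parse_pattern(text), anchoring)

    @classmethod
    def from_glycan(cls, tree: Glycan, anchoring: str = "floating") -> "MotifPattern":
        def conv(node: Glycan) -> PatternNode:
            return PatternNode(node.symbol, node.anomer, node.linkage, False,
                               [conv(c) for c in node.children])
        return cls(conv(tree), anchoring)

    def n_nodes(self) -> int:
        return self.root.n_nodes()

    def to_string(self) -> str:
        return self.root.to_string()

    def __repr__(self) -> str:
        return f"MotifPattern({self.to_string()!r}, anchoring={self.anchoring!r})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, MotifPattern)
                and self.to_string() == other.to_string())

    def __hash__(self) -> int:
        return hash(self.to_string())


def _pattern_factory(symbol, anomer, pos, bang, i):
    return PatternNode(symbol, anomer or "?", pos, closed=bang)


def parse_pattern(text: str) -> PatternNode:
    """Parse the pattern dialect: glycan notation plus ``*`` residues and a
    ``!`` suffix marking a node as closed (no unmatched substituents)."""
    s = _normalize(text)
    root, i = _parse_chain(s, 0, _pattern_factory, depth=0)
    if i != len(s):
        raise GlycanSyntaxError("trailing input after pattern root", i)
    if root.linkage is not None:
        raise GlycanSyntaxError("pattern root must not carry a linkage", 0)
    return root


def _field_match(p: str, t: str) -> bool:
    return p == "?" or t == "?" or p == t


def _node_match(p: PatternNode, t: Glycan, check_linkage: bool) -> bool:
    if p.symbol != "*" and p.symbol != t.symbol:
        return False
    if not _field_match(p.anomer, t.anomer):
        return False
    if check_linkage and not _field_match(p.linkage or "?", t.linkage or "?"):
        return False
    return True


def _embed(p: PatternNode, t: Glycan, check_linkage: bool) -> bool:
    if not _node_match(p, t, check_linkage):
        return False
    pc, tc = p.children, t.children
    if len(pc) > len(tc):
        return False
    if p.closed and len(pc) != len(tc):
        return False
    if not pc:
        return True
    for assignment in itertools.permutations(range(len(tc)), len(pc)):
        if all(_embed(pc[k], tc[j], True) for k, j in enumerate(assignment)):
            return True
    return False


def contains_motif(tree: Glycan, pattern: MotifPattern) -> tuple[bool, list[Glycan]]:
    """Whether an injective, wildcard-tolerant embedding of ``pattern`` into
    ``tree`` exists; returns the flag and the residues its root maps onto."""
    sites = [node for node in tree.walk()
             if _embed(pattern.root, node, check_linkage=False)]
    return bool(sites), sites
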
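"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration with no
shared code paths beyond elementary data types, so agreement with the
package is meaningful.
"""

from __future__ import annotations

import itertools

from glycoseq.glycan import CLASS_ORDER, Composition, Glycan
from glycoseq.masses import PROTON_MASS, RESIDUE_MASS, get_derivative
from glycoseq.sequencing import is_grammar_legal


# ---------------------------------------------------------------------------
# Composition enumeration by nested loops
# ---------------------------------------------------------------------------

def brute_force_compositions(mz, derivatives, tolerance, bounds,
                             adduct="deprotonated"):
    """All (counts tuple, derivative tag) within tolerance, by plain loops."""
    shift = {"deprotonated": -PROTON_MASS, "protonated": PROTON_MASS}[adduct]
    hits = []
    for tag in derivatives:
        deriv = get_derivative(tag)
        for d in range(bounds.get("dHex", 0) + 1):
            for h in range(bounds.get("Hex", 0) + 1):
                for n in range(bounds.get("HexNAc", 0) + 1):
                    for s in range(bounds.get("NeuAc", 0) + 1):
                        if d + h + n + s < 1:
                            continue
                        mass = (d * RESIDUE_MASS["dHex"]
                                + h * RESIDUE_MASS["Hex"]
                                + n * RESIDUE_MASS["HexNAc"]
                                + s * RESIDUE_MASS["NeuAc"]
                                + deriv.mass)
                        if abs(mz - (mass + shift)) <= tolerance:
                            hits.append(((d, h, n, 0, s), tag))
    return set(hits)


# ---------------------------------------------------------------------------
# Topology enumeration over all labeled rooted trees
# ---------------------------------------------------------------------------

#: Symbols the biosynthetic rules can realize, per mass class.
_SYMBOL_OPTIONS = {"dHex": ("Fuc",), "Hex": ("Gal",),
                   "HexNAc": ("GlcNAc", "GalNAc")}

#: (anomer, acceptor position) options per (parent symbol, child symbol),
#: written down independently of the grammar rule tables.
_EDGE_OPTIONS = {
    ("Gal", "GlcNAc"): (("b", "3"), ("b", "6")),
    ("GlcNAc", "Gal"): (("b", "3"), ("b", "4")),
    ("Gal", "Fuc"): (("a", "2"),),
    ("GlcNAc", "Fuc"): (("a", "3"), ("a", "4")),
    ("Gal", "GalNAc"): (("a", "3"),),
    ("Gal", "Gal"): (("a", "3"),),
}


def _parent_vectors(n, root):
    slots = [i for i in range(n) if i != root]
    for combo in itertools.product(range(n), repeat=len(slots)):
        parents = dict(zip(slots, combo))
        if any(parents[i] == i for i in slots):
            continue
        # every node must reach the root without cycles
        ok = True
        for i in slots:
            seen = set()
            j = i
            while j != root:
                if j in seen or j not in parents:
                    ok = False
                    break
                seen.add(j)
                j = parents[j]
            if not ok:
                break
        if ok:
            yield parents


def brute_force_topologies(comp: Composition, grammar, roots=("GlcNAc", "Gal")):
    """Canonical strings of every grammar-legal labeled rooted tree with
    the given composition, enumerated from scratch."""
    classes = []
    for cls in CLASS_ORDER:
        classes.extend([cls] * comp[cls])
    n = len(classes)
    found = set()
    symbol_choices = [(_SYMBOL_OPTIONS[cls]) for cls in classes]
    for symbols in itertools.product(*symbol_choices):
        for root in range(n):
            if symbols[root] not in roots:
                continue
            for parents in _parent_vectors(n, root):
                edge_opts = []
                dead = False
                children_idx = {i: [] for i in range(n)}
                for i, p in parents.items():
                    opts = _EDGE_OPTIONS.get((symbols[p], symbols[i]))
                    if not opts:
                        dead = True
                        break
                    edge_opts.append((i, opts))
                    children_idx[p].append(i)
                if dead:
                    continue
                for labels in itertools.product(*(o for _, o in edge_opts)):
                    lab = {i: l for (i, _), l in zip(edge_opts, labels)}
                    try:
                        tree = _build(root, symbols, children_idx, lab)
                    except ValueError:
                        continue
                    if is_grammar_legal(tree, grammar) and tree.symbol in roots:
                        found.add(tree.to_condensed())
    return found


def _build(i, symbols, children_idx, lab, linkage=None, anomer="?"):
    node = Glycan(symbols[i], anomer, linkage)
    for j in children_idx[i]:
        a, pos = lab[j]
        node.add_child(_build(j, symbols, children_idx, lab, pos, a))
    return node


# ---------------------------------------------------------------------------
# Motif containment by explicit embedding enumeration
# ---------------------------------------------------------------------------

def _all_nodes(tree):
    out = [tree]
    for c in tree.children:
        out.extend(_all_nodes(c))
    return out


def _fields_ok(p, t, with_linkage):
    if p.symbol != "*" and p.symbol != t.symbol:
        return False
    if p.anomer not in ("?",) and t.anomer not in ("?",) and p.anomer != t.anomer:
        return False
    if with_linkage:
        pl = p.linkage or "?"
        tl = t.linkage or "?"
        if pl != "?" and tl != "?" and pl != tl:
            return False
    return True


def _embeddings(pnode, tnode, with_linkage):
    """All embeddings of the pattern subtree as lists of (pattern, tree)
    node pairs; exhaustive, no early exit."""
    if not _fields_ok(pnode, tnode, with_linkage):
        return []
    if getattr(pnode, "closed", False) and len(pnode.children) != len(tnode.children):
        return []
    if len(pnode.children) > len(tnode.children):
        return []
    results = []
    tidx = range(len(tnode.children))
    for assign in itertools.permutations(tidx, len(pnode.children)):
        sub_lists = []
        ok = True
        for k, j in enumerate(assign):
            subs = _embeddings(pnode.children[k], tnode.children[j], True)
            if not subs:
                ok = False
                break
            sub_lists.append(subs)
        if not ok:
            continue
        for combo in itertools.product(*sub_lists) if sub_lists else [()]:
            pairs = [(pnode, tnode)]
            for sub in combo:
                pairs.extend(sub)
            results.append(pairs)
    return results


def brute_force_contains(tree, pattern):
    """All anchor residues at which the pattern embeds, by exhaustive
    enumeration of every embedding."""
    sites = []
    for node in _all_nodes(tree):
        if _embeddings(pattern.root, node, with_linkage=False):
            sites.append(node)
    return sites


# ---------------------------------------------------------------------------
# Y-ladder by explicit subset enumeration
# ---------------------------------------------------------------------------

def brute_force_ladder(tree, derivative, adduct="deprotonated"):
    """m/z set of all Y ions via explicit enumeration of node subsets that
    are unions of terminal subtrees (complement keeps the root connected)."""
    nodes = _all_nodes(tree)
    index = {id(n): k for k, n in enumerate(nodes)}
    parent = {}
    for nd in nodes:
        for c in nd.children:
            parent[index[id(c)]] = index[id(nd)]
    n = len(nodes)
    shift = {"deprotonated": -PROTON_MASS, "protonated": PROTON_MASS}[adduct]
    deriv = get_derivative(derivative)
    mzs = set()
    for keep_mask in itertools.product((False, True), repeat=n):
        if not keep_mask[0]:
            if any(keep_mask):
                continue  # root lost but others kept: not a Y fragment
        ok = all((not keep) or (k == 0) or keep_mask[parent[k]]
                 for k, keep in enumerate(keep_mask))
        if not ok:
            continue
        mass = deriv.mass + sum(
            RESIDUE_MASS[nodes[k].mass_class]
            for k, keep in enumerate(keep_mask) if keep)
        mzs.add(round(mass + shift, 6))
    return mzs
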
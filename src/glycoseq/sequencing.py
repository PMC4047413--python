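"""Branched-topology sequencing from CID-MS/MS Y-ion ladders.

Workflow: enumerate candidate topologies for a composition under a
biosynthetic grammar; predict each candidate's Y-type fragment ladder
(neutral losses of terminal residue sets, aglycone retained); match
ladders against the observed MS/MS peaks; detect branch points from the
simultaneous Hex+HexNAc loss with no single-residue intermediate; and
rank candidates deterministically.

Only Y ions are modelled by default, matching negative-mode CID spectra
of lipid-tagged glycans in which the annotated fragments are neutral-loss
species retaining the tag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence, Union

from .glycan import CLASS_ORDER, Composition, Glycan, MASS_CLASS
from .masses import (DEPROTONATED, Derivative, IonSpecies, RESIDUE_MASS,
                     get_derivative, ion_mz, neutral_mass)
from .peaklist import PeakList

__all__ = [
    "TopologyGrammar",
    "DEFAULT_GRAMMAR",
    "PSM_GRAMMAR",
    "FragmentIon",
    "FragmentLadder",
    "BranchEvidence",
    "MatchScore",
    "generate_candidates",
    "theoretical_Y_ions",
    "detect_branch",
    "match_and_rank",
]


@dataclass(frozen=True)
class TopologyGrammar:
    """Biosynthetic rules for mucin-type poly-N-acetyllactosamine arms.

    Backbones alternate Gal and GlcNAc: GlcNAc extends Gal at positions 3
    (elongation) and 6 (branching); Gal extends GlcNAc at 4 (type 2 unit)
    or 3 (type 1 unit).  Caps: blood-group H fucose (Fuc a1-2 on a
    terminal Gal), Lewis-type fucose (Fuc a1-3/4 on GlcNAc), and the A/B
    additions (GalNAc/Gal a1-3 on an a1-2-fucosylated Gal).
    """

    gal_acceptor_positions: tuple = (3, 6)
    glcnac_acceptor_positions: tuple = (4, 3)  # 4 = type 2, 3 = type 1
    allow_h_cap: bool = True
    allow_lewis_cap: bool = True
    allow_ab_cap: bool = True
    max_children: int = 2
    roots: tuple = ("GlcNAc", "Gal")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TopologyGrammar":
        d = dict(d)
        for key in ("gal_acceptor_positions", "glcnac_acceptor_positions",
                    "roots"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


DEFAULT_GRAMMAR = TopologyGrammar()

#: Grammar with the porcine-stomach-mucin prior: type 1 (Gal b1-3 GlcNAc)
#: backbone units were not detected in that O-glycome, so GlcNAc accepts
#: Gal only at position 4.
PSM_GRAMMAR = TopologyGrammar(glcnac_acceptor_positions=(4,))


def _child_rules(node: Glycan, grammar: TopologyGrammar) -> list[tuple]:
    """(symbol, anomer, position) extensions allowed on ``node``."""
    rules = []
    if node.symbol == "Gal":
        for pos in grammar.gal_acceptor_positions:
            rules.append(("GlcNAc", "b", str(pos)))
        if grammar.allow_h_cap:
            rules.append(("Fuc", "a", "2"))
        if grammar.allow_ab_cap:
            rules.append(("GalNAc", "a", "3"))
            rules.append(("Gal", "a", "3"))
    elif node.symbol == "GlcNAc":
        for pos in grammar.glcnac_acceptor_positions:
            rules.append(("Gal", "b", str(pos)))
        if grammar.allow_lewis_cap:
            rules.append(("Fuc", "a", "3"))
            rules.append(("Fuc", "a", "4"))
    elif node.symbol == "GalNAcol":
        rules.append(("Gal", "b", "3"))
        rules.append(("GlcNAc", "b", "6"))
    return rules


def _node_legal(node: Glycan, grammar: TopologyGrammar) -> bool:
    """Constraint checks on one residue's realized child set."""
    allowed = {(r[0], r[1], r[2]) for r in _child_rules(node, grammar)}
    seen_pos = set()
    for c in node.children:
        key = (c.symbol, c.anomer, c.linkage)
        if key not in allowed:
            return False
        if c.linkage in seen_pos:
            return False
        seen_pos.add(c.linkage)
    if len(node.children) > grammar.max_children:
        return False
    if node.symbol == "Gal":
        has_backbone = any(c.symbol == "GlcNAc" for c in node.children)
        has_h = any(c.symbol == "Fuc" and c.linkage == "2"
                    for c in node.children)
        has_ab = any(c.anomer == "a" and c.linkage == "3"
                     and c.symbol in ("Gal", "GalNAc") for c in node.children)
        if has_h and has_backbone:
            return False          # H fucose caps a terminal Gal
        if has_ab and not has_h:
            return False          # A/B additions require the H fucose
    return True


def is_grammar_legal(tree: Glycan, grammar: TopologyGrammar = DEFAULT_GRAMMAR,
                     check_root: bool = True) -> bool:
    """Whether every residue of ``tree`` satisfies the grammar."""
    if check_root and tree.symbol not in grammar.roots + ("GalNAcol",):
        return False
    return all(_node_legal(node, grammar) for node in tree.walk())


def _sub_budgets(budget: Composition) -> Iterable[Composition]:
    ranges = [range(budget[cls] + 1) for cls in CLASS_ORDER]
    for counts in itertools.product(*ranges):
        yield Composition(dict(zip(CLASS_ORDER, counts)))


def _budget_minus(a: Composition, b: Composition) -> Composition:
    return Composition({cls: a[cls] - b[cls] for cls in CLASS_ORDER})


def _enumerate_subtrees(symbol: str, anomer: str, linkage: Optional[str],
                        budget: Composition,
                        grammar: TopologyGrammar) -> list[Glycan]:
    """All grammar-legal subtrees rooted at the given residue whose
    descendants consume exactly ``budget``."""
    proto = Glycan(symbol, anomer, linkage)
    rules = _child_rules(proto, grammar)
    out = []
    max_k = min(grammar.max_children, budget.total())
    for k in range(0, max_k + 1):
        for rule_set in itertools.combinations(rules, k):
            positions = [r[2] for r in rule_set]
            if len(set(positions)) != len(positions):
                continue
            for trees in _assign_budgets(rule_set, budget, grammar):
                node = Glycan(symbol, anomer, linkage, [t for t in trees])
                if _node_legal(node, grammar):
                    out.append(node)
    # dedupe structurally equivalent assemblies
    uniq = {}
    for t in out:
        uniq[t.to_condensed(_as_chain=linkage is not None)] = t
    return list(uniq.values())


def _assign_budgets(rule_set, budget: Composition,
                    grammar: TopologyGrammar) -> Iterable[list]:
    if not rule_set:
        if budget.total() == 0:
            yield []
        return
    (sym, anomer, pos), rest = rule_set[0], rule_set[1:]
    cls = MASS_CLASS[sym]
    if budget[cls] < 1:
        return
    after_self = budget.minus(cls)
    for sub in _sub_budgets(after_self):
        subtrees = _enumerate_subtrees(sym, anomer, pos, sub, grammar)
        if not subtrees:
            continue
        remaining = _budget_minus(after_self, sub)
        for tail in _assign_budgets(rest, remaining, grammar):
            for st in subtrees:
                yield [st] + tail


def generate_candidates(comp: Composition,
                        grammar: TopologyGrammar = DEFAULT_GRAMMAR,
                        roots: Sequence[str] = None) -> list[Glycan]:
    """Exhaustive, duplicate-free list of grammar-legal topologies with the
    given composition, in canonical-string order."""
    roots = tuple(roots) if roots is not None else grammar.roots
    results = {}
    for root_sym in roots:
        cls = MASS_CLASS[root_sym]
        if comp[cls] < 1:
            continue
        for tree in _enumerate_subtrees(root_sym, "?", None,
                                        comp.minus(cls), grammar):
            results[tree.to_condensed()] = tree
    return [results[k] for k in sorted(results)]


@dataclass(frozen=True)
class FragmentIon:
    mz: float
    loss: Composition  # residues lost relative to the precursor

    def annotation(self) -> str:
        if self.loss.total() == 0:
            return "[M]"
        if self.loss.to_string() == "":
            return "[M]"
        return "-" + self.loss.to_string()


@dataclass
class FragmentLadder:
    candidate: Glycan
    derivative: Derivative
    species: IonSpecies
    ions: list  # of FragmentIon, ascending mz

    def mz_values(self) -> list[float]:
        return [ion.mz for ion in self.ions]

    def nominal_set(self) -> set[int]:
        return {int(round(ion.mz)) for ion in self.ions}

    def contains(self, mz: float, tolerance: float) -> bool:
        return any(abs(ion.mz - mz) <= tolerance for ion in self.ions)


def _kept_compositions(node: Glycan) -> set[tuple]:
    """Compositions of every rooted subtree of ``node`` containing its root
    (as count tuples in CLASS_ORDER)."""
    own = Composition({node.mass_class: 1}).as_tuple()
    options = [{None} | {t for t in _kept_compositions(c)}
               for c in node.children]
    kept = set()
    for combo in itertools.product(*options) if options else [()]:
        total = list(own)
        for t in combo:
            if t is not None:
                total = [a + b for a, b in zip(total, t)]
        kept.add(tuple(total))
    return kept


def theoretical_Y_ions(candidate: Glycan,
                       derivative: Union[str, Derivative],
                       species: IonSpecies = DEPROTONATED) -> FragmentLadder:
    """Y-type fragment ladder: one ion for every loss that is a union of
    terminal subtrees, from the intact precursor down to the bare-aglycone
    Y0 ion."""
    deriv = get_derivative(derivative)
    full = candidate.composition()
    kept_tuples = _kept_compositions(candidate)
    kept_tuples.add(tuple(0 for _ in CLASS_ORDER))  # Y0: everything lost
    ions = {}
    for kept in kept_tuples:
        loss = Composition({cls: full[cls] - n
                            for cls, n in zip(CLASS_ORDER, kept)})
        mass = (deriv.mass
                + sum(RESIDUE_MASS[cls] * n
                      for cls, n in zip(CLASS_ORDER, kept)))
        mz = ion_mz(mass, species)
        ions[loss.as_tuple()] = FragmentIon(mz, loss)
    ladder = sorted(ions.values(), key=lambda i: i.mz)
    return FragmentLadder(candidate, deriv, species, ladder)


@dataclass(frozen=True)
class BranchEvidence:
    kind: str          # 'HexHexNAc-gap' | 'terminal-HexNAc-stub'
    upper_mz: float
    lower_mz: float
    gap: float


_HEX = RESIDUE_MASS["Hex"]
_HEXNAC = RESIDUE_MASS["HexNAc"]


def detect_branch(peaks: PeakList, tolerance: float = 0.5) -> list[BranchEvidence]:
    """Branch-point evidence from an MS/MS peak list.

    A pair of fragments separated by the combined Hex+HexNAc mass with no
    observed peak at either single-residue intermediate step indicates a
    simultaneous double loss, i.e. a branch.  Independently, when the
    precursor shows two different single-residue first losses, the HexNAc
    one marks a terminal HexNAc stub; a linear chain has a unique
    non-reducing terminus and cannot produce two first losses.
    """
    evidence = []
    mzs = list(peaks.mz)
    gap = _HEX + _HEXNAC
    for hi, lo in itertools.combinations(sorted(mzs, reverse=True), 2):
        if abs((hi - lo) - gap) > tolerance:
            continue
        inter_hex = hi - _HEX
        inter_hexnac = hi - _HEXNAC
        if (not peaks.has_peak_near(inter_hex, tolerance)
                and not peaks.has_peak_near(inter_hexnac, tolerance)):
            evidence.append(BranchEvidence("HexHexNAc-gap", hi, lo, hi - lo))
    precursor = peaks.precursor_mz if peaks.precursor_mz is not None else (
        max(mzs) if mzs else None)
    if precursor is not None:
        first_losses = {
            cls for cls in ("dHex", "Hex", "HexNAc")
            if peaks.has_peak_near(precursor - RESIDUE_MASS[cls], tolerance)
        }
        if "HexNAc" in first_losses and len(first_losses) >= 2:
            stub_mz = precursor - _HEXNAC
            observed = [m for m in mzs if abs(m - stub_mz) <= tolerance]
            evidence.append(BranchEvidence(
                "terminal-HexNAc-stub", precursor, observed[0],
                precursor - observed[0]))
    return evidence


@dataclass(frozen=True)
class MatchScore:
    matched_peaks: int
    unexplained_major_peaks: int
    matched_intensity_fraction: float
    branch_evidence: bool

    def sort_key(self) -> tuple:
        return (-self.matched_peaks, self.unexplained_major_peaks,
                -round(self.matched_intensity_fraction, 9))


def match_and_rank(peaks: PeakList,
                   candidates: Sequence[Glycan],
                   derivative: Union[str, Derivative],
                   species: IonSpecies = DEPROTONATED,
                   tolerance: float = 0.5,
                   major_fraction: float = 0.1) -> list[tuple]:
    """Rank candidate topologies by how well their Y-ladders explain the
    observed peaks.

    Deterministic ordering: matched peak count (desc), unexplained major
    peaks (asc; major = intensity >= ``major_fraction`` of the base peak),
    matched intensity fraction (desc), canonical string (asc).  Returns
    ``[(candidate, MatchScore), ...]``; ties in score are visible to the
    caller by comparing :meth:`MatchScore.sort_key`.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    branch_seen = bool(detect_branch(peaks, tolerance))
    base = peaks.base_peak_intensity()
    total_intensity = float(peaks.intensity.sum()) or 1.0
    scored = []
    for cand in candidates:
        ladder = theoretical_Y_ions(cand, derivative, species)
        matched = 0
        matched_intensity = 0.0
        unexplained_major = 0
        for mz, inten in zip(peaks.mz, peaks.intensity):
            if ladder.contains(float(mz), tolerance):
                matched += 1
                matched_intensity += float(inten)
            elif base and inten >= major_fraction * base:
                unexplained_major += 1
        score = MatchScore(matched, unexplained_major,
                           matched_intensity / total_intensity, branch_seen)
        scored.append((cand, score))
    scored.sort(key=lambda cs: cs[1].sort_key() + (cs[0].to_condensed(),))
    return scored
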
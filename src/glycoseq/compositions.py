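"""Enumerate monosaccharide compositions consistent with observed m/z.

Given a precursor m/z, an ion species and a set of candidate reducing-end
derivatives, every composition within the per-class count bounds whose
theoretical ion m/z lies inside the tolerance window is returned.  This is
the computation behind deducing e.g. ``dHex1Hex2HexNAc3-OY`` from a
nominal 2033 [M-H]- survey peak.

Defaults follow nominal-integer MALDI-TOF reporting: +/-0.5 Da tolerance,
counts bounded at 4 dHex / 8 Hex / 8 HexNAc / 2 NeuAc, and NeuAc excluded
(neutral-fraction workflows); all are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .glycan import CLASS_ORDER, Composition
from .masses import (DEPROTONATED, Derivative, IonSpecies, get_derivative,
                     ion_mz, neutral_mass)
from .peaklist import PeakList

__all__ = [
    "DEFAULT_BOUNDS",
    "CandidateMatch",
    "CompositionAssignment",
    "AssignmentSettings",
    "enumerate_compositions",
    "assign_peaks",
]

DEFAULT_BOUNDS = {"dHex": 4, "Hex": 8, "HexNAc": 8, "HexNAcol": 0, "NeuAc": 2}


@dataclass(frozen=True)
class CandidateMatch:
    composition: Composition
    derivative: Derivative
    theoretical_mz: float
    error: float  # observed - theoretical, Da

    def label(self) -> str:
        suffix = {"ADHP_OX": "-OX", "ADHP_OY": "-OY"}.get(
            self.derivative.tag, f"-{self.derivative.tag}")
        return self.composition.to_string() + suffix


@dataclass
class CompositionAssignment:
    mz: float
    intensity: float
    candidates: list  # of CandidateMatch, sorted by |error|
    flag: str         # 'unique' | 'ambiguous' | 'unassigned'


@dataclass
class AssignmentSettings:
    species: IonSpecies = DEPROTONATED
    derivatives: tuple = ("ADHP_OX", "ADHP_OY")
    tolerance: float = 0.5
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    include_neuac: bool = False


def _effective_bounds(bounds, include_neuac) -> dict:
    eff = dict(DEFAULT_BOUNDS)
    eff.update(bounds or {})
    if not include_neuac:
        eff["NeuAc"] = 0
    return eff


def enumerate_compositions(mz: float,
                           species: IonSpecies = DEPROTONATED,
                           derivatives: Iterable[Union[str, Derivative]] = (
                               "ADHP_OX", "ADHP_OY"),
                           tolerance: float = 0.5,
                           bounds: dict = None,
                           include_neuac: bool = False) -> list[CandidateMatch]:
    """All (composition, derivative) pairs whose ion m/z is within
    ``tolerance`` of ``mz``, exhaustively over the bounded count lattice.

    Sorted by |error|, ties broken by fewer total residues then by class
    counts and derivative tag, so output order is deterministic.
    """
    derivs = [get_derivative(d) for d in derivatives]
    if not derivs:
        raise ValueError("at least one candidate derivative is required")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    eff = _effective_bounds(bounds, include_neuac)
    hits = []
    ranges = [range(eff.get(cls, 0) + 1) for cls in CLASS_ORDER]
    for deriv in derivs:
        if deriv.tag != "alditol":
            local = list(ranges)
            local[CLASS_ORDER.index("HexNAcol")] = range(1)
        else:
            local = ranges
        for counts in itertools.product(*local):
            if sum(counts) < 1:
                continue
            comp = Composition(dict(zip(CLASS_ORDER, counts)))
            theo = ion_mz(neutral_mass(comp, deriv), species)
            err = mz - theo
            if abs(err) <= tolerance:
                hits.append(CandidateMatch(comp, deriv, theo, err))
    hits.sort(key=lambda c: (abs(c.error), c.composition.total(),
                             c.composition.as_tuple(), c.derivative.tag))
    return hits


def assign_peaks(peaks: PeakList,
                 settings: AssignmentSettings = None) -> list[CompositionAssignment]:
    """One composition assignment per survey peak, deterministic given
    settings; peaks with no candidate are flagged ``unassigned``."""
    settings = settings or AssignmentSettings()
    out = []
    for mz, inten in zip(peaks.mz, peaks.intensity):
        cands = enumerate_compositions(
            float(mz), settings.species, settings.derivatives,
            settings.tolerance, settings.bounds, settings.include_neuac)
        flag = ("unassigned" if not cands
                else "unique" if len(cands) == 1 else "ambiguous")
        out.append(CompositionAssignment(float(mz), float(inten), cands, flag))
    return out


def assignments_to_tsv(assignments: Sequence[CompositionAssignment], path) -> None:
    """Write assignments as TSV with composition labels like
    ``dHex1Hex2HexNAc3-OY``."""
    with open(path, "w") as fh:
        fh.write("# mz\tintensity\tflag\tcandidates\n")
        for a in assignments:
            labels = ";".join(
                f"{c.label()}@{c.theoretical_mz:.2f}({c.error:+.3f})"
                for c in a.candidates)
            fh.write(f"{a.mz:.4f}\t{a.intensity:.4f}\t{a.flag}\t{labels}\n")
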
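"""Monoisotopic mass bookkeeping for glycans, reducing-end tags and ions.

The neutral mass of a derivatized glycan is the sum of its residue masses
(free monosaccharide minus water) plus an *aglycone* term carrying every
atom beyond the glycosyl residues: the reducing-end remnant and the tag
chemistry.  For the fluorescent anthracenyl lipid tag (ADHP,
N-aminoacetyl-N-(9-anthracenylmethyl)-1,2-dihexadecyl-sn-glycero-3-
phosphoethanolamine, C54H91N2O7P) three aglycones are distinguished:

* ``ADHP_reducing`` — intact reducing glycan, reductive amination
  (net ADHP + H2 relative to the residue sum);
* ``ADHP_OY`` — the arm that was 6-linked to a periodate-cleaved reduced
  core GalNAcol, retaining an -O-CH2-CH2- remnant (ADHP + C2H4O);
* ``ADHP_OX`` — the 3-linked arm, which additionally retains the
  CH(NHAc)-CH2OH fragment of the core (OY + C4H8NO2).

Printed MALDI-TOF values are matched by rounding computed monoisotopic
m/z to the nearest integer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Union

from .glycan import CLASS_ORDER, Composition, Glycan

__all__ = [
    "Derivative",
    "IonSpecies",
    "PROTON_MASS",
    "SODIUM_ADDUCT_MASS",
    "RESIDUE_MASS",
    "DERIVATIVES",
    "formula_mass",
    "aglycone_mass",
    "neutral_mass",
    "ion_mz",
    "nominal",
    "periodate_scission",
    "ScissionProduct",
]

#: Mass of a proton, used for (de)protonation arithmetic.
PROTON_MASS = 1.00728

#: Na+ adduct mass (Na minus one electron).
SODIUM_ADDUCT_MASS = 22.98922


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a Hill-style elemental formula like C6H10O5."""
    from pyteomics.mass import calculate_mass
    return float(calculate_mass(formula=formula))


@dataclass(frozen=True)
class Derivative:
    """A reducing-end tag: its aglycone elemental formula and provenance."""

    tag: str
    aglycone_formula: str
    notes: str = ""

    @property
    def mass(self) -> float:
        return formula_mass(self.aglycone_formula)


def _load_constants() -> tuple[dict, dict]:
    text = (resources.files("glycoseq") / "data" / "mass_constants.json").read_text()
    raw = json.loads(text)
    residues = {cls: formula_mass(f) for cls, f in raw["residues"].items()}
    derivatives = {
        tag: Derivative(tag, entry["formula"], entry.get("notes", ""))
        for tag, entry in raw["derivatives"].items()
    }
    return residues, derivatives


RESIDUE_MASS, DERIVATIVES = _load_constants()


def load_mass_table(path) -> tuple[dict, dict]:
    """Load an alternative residue/derivative table from a JSON file with
    the same layout as the packaged ``mass_constants.json``."""
    with open(path) as fh:
        raw = json.load(fh)
    residues = {cls: formula_mass(f) for cls, f in raw["residues"].items()}
    derivatives = {
        tag: Derivative(tag, entry["formula"], entry.get("notes", ""))
        for tag, entry in raw["derivatives"].items()
    }
    return residues, derivatives


def get_derivative(tag_or_derivative: Union[str, Derivative]) -> Derivative:
    if isinstance(tag_or_derivative, Derivative):
        return tag_or_derivative
    try:
        return DERIVATIVES[tag_or_derivative]
    except KeyError:
        raise KeyError(f"unknown derivative tag {tag_or_derivative!r}; "
                       f"known: {sorted(DERIVATIVES)}") from None


def aglycone_mass(derivative: Union[str, Derivative]) -> float:
    """Monoisotopic mass of all atoms beyond the summed glycosyl residues."""
    return get_derivative(derivative).mass


def neutral_mass(x: Union[Glycan, Composition],
                 derivative: Union[str, Derivative]) -> float:
    """Neutral monoisotopic mass of a derivatized glycan or composition.

    Topology-independent: a tree and its composition give the same value.
    """
    deriv = get_derivative(derivative)
    comp = x.composition() if isinstance(x, Glycan) else x
    if comp.total() < 1:
        raise ValueError("composition must contain at least one residue")
    if comp["HexNAcol"] and deriv.tag != "alditol":
        raise ValueError(
            "HexNAcol (reduced core) is only meaningful with the alditol "
            f"derivative, not {deriv.tag!r}")
    return sum(RESIDUE_MASS[cls] * comp[cls] for cls in CLASS_ORDER) + deriv.mass


@dataclass(frozen=True)
class IonSpecies:
    """Singly charged ion species used in MALDI work."""

    polarity: str  # 'negative' | 'positive'
    adduct: str    # 'deprotonated' | 'protonated' | 'sodiated'
    charge: int = 1

    def __post_init__(self):
        if self.charge != 1:
            raise ValueError("only singly charged species are supported")
        valid = {
            ("negative", "deprotonated"),
            ("positive", "protonated"),
            ("positive", "sodiated"),
        }
        if (self.polarity, self.adduct) not in valid:
            raise ValueError(
                f"unsupported species {self.polarity}/{self.adduct}")


DEPROTONATED = IonSpecies("negative", "deprotonated")
PROTONATED = IonSpecies("positive", "protonated")
SODIATED = IonSpecies("positive", "sodiated")


def ion_mz(neutral: float, species: IonSpecies = DEPROTONATED) -> float:
    """m/z of the singly charged adduct of a neutral mass."""
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    if species.adduct == "deprotonated":
        return neutral - PROTON_MASS
    if species.adduct == "protonated":
        return neutral + PROTON_MASS
    return neutral + SODIUM_ADDUCT_MASS


def nominal(mz: float) -> int:
    """Round-to-nearest-integer view for comparison with printed values."""
    return int(round(mz))


@dataclass(frozen=True)
class ScissionProduct:
    """One arm released by periodate cleavage of a reduced GalNAcol core."""

    branch: Glycan
    derivative: Derivative
    origin_position: str  # '3' or '6' on the core


def periodate_scission(core: Glycan) -> list[ScissionProduct]:
    """Split a GalNAcol-rooted alditol at the core, tagging each arm.

    Mild periodate oxidation cleaves the open-chain GalNAcol; after
    conjugation the arm from the core 3-position carries the OX aglycone
    and the arm from the 6-position the OY aglycone.  A 3,6-disubstituted
    core yields exactly two products.
    """
    if core.symbol != "GalNAcol":
        raise ValueError(
            f"periodate scission requires a GalNAcol root, got {core.symbol}")
    products = []
    for child in core.children:
        if child.linkage == "3":
            tag = DERIVATIVES["ADHP_OX"]
        elif child.linkage == "6":
            tag = DERIVATIVES["ADHP_OY"]
        else:
            raise ValueError(
                f"core GalNAcol arm at position {child.linkage!r}; only 3- "
                "and 6-linked arms survive periodate scission bookkeeping")
        products.append(ScissionProduct(child.copy(linkage=None), tag,
                                        child.linkage))
    products.sort(key=lambda p: p.origin_position)
    return products
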
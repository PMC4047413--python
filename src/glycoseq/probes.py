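"""Sequence-defined probe structures for the focused blood-group array.

These are the classical red-cell and milk-sugar glycans used to map the
epitope: linear vs branched poly-N-acetyllactosamine backbones carrying
blood-group H, A or B caps.  Glycolipid probes are represented by their
glycan moiety only (the ceramide is not modelled); the mucin O-glycan
probe 4M-f1 is the 6-arm NGL hexasaccharide.

Most structures follow their published assignments.  The three probes
marked SYNTHETIC below (type-1 branched H analogues and the branched
difucosylated Lewis-y analogue) are plausible reconstructions consistent
with their verbal descriptions, shipped so the qualitative
positive/negative split can be exercised; they are synthetic stand-ins,
not literature transcriptions.
"""

from __future__ import annotations

from .glycan import Glycan, parse_condensed

__all__ = ["PROBE_STRUCTURES", "FOCUSED_ARRAY", "F77_POSITIVE", "F77_NEGATIVE"]

_STRINGS = {
    # linear H type 2 heptaglycosylceramide
    "H2": "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
    # branched H type 2 decaglycosylceramide (H on both arms)
    "H3": ("Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)"
           "[Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)]"
           "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # linear blood group A octaglycosylceramide
    "Ab": ("GalNAc(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-3)"
           "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # branched blood group A tetradecaglycosylceramide
    "Ad": ("GalNAc(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-6)"
           "[GalNAc(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-3)]"
           "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # branched blood group B dodecaglycosylceramide
    "BIII": ("Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-6)"
             "[Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-3)]"
             "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # branched blood group B tetradecaglycosylceramide
    "BIV": ("Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-6)"
            "[Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-3)]"
            "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # unbranched blood group B hexaglycosylceramide
    "B-hexa": "Gal(a1-3)[Fuc(a1-2)]Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
    # branched "B-like" decaglycosylceramide lacking the a1-2 fucose
    "B-like": ("Gal(a1-3)Gal(b1-4)GlcNAc(b1-6)"
               "[Gal(a1-3)Gal(b1-4)GlcNAc(b1-3)]"
               "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # branched I-antigen octaglycosylceramide (no caps)
    "I-octa": ("Gal(b1-4)GlcNAc(b1-6)[Gal(b1-4)GlcNAc(b1-3)]"
               "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # lacto-N-neofucopentaose I (linear type 2 H pentasaccharide)
    "LnNFPI": "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
    # the mucin O-glycan 6-arm NGL hexasaccharide (branch linkages
    # assigned by analogy to I-type backbones; flagged inferred upstream)
    "4M-f1": "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)[GlcNAc(b1-3)]Gal(b1-4)GlcNAc",
    # SYNTHETIC stand-in: branched difucosylated Lewis-y analogue
    "LeY-branched": ("Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-6)"
                     "[Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-3)]"
                     "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # SYNTHETIC stand-in: branched H on type 1 backbone units
    "H-T1-branched": ("Fuc(a1-2)Gal(b1-3)GlcNAc(b1-6)"
                      "[Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)]"
                      "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc"),
    # synthetic linear/branched reference pentasaccharides
    "Orsay-1": "Gal(b1-4)GlcNAc(b1-6)Gal",
    "Orsay-6": "Gal(b1-4)GlcNAc(b1-6)[Gal(b1-4)GlcNAc(b1-3)]Gal",
    "Orsay-7": "Gal(b1-4)GlcNAc(b1-6)[Gal(b1-3)GlcNAc(b1-3)]Gal",
}

#: Parsed probe structures, keyed by probe name.
PROBE_STRUCTURES: dict[str, Glycan] = {
    name: parse_condensed(s) for name, s in _STRINGS.items()
}

#: The focused-array fixture: every probe identifiable from the published
#: descriptions (unnamed probes of the physical array are not included).
FOCUSED_ARRAY: list[tuple[str, Glycan]] = [
    (name, PROBE_STRUCTURES[name])
    for name in ("H2", "H3", "Ab", "Ad", "BIII", "BIV", "B-hexa", "B-like",
                 "I-octa", "LnNFPI", "4M-f1", "LeY-branched", "H-T1-branched")
]

#: Qualitative antigen-positivity split of the focused array.
F77_POSITIVE = ("H3", "Ad", "BIII", "BIV", "4M-f1")
F77_NEGATIVE = ("H2", "Ab", "B-hexa", "B-like", "I-octa", "LnNFPI",
                "LeY-branched", "H-T1-branched")
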
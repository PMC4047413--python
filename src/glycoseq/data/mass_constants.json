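{
  "version": 1,
  "comment": "Monoisotopic mass constants for glycan residue classes and reducing-end derivatives. Residue formulas are the free monosaccharide minus H2O, except HexNAcol which additionally retains the core water freed on periodate-independent reduction bookkeeping (alditol aglycone is then H2). Aglycone formulas are everything in the neutral molecule beyond the summed glycosyl residues.",
  "residues": {
    "dHex": "C6H10O4",
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "HexNAcol": "C8H15NO6",
    "NeuAc": "C11H17NO8"
  },
  "derivatives": {
    "free": {
      "formula": "H2O",
      "notes": "unmodified reducing glycan; terminal H/OH"
    },
    "alditol": {
      "formula": "H2",
      "notes": "borohydride-reduced glycan; the extra ring water is carried by the HexNAcol residue class"
    },
    "2AB": {
      "formula": "C7H10N2O",
      "notes": "2-aminobenzamide label by reductive amination (free aglycone + C7H8N2)"
    },
    "ADHP_reducing": {
      "formula": "C54H93N2O7P",
      "notes": "anthracenyl fluorescent lipid tag on an intact reducing glycan by reductive amination (ADHP C54H91N2O7P + H2)"
    },
    "ADHP_OY": {
      "formula": "C56H95N2O8P",
      "notes": "6-linked branch of a periodate-cleaved GalNAcol core: -OCH2-CH2- remnant conjugated to ADHP (ADHP + C2H4O)"
    },
    "ADHP_OX": {
      "formula": "C60H103N3O10P",
      "notes": "3-linked branch of a periodate-cleaved GalNAcol core: -OCH2-CH(NHAc)-CH2OH remnant conjugated to ADHP (OY + C4H8NO2)"
    },
    "DHPE_reducing": {
      "formula": "C37H80NO6P",
      "notes": "non-fluorescent phosphatidylethanolamine tag by reductive amination (DHPE C37H78NO6P + H2); constants shipped for completeness"
    },
    "AOPE_oxime": {
      "formula": "C39H81N2O8P",
      "notes": "aminooxy-acetyl DHPE tag by oxime ligation (net addition of AOPE, loss of H2O vs the free glycan); constants shipped for completeness"
    }
  }
}
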
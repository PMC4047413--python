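# glycoseq

Glycan mass-spectrometric structure elucidation and microarray motif
analysis, built for the *O*-glycome "designer array" workflow: release the
*O*-glycans of an antigen-bearing mucin, convert them to lipid-tagged
neoglycolipids (NGLs), locate the antibody-positive components on an
array, and assign their carbohydrate sequence by MALDI-MS and CID-MS/MS.

It is aimed at glycomics practitioners who need the *computational* half
of that workflow to be explicit, scriptable and testable:

* **Derivative-aware mass bookkeeping.** Neutral masses are
  `Σ residue masses + aglycone`, where the aglycone carries every atom
  beyond the glycosyl residues. The fluorescent anthracenyl lipid tag
  (ADHP, C54H91N2O7P) appears in three flavours: conjugated to an intact
  reducing glycan, or to the two arms released by mild periodate cleavage
  of the reduced core GalNAc-ol — the 6-linked arm retains
  `-O-CH2-CH2-` (**OY** = ADHP + C2H4O) and the 3-linked arm additionally
  retains `CH(NHAc)-CH2OH` (**OX** = OY + C4H8NO2, +102 Da). Singly
  charged \[M−H\]⁻, \[M+H\]⁺ and \[M+Na\]⁺ ions are supported; printed
  MALDI-TOF values are matched by rounding monoisotopic m/z to the
  nearest integer.
* **Composition enumeration.** Exhaustive search of the bounded count
  lattice over {dHex, Hex, HexNAc, NeuAc} × candidate derivatives within
  a tolerance window, the computation behind "m/z 2033 ⇒
  dHex₁Hex₂HexNAc₃-OY".
* **Y-ion ladder sequencing.** Candidate branched topologies are
  enumerated under a biosynthetic grammar (poly-*N*-acetyllactosamine
  backbones, β1-6 branching, blood-group H/A/B and Lewis caps), their
  Y-type neutral-loss ladders predicted, and candidates ranked against
  the observed MS/MS peaks. A simultaneous Hex+HexNAc loss (365 Da) with
  no single-residue intermediate is reported as branch-point evidence.
* **Exoglycosidase verification.** Digestion as pure specificity rules on
  the tree, plus pre/post mass-shift consistency checks (e.g. a 146 Da
  loss ⇒ one fucose).
* **Array analysis.** Duplicate-spot summarization (mean, half the
  difference), threshold/fold-over-control hit calling, inference of the
  minimal subtree pattern separating bound from unbound probes, and
  temperature-series monotonicity (cold-agglutinin behaviour).
* **Synthetic data.** A fully seeded generator of mucin-type O-glycomes,
  their NGL products and peak lists, and motif-driven binding tables, so
  every stage is testable end to end without instrument data.

Glycans are written in an ASCII condensed notation,
`Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)[GlcNAc(b1-3)]Gal(b1-4)GlcNAc`, reading
from the non-reducing end; branches sit in square brackets before their
attachment residue. Motif patterns extend the dialect with `*` (any
residue), `?` (any anomer/position) and a `!` suffix marking a residue as
*closed* (no unmatched substituents allowed on the matched residue).

## Worked example

The antigen-positive NGL of the mucin *O*-glycome gives a survey ion at
nominal m/z 2033 and the MS/MS fragments 1887, 1830, 1725, 1522, 1157
and 954:

```python
from glycoseq import (enumerate_compositions, generate_candidates,
                      match_and_rank, detect_branch, verify_shift,
                      PSM_GRAMMAR, PROTONATED)
from glycoseq.peaklist import PeakList

hits = enumerate_compositions(2033.0)
print(hits[0].label(), round(hits[0].theoretical_mz, 2))
# dHex1Hex2HexNAc3-OY 2033.08

cands = generate_candidates(hits[0].composition, PSM_GRAMMAR)
peaks = PeakList.from_pairs(
    [(2033, 100), (1887, 60), (1830, 30), (1725, 45),
     (1522, 50), (1157, 40), (954, 20)],
    level="MS2", precursor_mz=2033.0)
for ev in detect_branch(peaks):
    print(ev.kind, round(ev.upper_mz), round(ev.lower_mz))
# HexHexNAc-gap 1522 1157
# terminal-HexNAc-stub 2033 1830

top, score = match_and_rank(peaks, cands, "ADHP_OY")[0]
print(top.to_condensed(), score.matched_peaks, score.unexplained_major_peaks)
# Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)[GlcNAc(b1-3)]Gal(b1-4)GlcNAc 7 0

check = verify_shift(2035.0, 1889.0, "a1-2-fucosidase", PROTONATED)
print(check.consistent, check.inferred_removals)
# True 1
```

Reading: the 2033 ion is uniquely a fucosylated hexasaccharide from a
6-linked core arm (OY tag); the 365 Da gap between 1522 and 1157 marks a
branch point and the 1830 fragment a terminal HexNAc stub; of the 61
grammar-legal topologies, the branched blood-group-H sequence explains
all seven fragments with nothing left over; and the 2035→1889 shift
after α1-2 fucosidase treatment corresponds to exactly one fucose.

The same steps are available from the shell
(`glycoseq compose | sequence | digest | array | simulate | elucidate`);
`glycoseq elucidate --config run.json --out out/` chains them and writes
a structured JSON report.

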
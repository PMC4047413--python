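# Methods

This note documents the models and numerical conventions behind
`glycoseq`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Glycan representation and notation

A glycan is a rooted tree of monosaccharide residues; the root is the
reducing-end (or reduced, or tag-bearing) residue. Each non-root residue
records its anomeric configuration (`a`, `b`, `?`) and the acceptor
position on its parent (`2`–`6`, `?`). Residue symbols map to fixed mass
classes: Fuc→dHex; Gal, Glc→Hex; GlcNAc, GalNAc→HexNAc; GalNAcol→
HexNAcol; NeuAc→NeuAc. Ring stereochemistry and 3-D structure are out of
scope.

Serialization is canonical: among siblings, the child on the highest
acceptor position is written in the main chain and lower positions are
bracketed (so the 6-arm is main-chain at an I-type branch); remaining
ties are broken by the subtree string. Canonicalization makes tree
equality equal string equality and is idempotent under parse/write.
Unknown values (`?`) are permitted in trees and patterns and match
anything during motif matching; sibling acceptor positions must be
distinct only when both are known. Branching is bounded at two
substituents per Hex/HexNAc residue by default (the biosynthetic limit),
configurable at parse time.

## Mass model

Monoisotopic masses throughout. Residue masses are the free
monosaccharide minus water (dHex 146.0579, Hex 162.0528, HexNAc
203.0794, NeuAc 291.0954 Da); elemental masses come from pyteomics. The
neutral mass of a derivatized glycan is the residue sum plus an
*aglycone* term, the atoms beyond the residues:

| tag | aglycone | rationale |
|---|---|---|
| free | H2O | terminal H/OH |
| alditol | H2 | borohydride reduction; the ring water rides on the HexNAcol class (221.0899 = HexNAc + H2O) |
| 2AB | C7H10N2O | reductive amination: +C7H8N2 over the free glycan |
| ADHP_reducing | C54H93N2O7P | ADHP + H2 |
| ADHP_OY | C56H95N2O8P | ADHP + C2H4O: the `-O-CH2-CH2-` remnant of a 6-linked core arm |
| ADHP_OX | C60H103N3O10P | OY + C4H8NO2: additionally the `CH(NHAc)-CH2OH` core fragment |

The ADHP elemental formula C54H91N2O7P (910.656 Da) is derived from its
systematic name — the DHPE ether lipid C37H78NO6P plus a glycyl
(C2H3NO) and an anthracen-9-ylmethyl (C15H10) substituent — and frozen
as a constant; a unit test ties it to the observable identity that a
dHex1Hex2HexNAc3-OY NGL deprotonates to nominal m/z 2033. The OX−OY
aglycone difference equals C4H8NO2 (102.0555 Da) to <0.001 Da by
construction, and is testable as a 102 nominal split between arm pairs.
Constants live in a versioned JSON file shipped with the package and can
be overridden at run time. DHPE/AOPE tags (non-fluorescent arrays) share
the arithmetic; their constants are included but not exercised by any
headline value.

Adduct arithmetic uses the proton mass 1.00728 Da (not the H-atom mass;
the difference is far below the 0.5 Da reporting tolerance but stated
for determinism) and Na−e⁻ = 22.98922 Da; only singly charged species
are modelled. Printed instrument values are matched by
round-to-nearest-integer; rounding (rather than truncation) reproduces
every worked value, including 2033.08. Isotope patterns, multiple
charging and in-source fragmentation are not modelled.

## Composition enumeration

Exhaustive scan of the count lattice within per-class bounds (defaults
4 dHex, 8 Hex, 8 HexNAc, 2 NeuAc — enough to cover species beyond
undecasaccharides) for each candidate derivative, keeping candidates
within the m/z tolerance (default ±0.5 Da, matching nominal-integer
MALDI-TOF reporting). NeuAc is excluded by default because the intended
inputs are neutral-fraction glycans; a flag re-enables it. Output order
is deterministic: |error|, then fewer residues, then class counts, then
derivative tag. Results are returned per peak with a
unique/ambiguous/unassigned flag. Deisotoping, peak picking and
recalibration are out of scope: inputs are centroided peak lists.

## Topology grammar and Y-ladder sequencing

Candidate structures for a composition are enumerated under a
biosynthetic grammar: GlcNAc extends Gal at 3 (elongation) or 6
(branching); Gal extends GlcNAc at 4 (type 2) or 3 (type 1); caps are
Fuc a1-2 on an otherwise unextended Gal (blood-group H), GalNAc/Gal a1-3
on an H-fucosylated Gal (A/B), and Fuc a1-3/4 on GlcNAc (Lewis). The
default grammar allows both backbone types; `PSM_GRAMMAR` applies the
gastric-mucin prior in which type 1 units are absent. Enumeration is
exhaustive and deduplicated by canonical form; equivalence with a
brute-force scan over all labeled rooted trees is tested up to six
residues.

Fragment prediction covers Y-type ions only (negative-mode CID of
lipid-tagged glycans is dominated by neutral-loss species retaining the
tag); B/C/Z ions are out of scope. A ladder contains one ion per loss
that is a union of terminal subtrees, from the intact precursor to the
bare-aglycone Y0. Loss annotations are multisets — when two arms could
have produced the same loss the ambiguity is inherent and is surfaced,
not resolved.

Branch detection reports (i) peak pairs separated by Hex+HexNAc
(365.13 Da) with no observed peak at either single-residue intermediate,
and (ii) a single-HexNAc first loss from the precursor *when a second,
different first loss is also present* — a linear chain has one
non-reducing terminus and cannot lose two different residues first, so
this co-occurrence condition keeps complete linear ladders evidence-free
while still flagging the terminal-HexNAc stub of a branched arm.

Ranking is by matched peak count, then unexplained major peaks
(major = ≥10 % of the base peak; the threshold is a package convention,
configurable), then matched intensity fraction, then canonical string.
The ordering is invariant under peak-list permutation and intensity
rescaling. Exact score ties are exposed to the caller: arm-swap isomers
(3- vs 6-linkage of mass-identical branches) are genuinely
indistinguishable from Y-ladders alone, and the published branch
assignment of the mucin hexasaccharide rests on backbone analogy, not on
a mass difference — the fixtures flag those linkages as inferred.
One annotated fragment deserves note: the published 954 ion is described
as a dHex loss from 1157, but 1157 − 954 is a HexNAc mass; 954 is
instead consistent with the bare OY aglycone Y0 ion (953.68), and that
is how it is modelled here.

## Exoglycosidase simulation

Enzymes are pure specificity rules (symbol set, anomer, allowed
linkages, terminal-only); digestion removes matching terminal residues
to exhaustion, never the tag-bearing root, and is idempotent. No
kinetics or steric hindrance; a partial mode yields the intermediates of
an incomplete digest in deterministic order. Mass-shift verification
accepts a pre/post pair as consistent when the difference is an integer
multiple k of the target residue mass within tolerance, reporting k = 0
as "no digestion". Residues with unknown anomer/linkage are treated as
non-substrates.

## Array analysis

Duplicate-spot rows summarize as mean (a+b)/2 and half-difference
|a−b|/2; other replicate counts fall back to half the range and are
flagged. Hit calling is positive when a probe's mean is ≥ f_max of the
maximal probe mean AND ≥ k-fold its isotype-control mean; the published
workflow states no numeric criterion, so the defaults f_max = 0.1 and
k = 5 are package conventions chosen to reproduce the qualitative hit
sets on the fixtures, and both are exposed in config. Structure-less
probes (glycoproteins) participate in summarization and hit calling but
not in motif inference.

Motif patterns are glycan fragments with wildcards plus a per-node
open/closed flag: a *closed* node requires every substituent of the
matched residue to be matched by a pattern child, while open nodes
tolerate extras. This flag is the smallest extension that lets one
pattern express "blood-group H on a 6-linked branch, additional a1-3
caps on the fucosylated Gal tolerated, but no a1-3 fucose on the
GlcNAc": plain injective containment cannot exclude the branched
Lewis-y analogue (which contains the open H-motif as a subgraph), and
fully exact matching cannot admit the A/B analogues. Terminal anchoring
is the special case in which every pattern leaf is closed.

Discriminating-motif inference enumerates connected fragments of the
smallest positive structure (any shared motif must embed there), each
optionally extended by a wildcard parent carrying the branch-attachment
linkage, under all open/closed assignments up to a size cap (default 6
residues); patterns present in every positive and absent from every
negative are filtered to the most general ones (structural subsumption),
smallest first. On the focused-array fixture the unique minimal result
is `Fuc(a1-2)Gal(b1-4)GlcNAc!(b1-6)*`. An empty result is a reported
outcome, not an error. Field-level wildcard generalization (beyond the
added parent) is not searched; planted concrete motifs are therefore
recovered up to generalization, which the tests check by subsumption.

Temperature series are judged on per-probe means: strictly-decreasing,
flat (constant, reported as a flagged non-monotone case) or
non-monotone. No thermodynamic model is fitted.

## Synthetic-data generator

The generator emulates an A/H-positive gastric-mucin O-glycome: core 1
(Galβ1-3GalNAcol) and core 2 (plus GlcNAcβ1-6) alditols, type 2
poly-N-acetyllactosamine extension, I-type β1-6 branching, H capping
with A additions, optional B/Lewis capping, and a residue-count cap.
Defaults — 60 % core 2, extension 0.55/step, branching 0.25, H cap 0.35,
A-on-H 0.30, B 0, Lewis 0.05, type 1 0, cap 12 residues — produce
alditols spanning penta- through dodecasaccharides with the epitope
confined to a minor fraction (~6 % of structures), mirroring the
minor-component character of the antigen. No published abundance
distribution exists for this O-glycome; these rates are modelling
choices, stated once and not tuned further.

Release simulation routes alditols through periodate scission (OX/OY
arms with ground truth retained) or emits intact reducing glycans for
the hydrazinolysis route, with an optional peeling artifact (core loss,
default off). Spectra carry a calibration offset, per-peak Gaussian
jitter, log-normal intensities and peak dropout; all randomness flows
through explicitly seeded NumPy generators with no global state, so
identical parameters give byte-identical outputs. Binding tables draw
log-normal intensities around μ₊·s(T) for motif-positive probes and
μ₋·s(T) otherwise, with s(4) > s(20) > s(37) enforcing the
cold-agglutinin ordering in expectation; the isotype-control table is
motif-blind noise.

What passing tests on synthetic data do **not** show: fidelity to real
abundances or chromatographic behaviour (size fractions are emulated
only as subsets), real calibration drift structure, cross-ring
fragmentation, partial digestion kinetics, or array spot-level
artifacts. The generator shares the package's mass tables by design —
recovery tests validate the inference logic, not the constants; the
constants are pinned independently by the printed-value tests.

## Problem sizes and numerical conventions

Default tolerances: ±0.5 Da (nominal-integer data), 0.2–0.3 Da in
recovery tests of simulated high-quality data. Brute-force
cross-checks run at ≤6 residues (topology), bounds ≤8 per class
(composition) and ≤6-residue patterns (motifs); recovery suites use
100–500 simulated structures. These sizes make every enumeration exact
and keep the whole suite fast while covering all structural regimes
(linear/branched, capped/uncapped, both derivative tags). Degenerate
inputs are defined outcomes: empty peak lists assign to nothing,
compositions unreachable under the grammar yield empty candidate lists,
identical positive/negative probe sets yield no motif, and an all-zero
array yields no hits.
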
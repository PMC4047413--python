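"""Synthetic mucin-type O-glycomes, spectra and array binding tables.

The generator emulates the inputs of the structure-elucidation pipeline
with full seed determinism: core-1/core-2 O-glycan alditols extended with
poly-N-acetyllactosamine backbones, 6-branching and blood-group capping;
their periodate-scission NGL products with survey (MS1) and Y-ladder
(MS/MS) peak lists under calibration noise; and duplicate-spot binding
tables driven by a hidden epitope motif with cold-agglutinin temperature
scaling.  Ground truth is retained alongside every simulated observable.

All randomness flows through ``numpy.random.default_rng`` seeded from the
parameter objects; identical parameters give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .glycan import Composition, Glycan, MotifPattern, contains_motif
from .masses import (DEPROTONATED, DERIVATIVES, IonSpecies, ion_mz,
                     neutral_mass, periodate_scission)
from .peaklist import PeakList
from .sequencing import theoretical_Y_ions

__all__ = [
    "GlycomeParams",
    "SpectrumNoise",
    "BindingModel",
    "ProductTruth",
    "SimulatedSpectra",
    "simulate_oglycome",
    "simulate_release_and_spectra",
    "simulate_array",
]


@dataclass(frozen=True)
class GlycomeParams:
    """Rates of the simulated mucin O-glycan biosynthesis.

    Defaults emulate an A/H-positive gastric mucin O-glycome: a core-2
    majority, moderate poly-N-acetyllactosamine extension spanning penta-
    to undeca-saccharide alditols, occasional I-type 6-branching, frequent
    blood-group H capping with A additions, no B additions, and type 2
    backbones only.  Where no published abundances exist the values are
    plain modelling choices, documented as such.
    """

    n_structures: int = 500
    core2_weight: float = 0.6       # core 2 vs core 1
    extension_prob: float = 0.55    # add one more LacNAc unit
    branch_prob: float = 0.25       # b1-6 GlcNAc branch on a backbone Gal
    h_cap_prob: float = 0.35        # Fuc a1-2 on a terminal Gal
    a_on_h_prob: float = 0.30       # GalNAc a1-3 on an H-capped Gal
    b_on_h_prob: float = 0.0        # Gal a1-3 on an H-capped Gal
    lewis_prob: float = 0.05        # Fuc a1-3 on GlcNAc
    type1_prob: float = 0.0         # Gal b1-3 (type 1) vs b1-4 (type 2)
    max_residues: int = 12
    seed: int = 0


@dataclass(frozen=True)
class SpectrumNoise:
    """Peak-list degradation model (all off -> exact theoretical values)."""

    mz_jitter_sd: float = 0.05      # Da, per-peak Gaussian
    calibration_offset: float = 0.0  # Da, constant shift
    dropout_prob: float = 0.05      # per fragment peak
    intensity_log_sd: float = 0.5   # log-normal intensity spread
    seed: int = 0

    def __post_init__(self):
        if self.mz_jitter_sd < 0:
            raise ValueError("jitter SD must be non-negative")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout probability must be in [0, 1)")


@dataclass
class BindingModel:
    """Hidden-epitope binding model for array simulation.

    Motif-positive probes draw intensities around ``mu_pos * s(T)``,
    others around ``mu_neg * s(T)``, log-normally; the temperature scale
    factors decrease with temperature (cold-agglutinin behaviour), so
    positive-probe means decrease strictly with temperature.
    """

    motif: MotifPattern
    mu_pos: float = 40000.0
    mu_neg: float = 250.0
    log_sd: float = 0.15
    temp_scale: dict = field(default_factory=lambda: {4: 1.3, 20: 1.0, 37: 0.45})
    control_mu: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.mu_pos <= self.mu_neg:
            raise ValueError("positive mean must exceed negative mean")
        temps = sorted(self.temp_scale)
        scales = [self.temp_scale[t] for t in temps]
        if any(s <= 0 for s in scales):
            raise ValueError("temperature scales must be positive")
        if any(a <= b for a, b in zip(scales, scales[1:])):
            raise ValueError("temperature scales must decrease with temperature")


# ---------------------------------------------------------------------------
# O-glycome generation
# ---------------------------------------------------------------------------

class _Budget:
    def __init__(self, limit: int):
        self.limit = limit
        self.used = 0

    def take(self, n: int = 1) -> bool:
        if self.used + n > self.limit:
            return False
        self.used += n
        return True


def _grow_gal(gal: Glycan, params: GlycomeParams, rng, budget: _Budget) -> None:
    extended = False
    if rng.random() < params.extension_prob and budget.take():
        pos = "3"
        glcnac = Glycan("GlcNAc", "b", pos)
        gal.add_child(glcnac)
        _grow_glcnac(glcnac, params, rng, budget)
        extended = True
    if rng.random() < params.branch_prob and budget.take():
        glcnac = Glycan("GlcNAc", "b", "6")
        gal.add_child(glcnac)
        _grow_glcnac(glcnac, params, rng, budget)
        extended = True
    if not extended and rng.random() < params.h_cap_prob and budget.take():
        gal.add_child(Glycan("Fuc", "a", "2"))
        r = rng.random()
        if r < params.a_on_h_prob and budget.take():
            gal.add_child(Glycan("GalNAc", "a", "3"))
        elif r < params.a_on_h_prob + params.b_on_h_prob and budget.take():
            gal.add_child(Glycan("Gal", "a", "3"))


def _grow_glcnac(glcnac: Glycan, params: GlycomeParams, rng, budget: _Budget) -> None:
    if rng.random() < params.extension_prob and budget.take():
        pos = "3" if rng.random() < params.type1_prob else "4"
        gal = Glycan("Gal", "b", pos)
        glcnac.add_child(gal)
        _grow_gal(gal, params, rng, budget)
        if rng.random() < params.lewis_prob and budget.take():
            fuc_pos = "4" if pos == "3" else "3"
            glcnac.add_child(Glycan("Fuc", "a", fuc_pos))


def simulate_oglycome(params: GlycomeParams) -> list[Glycan]:
    """GalNAcol-rooted O-glycan alditols, reproducible by seed."""
    rng = np.random.default_rng(params.seed)
    glycome = []
    for _ in range(params.n_structures):
        budget = _Budget(params.max_residues)
        budget.take()  # the core itself
        core = Glycan("GalNAcol", "?", None)
        gal = Glycan("Gal", "b", "3")
        budget.take()
        core.add_child(gal)
        if rng.random() < params.core2_weight and budget.take():
            arm6 = Glycan("GlcNAc", "b", "6")
            core.add_child(arm6)
            _grow_gal(gal, params, rng, budget)
            _grow_glcnac(arm6, params, rng, budget)
        else:
            _grow_gal(gal, params, rng, budget)
        glycome.append(core)
    return glycome


# ---------------------------------------------------------------------------
# Release + spectra
# ---------------------------------------------------------------------------

@dataclass
class ProductTruth:
    index: int
    parent_index: int
    structure: Glycan
    derivative_tag: str
    origin_position: Optional[str]  # core position for scission products
    composition: Composition
    neutral: float
    theoretical_mz: float


@dataclass
class SimulatedSpectra:
    products: list
    ms1: PeakList
    ms2: dict  # product index -> PeakList
    truth: pd.DataFrame
    species: IonSpecies


def _reduced_to_reducing(core: Glycan) -> Glycan:
    out = core.copy()
    if out.symbol != "GalNAcol":
        raise ValueError("expected a GalNAcol-rooted alditol")
    reducing = Glycan("GalNAc", out.anomer, None, out.children)
    return reducing


def simulate_release_and_spectra(glycome: Sequence[Glycan],
                                 mode: str = "reductive",
                                 noise: SpectrumNoise = SpectrumNoise(),
                                 species: IonSpecies = DEPROTONATED,
                                 peeling_prob: float = 0.0) -> SimulatedSpectra:
    """Simulated NGL products with MS1 survey and per-precursor MS/MS lists.

    ``mode='reductive'`` routes each alditol through periodate scission
    (OX/OY-tagged arms); ``mode='hydrazinolysis'`` emits the intact glycan
    with a reducing GalNAc core conjugated to the fluorescent tag, with an
    optional peeling artifact (core loss) at ``peeling_prob``.
    """
    if mode not in ("reductive", "hydrazinolysis"):
        raise ValueError("mode must be 'reductive' or 'hydrazinolysis'")
    rng = np.random.default_rng(noise.seed)
    products: list[ProductTruth] = []
    for pi, core in enumerate(glycome):
        if mode == "reductive":
            for sp in periodate_scission(core):
                comp = sp.branch.composition()
                neutral = neutral_mass(comp, sp.derivative)
                products.append(ProductTruth(
                    len(products), pi, sp.branch, sp.derivative.tag,
                    sp.origin_position, comp, neutral,
                    ion_mz(neutral, species)))
        else:
            tree = _reduced_to_reducing(core)
            variants = [tree]
            if peeling_prob and rng.random() < peeling_prob and len(tree.children) == 1:
                variants.append(tree.children[0].copy(linkage=None))
            for tree in variants:
                comp = tree.composition()
                neutral = neutral_mass(comp, "ADHP_reducing")
                products.append(ProductTruth(
                    len(products), pi, tree, "ADHP_reducing", None, comp,
                    neutral, ion_mz(neutral, species)))

    ms1_rows = []
    ms2 = {}
    for prod in products:
        mz = (prod.theoretical_mz + noise.calibration_offset
              + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0))
        inten = float(np.exp(rng.normal(np.log(100.0), noise.intensity_log_sd))) \
            if noise.intensity_log_sd else 100.0
        dropped = noise.dropout_prob and rng.random() < noise.dropout_prob
        if not dropped:
            ms1_rows.append((mz, inten))
        ladder = theoretical_Y_ions(prod.structure, prod.derivative_tag, species)
        frag_rows = []
        for ion in ladder.ions:
            if noise.dropout_prob and ion.loss.total() != 0 \
                    and rng.random() < noise.dropout_prob:
                continue
            fmz = (ion.mz + noise.calibration_offset
                   + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0))
            finten = float(np.exp(rng.normal(np.log(50.0), noise.intensity_log_sd))) \
                if noise.intensity_log_sd else 50.0
            frag_rows.append((fmz, finten))
        ms2[prod.index] = PeakList.from_pairs(
            frag_rows, polarity=species.polarity, level="MS2",
            precursor_mz=prod.theoretical_mz)

    ms1 = PeakList.from_pairs(ms1_rows, polarity=species.polarity, level="MS1")
    truth = pd.DataFrame([
        {"index": p.index, "parent_index": p.parent_index,
         "structure": p.structure.to_condensed(),
         "derivative": p.derivative_tag, "origin": p.origin_position,
         "composition": p.composition.to_string(),
         "neutral": p.neutral, "theoretical_mz": p.theoretical_mz}
        for p in products])
    return SimulatedSpectra(products, ms1, ms2, truth, species)


# ---------------------------------------------------------------------------
# Array simulation
# ---------------------------------------------------------------------------

def simulate_array(probes: Sequence[tuple],
                   model: BindingModel,
                   temperatures: Iterable[float] = (20,),
                   replicates: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binding and isotype-control tables for (probe_id, Glycan-or-None)
    probes.  Structure-less probes (glycoproteins) are treated as
    motif-negative.  Returns wide frames with ``rep1..repN`` columns."""
    rng = np.random.default_rng(model.seed)
    rows, ctrl_rows = [], []
    for temp in temperatures:
        try:
            scale = model.temp_scale[temp]
        except KeyError:
            raise ValueError(f"no temperature scale for {temp} degC") from None
        for pid, glycan in probes:
            is_pos = glycan is not None and contains_motif(glycan, model.motif)[0]
            mu = (model.mu_pos if is_pos else model.mu_neg) * scale
            reps = np.exp(rng.normal(np.log(mu), model.log_sd, size=replicates))
            crtl = np.exp(rng.normal(np.log(model.control_mu), model.log_sd,
                                     size=replicates))
            rows.append({"probe_id": pid, "temperature": temp,
                         **{f"rep{i+1}": float(v) for i, v in enumerate(reps)}})
            ctrl_rows.append({"probe_id": pid, "temperature": temp,
                              **{f"rep{i+1}": float(v) for i, v in enumerate(crtl)}})
    return pd.DataFrame(rows), pd.DataFrame(ctrl_rows)
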
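"""End-to-end elucidation workflow and its run configuration.

Chains the pipeline stages — precursor composition inference, MS/MS
topology sequencing with branch detection, exoglycosidase shift
verification, and array hit calling with discriminating-motif inference —
into one structured, JSON-serializable report.  The report of a chained
run equals the composition of individually invoked stages; there is no
hidden state beyond the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .arrays import call_hits, infer_discriminating_motif, summarize
from .compositions import AssignmentSettings, assign_peaks
from .enzymes import verify_shift
from .glycan import parse_condensed
from .masses import DEPROTONATED, PROTONATED, IonSpecies
from .peaklist import PeakList
from .sequencing import (TopologyGrammar, DEFAULT_GRAMMAR, detect_branch,
                         generate_candidates, match_and_rank,
                         theoretical_Y_ions)

__all__ = ["RunConfig", "run_elucidate", "StageError"]

_SPECIES = {"deprotonated": DEPROTONATED, "protonated": PROTONATED}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved settings of one elucidation run; JSON round-trippable."""

    ms1_path: Optional[str] = None
    ms2_paths: dict = field(default_factory=dict)   # precursor label -> path
    digestions: list = field(default_factory=list)  # [pre_mz, post_mz, enzyme, species]
    binding_path: Optional[str] = None
    control_path: Optional[str] = None
    probes_path: Optional[str] = None
    tolerance: float = 0.5
    derivatives: list = field(default_factory=lambda: ["ADHP_OX", "ADHP_OY"])
    species: str = "deprotonated"
    grammar: dict = field(default_factory=lambda: DEFAULT_GRAMMAR.to_dict())
    f_max: float = 0.1
    k: float = 5.0
    motif_max_size: int = 6
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def ion_species(self) -> IonSpecies:
        return _SPECIES[self.species]

    def topology_grammar(self) -> TopologyGrammar:
        return TopologyGrammar.from_dict(self.grammar)


def read_probe_library(path) -> list[tuple]:
    """Probe TSV: probe_id <tab> condensed structure ('-' for probes with
    no defined glycan, e.g. glycoproteins)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    probes = []
    for _, row in df.iterrows():
        s = str(row["structure"]).strip()
        probes.append((str(row["probe_id"]),
                       None if s in ("-", "", "nan") else parse_condensed(s)))
    return probes


def _stage_compositions(config: RunConfig) -> list[dict]:
    peaks = PeakList.from_tsv(config.ms1_path)
    settings = AssignmentSettings(
        species=config.ion_species(),
        derivatives=tuple(config.derivatives),
        tolerance=config.tolerance)
    out = []
    for a in assign_peaks(peaks, settings):
        out.append({
            "mz": a.mz, "flag": a.flag,
            "candidates": [
                {"composition": c.composition.to_string(),
                 "derivative": c.derivative.tag,
                 "theoretical_mz": round(c.theoretical_mz, 4),
                 "error": round(c.error, 4), "label": c.label()}
                for c in a.candidates],
        })
    return out


def _stage_sequencing(config: RunConfig) -> dict:
    grammar = config.topology_grammar()
    species = config.ion_species()
    settings = AssignmentSettings(
        species=species, derivatives=tuple(config.derivatives),
        tolerance=config.tolerance)
    results = {}
    for label, path in config.ms2_paths.items():
        peaks = PeakList.from_tsv(path)
        precursor = peaks.precursor_mz
        if precursor is None:
            raise ValueError(f"MS2 list {label!r} has no precursor_mz header")
        comp_hits = assign_peaks(
            PeakList.from_pairs([(precursor, 1.0)]), settings)[0]
        entry = {"precursor_mz": precursor,
                 "composition_flag": comp_hits.flag,
                 "branch_evidence": [
                     {"kind": ev.kind, "upper_mz": round(ev.upper_mz, 4),
                      "lower_mz": round(ev.lower_mz, 4),
                      "gap": round(ev.gap, 4)}
                     for ev in detect_branch(peaks, config.tolerance)],
                 "ranked": []}
        for cand_match in comp_hits.candidates[:1]:
            candidates = generate_candidates(cand_match.composition, grammar)
            if not candidates:
                continue
            ranked = match_and_rank(peaks, candidates, cand_match.derivative,
                                    species, config.tolerance)
            top_key = ranked[0][1].sort_key()
            for cand, score in ranked[:10]:
                ladder = theoretical_Y_ions(cand, cand_match.derivative, species)
                entry["ranked"].append({
                    "structure": cand.to_condensed(),
                    "matched_peaks": score.matched_peaks,
                    "unexplained_major_peaks": score.unexplained_major_peaks,
                    "matched_intensity_fraction": round(
                        score.matched_intensity_fraction, 4),
                    "tied_with_top": score.sort_key() == top_key,
                    "ladder_nominal": sorted(ladder.nominal_set()),
                })
        results[label] = entry
    return results


def _stage_digestion(config: RunConfig) -> list[dict]:
    out = []
    for pre_mz, post_mz, enzyme, species_name in config.digestions:
        check = verify_shift(float(pre_mz), float(post_mz), enzyme,
                             _SPECIES[species_name], config.tolerance)
        out.append({"pre_mz": pre_mz, "post_mz": post_mz, "enzyme": enzyme,
                    "consistent": check.consistent,
                    "inferred_removals": check.inferred_removals,
                    "no_digestion": check.no_digestion})
    return out


def _stage_array(config: RunConfig) -> dict:
    binding = pd.read_csv(config.binding_path, sep="\t", comment="#")
    summary = summarize(binding)
    control_summary = None
    if config.control_path:
        control_summary = summarize(
            pd.read_csv(config.control_path, sep="\t", comment="#"))
    hits = call_hits(summary, control_summary, config.f_max, config.k)
    result = {
        "hits": sorted(hits.loc[hits["positive"], "probe_id"].astype(str)),
        "n_probes": int(len(hits)),
        "motifs": [],
    }
    if config.probes_path:
        probes = dict(read_probe_library(config.probes_path))
        pos = [probes[p] for p in hits.loc[hits["positive"], "probe_id"]
               if probes.get(p) is not None]
        neg = [probes[p] for p in hits.loc[~hits["positive"], "probe_id"]
               if probes.get(p) is not None]
        if pos and neg:
            motifs = infer_discriminating_motif(pos, neg,
                                                config.motif_max_size)
            result["motifs"] = [m.to_string() for m in motifs]
    return result


def run_elucidate(config: RunConfig, out_dir=None) -> dict:
    """Run every configured stage; returns the structured report.

    Stage failures are wrapped in :class:`StageError` carrying the stage
    name; previously completed stage results are preserved on the raised
    error as ``partial_report``.
    """
    report = {"tool": "glycoseq", "version": __version__,
              "seed": config.seed, "stages": {}}
    stages = []
    if config.ms1_path:
        stages.append(("compositions", _stage_compositions))
    if config.ms2_paths:
        stages.append(("sequencing", _stage_sequencing))
    if config.digestions:
        stages.append(("digestion", _stage_digestion))
    if config.binding_path:
        stages.append(("array", _stage_array))
    if not stages:
        raise ValueError("config references no inputs; nothing to do")
    for name, fn in stages:
        try:
            report["stages"][name] = fn(config)
        except Exception as exc:
            err = StageError(name, exc)
            err.partial_report = report
            raise err from exc
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_json(out_dir / "resolved_config.json")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
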
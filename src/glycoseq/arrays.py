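"""Glycan-microarray binding analysis and discriminating-motif inference.

Replicate fluorescence intensities are summarized as the duplicate mean
with half the absolute difference as the dispersion (the convention for
duplicate-spot arrays); probes are called positive against a fraction of
the maximal signal and a fold over the isotype control; and the minimal
subtree patterns separating bound from unbound probe structures are mined
by exhaustive fragment enumeration.

Binding tables are pandas DataFrames in wide replicate layout:
``probe_id`` (plus optional condition columns such as ``temperature``)
followed by replicate columns ``rep1``, ``rep2``, ...
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .glycan import (Glycan, MotifPattern, PatternNode, contains_motif)

__all__ = [
    "summarize",
    "call_hits",
    "infer_discriminating_motif",
    "temperature_trend",
]

_REP_PREFIX = "rep"


def _replicate_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if str(c).startswith(_REP_PREFIX)]
    if not cols:
        raise ValueError("binding table has no replicate columns (rep1, rep2, ...)")
    return cols


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row mean and half-difference of replicate intensities.

    With exactly two replicates, dispersion = |a - b| / 2.  Other replicate
    counts fall back to half the range and are flagged in the
    ``dispersion_flagged`` column.
    """
    reps = _replicate_columns(table)
    values = table[reps].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("intensities must be non-negative")
    out = table.drop(columns=reps).copy()
    out["mean"] = values.mean(axis=1)
    out["half_difference"] = (values.max(axis=1) - values.min(axis=1)) / 2.0
    out["n_replicates"] = values.shape[1]
    out["dispersion_flagged"] = values.shape[1] != 2
    return out


@dataclass(frozen=True)
class HitCriterion:
    f_max: float
    k: float
    max_mean: float
    control_used: bool


def call_hits(summary: pd.DataFrame,
              control_summary: Optional[pd.DataFrame] = None,
              f_max: float = 0.1,
              k: float = 5.0) -> pd.DataFrame:
    """Call antigen-positive probes.

    A probe is positive iff its mean is at least ``f_max`` of the maximal
    probe mean AND at least ``k`` times its isotype-control mean.  Both
    terms are scale-invariant when test and control scale together.
    Missing control rows disable the control term with a warning.
    """
    out = summary.copy()
    max_mean = float(out["mean"].max()) if len(out) else 0.0
    threshold = f_max * max_mean
    control_used = control_summary is not None
    if control_used:
        ctrl = control_summary.set_index("probe_id")["mean"]
        missing = set(out["probe_id"]) - set(ctrl.index)
        if missing:
            warnings.warn(
                f"no control rows for probes {sorted(missing)}; control "
                "criterion skipped for them")
        control_means = out["probe_id"].map(ctrl)
    else:
        control_means = pd.Series(np.nan, index=out.index)
    out["control_mean"] = control_means.to_numpy()
    means = out["mean"].to_numpy(dtype=float)
    ctrl_means = out["control_mean"].to_numpy(dtype=float)
    signal_ok = (means >= threshold) if max_mean > 0 else np.zeros(len(out), bool)
    control_ok = np.ones(len(out), dtype=bool)
    has_ctrl = ~np.isnan(ctrl_means)
    control_ok[has_ctrl] = means[has_ctrl] >= k * ctrl_means[has_ctrl]
    out["positive"] = signal_ok & control_ok
    out.attrs["criterion"] = HitCriterion(f_max, k, max_mean, control_used)
    return out


# ---------------------------------------------------------------------------
# Discriminating-motif inference
# ---------------------------------------------------------------------------

def _fragments_rooted(node: Glycan, max_size: int):
    """Connected fragments of the subtree that contain ``node`` as their
    root, as PatternNode copies (open, concrete fields)."""
    child_options = []
    for c in node.children:
        opts = [None] + list(_fragments_rooted(c, max_size - 1))
        child_options.append(opts)
    for combo in itertools.product(*child_options) if child_options else [()]:
        chosen = [c for c in combo if c is not None]
        size = 1 + sum(p.n_nodes() for p in chosen)
        if size > max_size:
            continue
        yield PatternNode(node.symbol, node.anomer, node.linkage, False,
                          [c.copy() for c in chosen])


def _candidate_patterns(tree: Glycan, max_size: int):
    """Fragments of ``tree`` (each with and without a wildcard parent
    capturing the attachment linkage) under all open/closed assignments."""
    seen = set()
    for node in tree.walk():
        for frag in _fragments_rooted(node, max_size):
            variants = [frag]
            if node.linkage is not None:
                anchored = frag.copy()
                wild = PatternNode("*", "?", None, False, [anchored])
                variants.append(wild)
            for var in variants:
                nodes = list(var.walk())
                if len(nodes) > max_size + 1:
                    continue
                for mask in itertools.product((False, True), repeat=len(nodes)):
                    pat = var.copy()
                    for pnode, closed in zip(pat.walk(), mask):
                        pnode.closed = closed
                    key = pat.to_string()
                    if key in seen:
                        continue
                    seen.add(key)
                    root = pat.copy()
                    root.linkage = None
                    yield MotifPattern(root)


def _pattern_subsumes(q: PatternNode, p: PatternNode,
                      check_linkage: bool = False) -> bool:
    """Structural generality: every tree matched by pattern ``p`` is matched
    by ``q`` when ``q`` embeds into ``p`` with weaker constraints."""
    if q.symbol != "*" and q.symbol != p.symbol:
        return False
    if q.anomer != "?" and q.anomer != p.anomer:
        return False
    if check_linkage and q.linkage not in (None, "?") and q.linkage != p.linkage:
        return False
    if q.closed and not p.closed:
        return False
    qc, pc = q.children, p.children
    if len(qc) > len(pc):
        return False
    if q.closed and len(qc) != len(pc):
        return False
    if not qc:
        return True
    for assignment in itertools.permutations(range(len(pc)), len(qc)):
        if all(_pattern_subsumes(qc[i], pc[j], True)
               for i, j in enumerate(assignment)):
            return True
    return False


def pattern_subsumes(general: MotifPattern, specific: MotifPattern) -> bool:
    """Whether every tree matched by ``specific`` is matched by ``general``.

    Since both patterns are floating, the general pattern may anchor on
    any node the specific pattern guarantees to exist, not just its root.
    """
    return any(_pattern_subsumes(general.root, node)
               for node in specific.root.walk())


def infer_discriminating_motif(positives: Iterable[Glycan],
                               negatives: Iterable[Glycan],
                               max_size: int = 6) -> list[MotifPattern]:
    """Minimal connected subtree patterns present in every positive
    structure and absent from every negative one, smallest first.

    Candidates are mined from the smallest positive structure (any shared
    motif must occur in it); each fragment is tried with every open/closed
    flag assignment and optionally below a wildcard parent that carries
    the branch-attachment linkage.  Returns an empty list when no pattern
    separates the sets.
    """
    positives = list(positives)
    negatives = list(negatives)
    if not positives or not negatives:
        raise ValueError("both probe sets must be non-empty")
    seedtree = min(positives, key=lambda t: (t.n_residues(), t.to_condensed()))
    qualifying = []
    for pattern in _candidate_patterns(seedtree, max_size):
        if not all(contains_motif(t, pattern)[0] for t in positives):
            continue
        if any(contains_motif(t, pattern)[0] for t in negatives):
            continue
        qualifying.append(pattern)
    qualifying.sort(key=lambda p: (
        p.n_nodes(), sum(n.closed for n in p.root.walk()), p.to_string()))
    minimal = []
    for p in qualifying:
        if any(q is not p and pattern_subsumes(q, p) for q in qualifying):
            continue
        minimal.append(p)
    return minimal


# ---------------------------------------------------------------------------
# Temperature series
# ---------------------------------------------------------------------------

def temperature_trend(tables: dict) -> pd.DataFrame:
    """Per-probe monotonicity verdict across a temperature series.

    ``tables`` maps temperature (numeric, e.g. 4/20/37) to a summary frame
    (or raw binding table, summarized on the fly).  Verdicts on means:
    ``strictly-decreasing``, ``flat`` (constant; reported as a flagged
    non-monotone case) or ``non-monotone``.
    """
    if len(tables) < 2:
        raise ValueError("need at least two temperature levels")
    temps = sorted(tables)
    frames = {}
    probe_ids = None
    for t in temps:
        df = tables[t]
        if "mean" not in df.columns:
            df = summarize(df)
        frames[t] = df.set_index("probe_id")["mean"]
        ids = set(frames[t].index)
        if probe_ids is None:
            probe_ids = ids
        elif ids != probe_ids:
            raise ValueError("temperature levels cover different probes")
    rows = []
    for pid in sorted(probe_ids):
        means = [float(frames[t][pid]) for t in temps]
        if all(a > b for a, b in zip(means, means[1:])):
            verdict = "strictly-decreasing"
        elif all(a == b for a, b in zip(means, means[1:])):
            verdict = "flat"
        else:
            verdict = "non-monotone"
        rows.append({"probe_id": pid, "verdict": verdict,
                     **{f"mean_{t}": m for t, m in zip(temps, means)}})
    return pd.DataFrame(rows)
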
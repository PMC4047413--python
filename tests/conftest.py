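import numpy as np
import pytest

from glycoseq.glycan import Glycan, parse_condensed
from glycoseq.peaklist import PeakList

#: The published MS/MS fragment set of the antigen-positive hexasaccharide
#: NGL (nominal [M-H]- values; intensities are illustrative).
FIG4E_PEAKS = [(2033, 100.0), (1887, 60.0), (1830, 30.0), (1725, 45.0),
               (1522, 50.0), (1157, 40.0), (954, 20.0)]

FOUR_M_F1 = "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-6)[GlcNAc(b1-3)]Gal(b1-4)GlcNAc"


@pytest.fixture
def fmf1_tree() -> Glycan:
    return parse_condensed(FOUR_M_F1)


@pytest.fixture
def fig4e_peaklist() -> PeakList:
    return PeakList.from_pairs(FIG4E_PEAKS, polarity="negative", level="MS2",
                               precursor_mz=2033.0)


# ---------------------------------------------------------------------------
# Seeded random trees (valid notation, not necessarily grammar-legal)
# ---------------------------------------------------------------------------

_SYMBOLS = ("Fuc", "Gal", "Glc", "GlcNAc", "GalNAc", "NeuAc")
_ANOMERS = ("a", "b", "?")
_POSITIONS = ("2", "3", "4", "6", "?")


def random_tree(rng: np.random.Generator, max_residues: int = 10) -> Glycan:
    root = Glycan(str(rng.choice(_SYMBOLS)), str(rng.choice(_ANOMERS)), None)
    nodes = [root]
    n = int(rng.integers(1, max_residues + 1))
    for _ in range(n - 1):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        if parent.mass_class in ("Hex", "HexNAc") and len(parent.children) >= 2:
            continue
        if parent.mass_class in ("dHex", "NeuAc"):
            continue  # caps stay terminal
        taken = {c.linkage for c in parent.children}
        free = [p for p in _POSITIONS if p == "?" or p not in taken]
        if not free:
            continue
        child = Glycan(str(rng.choice(_SYMBOLS)), str(rng.choice(_ANOMERS)),
                       str(rng.choice(free)))
        parent.add_child(child)
        nodes.append(child)
    return root
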
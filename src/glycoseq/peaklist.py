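"""Peak lists: observed (m/z, intensity) pairs with plain-TSV round-trip.

The TSV dialect is two columns (mz, intensity), tab-separated, with ``#``
comment lines; metadata (polarity, MS level, precursor m/z) is carried in
``# key: value`` header comments so a file is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["PeakList"]


@dataclass
class PeakList:
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    level: str = "MS1"  # 'MS1' | 'MS2'
    precursor_mz: Optional[float] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        if self.level not in ("MS1", "MS2"):
            raise ValueError("level must be MS1 or MS2")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def has_peak_near(self, mz: float, tolerance: float) -> bool:
        return bool(len(self)) and bool(np.any(np.abs(self.mz - mz) <= tolerance))

    @classmethod
    def from_pairs(cls, pairs, **kwargs) -> "PeakList":
        pairs = list(pairs)
        mz = [p[0] for p in pairs]
        inten = [p[1] if len(p) > 1 else 1.0 for p in pairs]
        return cls(np.array(mz, float), np.array(inten, float), **kwargs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# polarity: {self.polarity}\n")
            fh.write(f"# level: {self.level}\n")
            if self.precursor_mz is not None:
                fh.write(f"# precursor_mz: {self.precursor_mz:.4f}\n")
            fh.write("# mz\tintensity\n")
            for mz, inten in zip(self.mz, self.intensity):
                fh.write(f"{mz:.4f}\t{inten:.4f}\n")

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            rows.append((float(parts[0]),
                         float(parts[1]) if len(parts) > 1 else 1.0))
        mz = np.array([r[0] for r in rows], float)
        inten = np.array([r[1] for r in rows], float)
        prec = meta.get("precursor_mz")
        return cls(mz, inten,
                   polarity=meta.get("polarity", "negative"),
                   level=meta.get("level", "MS1"),
                   precursor_mz=float(prec) if prec else None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})
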
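"""Standard 10-20 electrode montages on the unit sphere.

Coordinates are shipped as a packaged CSV (name, x, y, z) derived from the
10-20 placement geometry: electrodes sit on great-circle arcs in steps of
20% of the nasion-inion / ear-to-ear distance (36 degrees on a sphere),
with intermediate sites (F3, P4, FCz, ...) at spherical midpoints of their
neighbours. +x is toward the right ear, +y toward the nasion, +z up.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List

import numpy as np
import pandas as pd

from .types import ConfigurationError

#: the unified 19-channel set, in canonical order (16 shared sites first,
#: then the three midline sites present only in 19-channel recordings)
CHANNELS_19: List[str] = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "FCz", "CPz", "Oz",
]

#: the 16 positions shared by 16- and 19-channel 10-20 recordings
CHANNELS_16: List[str] = CHANNELS_19[:16]

#: sites estimated by interpolation when harmonizing 16 -> 19 channels
EXTRA_19: List[str] = ["FCz", "CPz", "Oz"]

#: legacy 10-20 names mapped to their modern equivalents
CHANNEL_ALIASES: Dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

MONTAGES: Dict[str, List[str]] = {"std19": CHANNELS_19, "std16": CHANNELS_16}


@dataclass(frozen=True)
class MontageSpec:
    """Electrode name -> 3-D unit-sphere coordinate table."""

    positions: tuple  # tuple of (name, np.ndarray) pairs; kept hashable-ish

    def __contains__(self, name: str) -> bool:
        return name in self.as_dict()

    def as_dict(self) -> Dict[str, np.ndarray]:
        return dict(self.positions)

    def coords(self, names) -> np.ndarray:
        table = self.as_dict()
        missing = [n for n in names if n not in table]
        if missing:
            raise ConfigurationError(f"unknown electrode position(s): {missing}")
        return np.stack([table[n] for n in names])


def load_montage_table() -> MontageSpec:
    """Load the packaged 10-20 coordinate table."""
    with resources.files("mdefusion.data").joinpath("montage_1020.csv").open() as fh:
        df = pd.read_csv(fh)
    pos = []
    for _, row in df.iterrows():
        v = np.array([row.x, row.y, row.z], dtype=float)
        n = np.linalg.norm(v)
        if abs(n - 1.0) > 1e-6:
            raise ConfigurationError(f"electrode {row['name']} is not on the unit sphere")
        pos.append((str(row["name"]), v / n))
    return MontageSpec(positions=tuple(pos))


def montage_channels(montage_name: str) -> List[str]:
    try:
        return list(MONTAGES[montage_name])
    except KeyError:
        raise ConfigurationError(
            f"unknown montage {montage_name!r}; available: {sorted(MONTAGES)}"
        ) from None


def canonical_name(name: str) -> str:
    """Canonicalize an EDF channel label to its 10-20 electrode name.

    Strips common prefixes/suffixes (``EEG Fp1-REF`` -> ``Fp1``) and applies
    the legacy aliases T3/T4/T5/T6 -> T7/T8/P7/P8.
    """
    n = name.strip()
    for prefix in ("EEG ", "eeg "):
        if n.startswith(prefix):
            n = n[len(prefix):]
    n = n.split("-")[0].strip().replace(".", "")
    # normalize case: electrode names like FP1 -> Fp1, cz -> Cz, fcz -> FCz
    known = {c.upper(): c for c in CHANNELS_19 + ["Fz", "Cz", "Pz", "Fpz"]}
    known.update({a.upper(): a for a in CHANNEL_ALIASES})
    n = known.get(n.upper(), n)
    return CHANNEL_ALIASES.get(n, n)
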
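"""Isotope-label arithmetic for SILAC experiments.

Heavy lysine and arginine carry stable-isotope substitutions (13C for 12C,
15N for 14N) that shift every tryptic peptide by a fixed monoisotopic mass:
Lys8 by 8.0142 Da and Arg10 by 10.00827 Da. The shift is the sum over
substituted atoms of (heavy isotope mass - light isotope mass), computed
from the NIST monoisotopic mass table shipped with pyteomics.

Incorporation efficiency — the fraction of a cell line's proteome carrying
the heavy label — is estimated per peptide as heavy/(heavy+light) intensity
and summarized by the median across peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "LabelSpec",
    "IncorporationEstimate",
    "LABELS",
    "label_mass_shift",
    "incorporation_efficiency",
]


@dataclass(frozen=True)
class LabelSpec:
    """Isotopic substitutions of one labeled residue.

    ``substitutions`` lists (element symbol, light mass number, heavy mass
    number, atom count) tuples, e.g. ``("C", 12, 13, 6)`` for six 13C atoms.
    """

    residue: str
    substitutions: tuple[tuple[str, int, int, int], ...]

    def __post_init__(self) -> None:
        for element, light, heavy, count in self.substitutions:
            if count < 1 or int(count) != count:
                raise ValueError(f"atom count must be a positive integer, got {count}")
            for mass_number in (light, heavy):
                if element not in _pmass.nist_mass or mass_number not in _pmass.nist_mass[element]:
                    raise KeyError(f"unknown isotope {mass_number}{element}")


#: Standard heavy-label presets: 13C6 15N2 lysine and 13C6 15N4 arginine.
LABELS: dict[str, LabelSpec] = {
    "K8": LabelSpec("K", (("C", 12, 13, 6), ("N", 14, 15, 2))),
    "R10": LabelSpec("R", (("C", 12, 13, 6), ("N", 14, 15, 4))),
}


def label_mass_shift(spec: LabelSpec | str) -> float:
    """Monoisotopic mass difference (Da) introduced by a heavy label.

    Accepts a :class:`LabelSpec` or a registry key (``"K8"``, ``"R10"``).
    """
    if isinstance(spec, str):
        spec = LABELS[spec]
    shift = 0.0
    for element, light, heavy, count in spec.substitutions:
        m_light = _pmass.nist_mass[element][light][0]
        m_heavy = _pmass.nist_mass[element][heavy][0]
        shift += count * (m_heavy - m_light)
    return shift


@dataclass(frozen=True)
class IncorporationEstimate:
    cell_line: str
    fraction: float
    n_peptides: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def incorporation_efficiency(
    heavy: Sequence[float],
    light: Sequence[float],
    cell_line: str = "",
) -> IncorporationEstimate:
    """Median per-peptide heavy/(heavy+light) fraction across peptide pairs.

    Pairs with zero total intensity carry no information and are skipped;
    the median (rather than the mean) keeps single aberrant peptides from
    dominating the estimate. Scale-invariant: rescaling all intensities by
    a common factor leaves the estimate unchanged.
    """
    h = np.asarray(heavy, dtype=float)
    l = np.asarray(light, dtype=float)
    if h.shape != l.shape:
        raise ValueError("heavy and light intensity lists must be paired")
    if np.any(h < 0) or np.any(l < 0):
        raise ValueError("intensities must be non-negative")
    total = h + l
    ok = total > 0
    if not ok.any():
        raise ValueError("all peptide pairs have zero total intensity")
    fractions = h[ok] / total[ok]
    return IncorporationEstimate(
        cell_line=cell_line,
        fraction=float(np.median(fractions)),
        n_peptides=int(ok.sum()),
    )
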
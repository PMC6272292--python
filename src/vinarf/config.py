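"""Shared physical constants and default parameterizations.

Everything here is an external convention (AutoDock Vina's published term
constants and weights, van der Waals radii, atomic masses) rather than a fitted
quantity; all of it is overridable by passing explicit objects to the functions
that consume it.
"""

from __future__ import annotations

from dataclasses import dataclass

#: van der Waals radii (Angstrom) used for surface distances, by element.
#: Elements not listed fall back to VDW_DEFAULT (metals and exotica).
VDW_RADII: dict[str, float] = {
    "C": 1.9,
    "N": 1.8,
    "O": 1.7,
    "S": 2.0,
    "P": 2.1,
    "F": 1.5,
    "Cl": 1.8,
    "Br": 2.0,
    "I": 2.2,
}
VDW_DEFAULT = 1.2

#: Standard atomic weights for the heavy elements the descriptors recognise.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}

#: Protein-side and ligand-side element alphabets of the 36 occurrence-count
#: descriptors (4 x 9 ordered pairs; order is frozen - trained models depend
#: on it).
PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

#: Euclidean distance cutoff (Angstrom) for the element-pair occurrence counts.
RF_COUNT_CUTOFF = 12.0

#: Surface-distance cutoff (Angstrom) for the five Vina interaction terms.
VINA_TERM_CUTOFF = 8.0


@dataclass(frozen=True)
class VinaTermConstants:
    """Shape constants of the five Vina pairwise terms.

    gauss1 = exp(-(d/gauss1_width)^2)
    gauss2 = exp(-((d-gauss2_offset)/gauss2_width)^2)
    repulsion = d^2 for d < 0
    hydrophobic: linear ramp 1 -> 0 over [hydrophobic_good, hydrophobic_bad]
    hbond: linear ramp 1 -> 0 over [hbond_good, hbond_bad]
    """

    gauss1_width: float = 0.5
    gauss2_offset: float = 3.0
    gauss2_width: float = 2.0
    hydrophobic_good: float = 0.5
    hydrophobic_bad: float = 1.5
    hbond_good: float = -0.7
    hbond_bad: float = 0.0


@dataclass(frozen=True)
class VinaWeights:
    """Weights of the Vina composite score (published parameterization).

    The composite intermolecular energy is
        e = sum_k w_k * term_k / (1 + w_nrot * Nrot)   [kcal/mol]
    and predictions are reported as -e / KCAL_PER_PK (pKd scale).
    """

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_nrot: float = 0.05846


#: kcal/mol per pK unit at ~298 K (RT * ln 10).
KCAL_PER_PK = 1.3637

#: Default seed list for 10-seed random-forest ensembles.
DEFAULT_SEEDS: tuple[int, ...] = tuple(range(1, 11))


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Van der Waals radius for ``element`` with the metals/other fallback."""
    tab = VDW_RADII if table is None else table
    return tab.get(element, VDW_DEFAULT)
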
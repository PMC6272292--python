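"""Intermolecular descriptors of a protein-ligand complex.

Two descriptor schemes are computed from heavy-atom geometry alone:

``vina6``
    The five Vina interaction terms summed over all protein-ligand atom pairs
    within an 8 A surface-distance cutoff (two gaussians of the surface
    distance d, a steric repulsion d^2 for d<0, and two linear ramps active
    for hydrophobic-hydrophobic and donor-acceptor pairs), plus the ligand's
    rotatable-bond count Nrot.

``vinaelem42``
    The 6 Vina features followed by the 36 element-pair occurrence counts:
    the number of (protein atom, ligand atom) pairs within 12 A (Euclidean),
    for protein elements {C,N,O,S} x ligand elements {C,N,O,F,P,S,Cl,Br,I}.

The Vina composite score maps the vina6 features to a pKd-scale prediction
with the published weights; NHA/MWT are size-only baselines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import (
    ATOMIC_MASSES,
    KCAL_PER_PK,
    LIGAND_ELEMENTS,
    PROTEIN_ELEMENTS,
    RF_COUNT_CUTOFF,
    VINA_TERM_CUTOFF,
    VinaTermConstants,
    VinaWeights,
)
from .structio import MolecularComplex, TypedAtom

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "FeaturizationError",
    "VINA6_NAMES",
    "COUNT_NAMES",
    "VINAELEM42_NAMES",
    "surface_distance",
    "vina_pair_terms",
    "vina_features",
    "rf_counts",
    "vina_score",
    "baseline_descriptors",
    "featurize_set",
]

VINA6_NAMES: tuple[str, ...] = (
    "gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "nrot",
)
COUNT_NAMES: tuple[str, ...] = tuple(
    f"{p}.{l}" for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS
)
VINAELEM42_NAMES: tuple[str, ...] = VINA6_NAMES + COUNT_NAMES

_SCHEME_NAMES = {"vina6": VINA6_NAMES, "vinaelem42": VINAELEM42_NAMES}


class FeaturizationError(ValueError):
    """Raised when a complex cannot be featurized (e.g. an empty atom list)."""


@dataclass
class FeatureVector:
    """An ordered, named descriptor vector for one complex."""

    scheme: str
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = _SCHEME_NAMES.get(self.scheme)
        if expected is None and self.scheme != "counts36":
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if expected is not None and self.feature_names != expected:
            raise ValueError("feature names do not match scheme")
        if len(self.values) != len(self.feature_names):
            raise ValueError("length mismatch between values and names")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.feature_names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.feature_names.index(name)])


def surface_distance(atom_i: TypedAtom, atom_j: TypedAtom) -> float:
    """Euclidean distance minus both vdW radii; negative means overlap."""
    r = float(np.linalg.norm(atom_i.coords - atom_j.coords))
    return r - atom_i.vdw_radius - atom_j.vdw_radius


def vina_pair_terms(
    d: float,
    hydrophobic_pair: bool = False,
    donor_acceptor_pair: bool = False,
    constants: VinaTermConstants = VinaTermConstants(),
) -> np.ndarray:
    """The five Vina terms for one atom pair at surface distance ``d``.

    Returns ``[gauss1, gauss2, repulsion, hydrophobic, hbond]``; the last two
    are zero unless the pair is eligible.
    """
    c = constants
    gauss1 = math.exp(-((d / c.gauss1_width) ** 2))
    gauss2 = math.exp(-(((d - c.gauss2_offset) / c.gauss2_width) ** 2))
    repulsion = d * d if d < 0 else 0.0
    hydrophobic = 0.0
    if hydrophobic_pair:
        hydrophobic = _ramp(d, c.hydrophobic_good, c.hydrophobic_bad)
    hbond = 0.0
    if donor_acceptor_pair:
        hbond = _ramp(d, c.hbond_good, c.hbond_bad)
    return np.array([gauss1, gauss2, repulsion, hydrophobic, hbond])


def _ramp(d: float, good: float, bad: float) -> float:
    """Linear ramp: 1 at d<=good, 0 at d>=bad."""
    if d <= good:
        return 1.0
    if d >= bad:
        return 0.0
    return (bad - d) / (bad - good)


def _atom_arrays(atoms: list[TypedAtom]):
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    hyd = np.array([a.is_hydrophobic for a in atoms])
    don = np.array([a.is_hbond_donor for a in atoms])
    acc = np.array([a.is_hbond_acceptor for a in atoms])
    elems = np.array([a.element for a in atoms])
    return coords, radii, hyd, don, acc, elems


def vina_features(
    cplx: MolecularComplex,
    cutoff: float = VINA_TERM_CUTOFF,
    constants: VinaTermConstants = VinaTermConstants(),
) -> FeatureVector:
    """The six Vina features: five summed pair terms + Nrot.

    Pairs beyond ``cutoff`` (surface distance, A) contribute nothing.
    """
    if not cplx.protein_atoms or not cplx.ligand_atoms:
        raise FeaturizationError(f"complex {cplx.id!r} has an empty atom list")
    pc, pr, ph, pd_, pa, _ = _atom_arrays(cplx.protein_atoms)
    lc, lr, lh, ld, la, _ = _atom_arrays(cplx.ligand_atoms)

    d = cdist(pc, lc) - pr[:, None] - lr[None, :]
    mask = d <= cutoff

    c = constants
    dm = d[mask]
    gauss1 = np.exp(-((dm / c.gauss1_width) ** 2)).sum()
    gauss2 = np.exp(-(((dm - c.gauss2_offset) / c.gauss2_width) ** 2)).sum()
    repulsion = np.where(dm < 0, dm * dm, 0.0).sum()

    ramp_h = np.clip((c.hydrophobic_bad - dm) / (c.hydrophobic_bad - c.hydrophobic_good), 0.0, 1.0)
    hyd_pair = (ph[:, None] & lh[None, :])[mask]
    hydrophobic = (ramp_h * hyd_pair).sum()

    ramp_b = np.clip((c.hbond_bad - dm) / (c.hbond_bad - c.hbond_good), 0.0, 1.0)
    da_pair = ((pd_[:, None] & la[None, :]) | (pa[:, None] & ld[None, :]))[mask]
    hbond = (ramp_b * da_pair).sum()

    values = np.array(
        [gauss1, gauss2, repulsion, hydrophobic, hbond, float(cplx.n_rotatable_bonds)]
    )
    return FeatureVector("vina6", values, VINA6_NAMES)


def rf_counts(cplx: MolecularComplex, cutoff: float = RF_COUNT_CUTOFF) -> FeatureVector:
    """The 36 protein-ligand element-pair occurrence counts within ``cutoff`` A.

    Plain Euclidean distance; pairs exactly at the cutoff are included.
    Atoms whose element lies outside the two alphabets are ignored.
    """
    if not cplx.protein_atoms or not cplx.ligand_atoms:
        raise FeaturizationError(f"complex {cplx.id!r} has an empty atom list")
    pc, _, _, _, _, pe = _atom_arrays(cplx.protein_atoms)
    lc, _, _, _, _, le = _atom_arrays(cplx.ligand_atoms)

    within = cdist(pc, lc) <= cutoff
    counts = np.zeros((len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS)), dtype=int)
    for i, p_elem in enumerate(PROTEIN_ELEMENTS):
        p_mask = pe == p_elem
        if not p_mask.any():
            continue
        sub = within[p_mask]
        for j, l_elem in enumerate(LIGAND_ELEMENTS):
            l_mask = le == l_elem
            if l_mask.any():
                counts[i, j] = int(sub[:, l_mask].sum())
    return FeatureVector("counts36", counts.ravel().astype(float), COUNT_NAMES)


def vina_score(
    cplx: MolecularComplex,
    weights: VinaWeights = VinaWeights(),
    cutoff: float = VINA_TERM_CUTOFF,
    constants: VinaTermConstants = VinaTermConstants(),
    kcal_per_pk: float = KCAL_PER_PK,
) -> float:
    """Vina composite prediction on the pKd scale.

    e = sum(w_k * term_k) / (1 + w_nrot * Nrot)  [kcal/mol], returned as
    -e / kcal_per_pk so that stronger predicted binding gives a larger pK.
    """
    fv = vina_features(cplx, cutoff=cutoff, constants=constants)
    return vina_score_from_features(fv.values, weights, kcal_per_pk)


def vina_score_from_features(
    values: np.ndarray,
    weights: VinaWeights = VinaWeights(),
    kcal_per_pk: float = KCAL_PER_PK,
) -> float | np.ndarray:
    """Vina prediction from precomputed vina6 feature values (vectorised).

    ``values`` is a length-6 vector or an (n, 6) array ordered as VINA6_NAMES.
    """
    v = np.asarray(values, dtype=float)
    w = np.array(
        [weights.w_gauss1, weights.w_gauss2, weights.w_repulsion,
         weights.w_hydrophobic, weights.w_hbond]
    )
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    e = (v2[:, :5] @ w) / (1.0 + weights.w_nrot * v2[:, 5])
    pred = -e / kcal_per_pk
    return float(pred[0]) if single else pred


def baseline_descriptors(cplx: MolecularComplex) -> tuple[int, float]:
    """(NHA, MWT): ligand heavy-atom count and summed heavy-atom mass.

    MWT omits hydrogens (none are parsed), a documented approximation that
    preserves the ranking a size baseline is meant to capture.
    """
    if not cplx.ligand_atoms:
        raise FeaturizationError(f"complex {cplx.id!r} has no ligand atoms")
    nha = len(cplx.ligand_atoms)
    mwt = float(sum(ATOMIC_MASSES.get(a.element, 0.0) for a in cplx.ligand_atoms))
    return nha, mwt


def featurize(cplx: MolecularComplex, scheme: str = "vinaelem42") -> FeatureVector:
    """One complex -> one named feature vector under ``scheme``."""
    if scheme == "vina6":
        return vina_features(cplx)
    if scheme == "vinaelem42":
        v6 = vina_features(cplx)
        c36 = rf_counts(cplx)
        return FeatureVector(
            "vinaelem42", np.concatenate([v6.values, c36.values]), VINAELEM42_NAMES
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def featurize_set(
    complexes: list[MolecularComplex],
    scheme: str = "vinaelem42",
    out_csv: str | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Featurize many complexes into a table (rows in input order).

    Returns ``(table, rejects)`` where rejects lists ``(complex id, reason)``
    for complexes that failed featurization; failures never silently vanish.
    """
    rows, index, rejects = [], [], []
    for cplx in complexes:
        try:
            rows.append(featurize(cplx, scheme).values)
            index.append(cplx.id)
        except (FeaturizationError, ValueError) as exc:
            logger.warning("featurization failed for %s: %s", cplx.id, exc)
            rejects.append((cplx.id, str(exc)))
    table = pd.DataFrame(
        np.array(rows).reshape(len(rows), -1) if rows else np.empty((0, len(_SCHEME_NAMES[scheme]))),
        columns=list(_SCHEME_NAMES[scheme]),
        index=pd.Index(index, name="id"),
    )
    if out_csv is not None:
        # %.17g guarantees bit-exact float round trips on re-read
        table.to_csv(out_csv, float_format="%.17g")
    return table, rejects
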
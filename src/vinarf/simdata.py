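"""Synthetic protein-ligand complexes, affinity labels and index fixtures.

The generator produces the three kinds of inputs the pipeline consumes, with
the statistical structure the training experiments assume:

* 3-D complexes with realistic element composition and interatomic spacing:
  ligand atoms packed inside a spherical pocket, protein atoms in a shell
  around it, rejection-sampled to a minimum separation, so that pair
  distances populate both the 8 A surface-distance and 12 A count cutoffs;
* p-affinity labels that are linear or nonlinear functions of the descriptors
  with tunable Gaussian noise (nonlinear adds pairwise products and
  thresholded terms of standardised features — structure a linear model
  cannot capture but a forest can);
* quality degradation emulating lower-quality data: coordinate jitter stands
  in for worse crystallographic resolution, and per-record label bias plus
  extra noise stands in for IC50-vs-Kd assay heterogeneity;
* index fixtures with controlled counts of each quality defect.

Every generator is a pure function of its seed and spec.  No attempt is made
at chemically valid molecules; the point is exercising the descriptor,
curation and learning machinery at scale.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .interactions import featurize_set
from .structio import MolecularComplex, TypedAtom

__all__ = [
    "ComplexGenSpec",
    "LabelGenSpec",
    "DegradeSpec",
    "gen_complex",
    "gen_complexes",
    "gen_labels",
    "degrade",
    "gen_index",
    "gen_dataset",
]

#: default element draw frequencies (chosen to populate all 36 count features
#: at moderate sample sizes; arbitrary but fixed)
PROTEIN_FREQS: dict[str, float] = {"C": 0.60, "N": 0.16, "O": 0.22, "S": 0.02}
LIGAND_FREQS: dict[str, float] = {
    "C": 0.70, "N": 0.12, "O": 0.13, "S": 0.02, "F": 0.01,
    "P": 0.005, "Cl": 0.01, "Br": 0.0025, "I": 0.0025,
}


@dataclass
class ComplexGenSpec:
    """Geometry and composition of one synthetic complex."""

    n_protein_atoms: int = 48
    n_ligand_atoms: int = 16
    protein_freqs: dict[str, float] = field(default_factory=lambda: dict(PROTEIN_FREQS))
    ligand_freqs: dict[str, float] = field(default_factory=lambda: dict(LIGAND_FREQS))
    pocket_radius: float = 4.0  # ligand sphere radius, A
    shell_inner: float = 5.0  # protein shell, A from origin
    shell_outer: float = 12.0
    min_separation: float = 1.5
    nrot_max: int = 10
    donor_prob: float = 0.5  # chance an N/O is also a donor
    max_retries: int = 2000

    def __post_init__(self) -> None:
        for freqs in (self.protein_freqs, self.ligand_freqs):
            total = sum(freqs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"element frequencies must sum to 1, got {total}")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.n_protein_atoms < 1 or self.n_ligand_atoms < 1:
            raise ValueError("atom counts must be >= 1")


@dataclass
class LabelGenSpec:
    """Affinity-label mechanism: y = f(features) + Normal(0, noise_sd^2)."""

    mechanism: str = "nonlinear"  # "linear" | "nonlinear"
    intercept: float = 5.0
    coefficients: np.ndarray | None = None  # linear: applied to raw features
    noise_sd: float = 0.5  # pK units

    def __post_init__(self) -> None:
        if self.mechanism not in ("linear", "nonlinear"):
            raise ValueError("mechanism must be 'linear' or 'nonlinear'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DegradeSpec:
    """Quality degradation applied to a fraction of a data set.

    ``jitter_sd`` perturbs every coordinate (worse resolution: annotated
    resolution = jitter_sd / 0.1); ``label_bias_sd`` draws one systematic
    offset per record and ``label_noise_sd`` adds extra noise (IC50-style
    heterogeneity; degraded records are annotated as IC50 measurements).
    """

    jitter_sd: float = 0.3
    label_noise_sd: float = 0.5
    label_bias_sd: float = 0.5
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if min(self.jitter_sd, self.label_noise_sd, self.label_bias_sd) < 0:
            raise ValueError("degradation magnitudes must be >= 0")

    @property
    def implied_resolution(self) -> float:
        return self.jitter_sd / 0.1


def _sample_points(
    rng: np.random.Generator,
    n: int,
    sampler,
    existing: np.ndarray | None,
    min_sep: float,
    max_retries: int,
) -> np.ndarray:
    """Rejection-sample n points at >= min_sep from each other and existing."""
    placed: list[np.ndarray] = []
    anchor = existing if existing is not None else np.empty((0, 3))
    retries = 0
    while len(placed) < n:
        candidate = sampler(rng)
        pool = np.vstack([anchor] + [p[None, :] for p in placed]) if (len(placed) or len(anchor)) else np.empty((0, 3))
        if len(pool) == 0 or np.min(np.linalg.norm(pool - candidate, axis=1)) >= min_sep:
            placed.append(candidate)
        else:
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    "rejection sampling exceeded retry cap; use a larger box "
                    "or fewer atoms"
                )
    return np.array(placed)


def _uniform_ball(radius: float):
    def sampler(rng: np.random.Generator) -> np.ndarray:
        while True:
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) <= radius:
                return p

    return sampler


def _uniform_shell(inner: float, outer: float):
    def sampler(rng: np.random.Generator) -> np.ndarray:
        # uniform in volume between the two radii
        u = rng.random()
        r = (inner**3 + u * (outer**3 - inner**3)) ** (1.0 / 3.0)
        v = rng.normal(size=3)
        return r * v / np.linalg.norm(v)

    return sampler


def _draw_elements(rng: np.random.Generator, n: int, freqs: dict[str, float]) -> list[str]:
    symbols = list(freqs)
    probs = np.array([freqs[s] for s in symbols])
    return [symbols[i] for i in rng.choice(len(symbols), size=n, p=probs / probs.sum())]


def _make_atoms(
    rng: np.random.Generator,
    elements: list[str],
    coords: np.ndarray,
    role: str,
    donor_prob: float,
) -> list[TypedAtom]:
    """Typed atoms with geometry-consistent hydrophobic flags.

    A carbon is hydrophobic when no N/O/S of the same molecule sits within
    bonding range (the connectivity-free rule); N/O are acceptors and, with
    probability ``donor_prob``, donors.
    """
    from scipy.spatial.distance import cdist

    elem_arr = np.array(elements)
    hetero = np.isin(elem_arr, ("N", "O", "S"))
    if hetero.any():
        near_het = (cdist(coords, coords[hetero]) <= 1.9).any(axis=1)
    else:
        near_het = np.zeros(len(elements), dtype=bool)
    atoms = []
    for i, element in enumerate(elements):
        is_no = element in ("N", "O")
        atoms.append(
            TypedAtom(
                element=element,
                coords=coords[i],
                role=role,
                is_hydrophobic=(element == "C" and not near_het[i]),
                is_hbond_donor=bool(is_no and rng.random() < donor_prob),
                is_hbond_acceptor=is_no,
            )
        )
    return atoms


def gen_complex(spec: ComplexGenSpec, seed: int, complex_id: str | None = None) -> MolecularComplex:
    """One synthetic complex; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    lig_coords = _sample_points(
        rng, spec.n_ligand_atoms, _uniform_ball(spec.pocket_radius),
        None, spec.min_separation, spec.max_retries,
    )
    prot_coords = _sample_points(
        rng, spec.n_protein_atoms, _uniform_shell(spec.shell_inner, spec.shell_outer),
        lig_coords, spec.min_separation, spec.max_retries,
    )
    lig_elements = _draw_elements(rng, spec.n_ligand_atoms, spec.ligand_freqs)
    prot_elements = _draw_elements(rng, spec.n_protein_atoms, spec.protein_freqs)
    return MolecularComplex(
        id=complex_id or f"syn{seed:06d}",
        protein_atoms=_make_atoms(rng, prot_elements, prot_coords, "protein", spec.donor_prob),
        ligand_atoms=_make_atoms(rng, lig_elements, lig_coords, "ligand", spec.donor_prob),
        n_rotatable_bonds=int(rng.integers(0, spec.nrot_max + 1)),
    )


def gen_complexes(n: int, spec: ComplexGenSpec, seed: int) -> list[MolecularComplex]:
    """n independent complexes; per-complex seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    return [
        gen_complex(spec, child_seeds[i], complex_id=f"syn{seed:04d}_{i:05d}")
        for i in range(n)
    ]


# -- labels -----------------------------------------------------------------

#: default raw-feature coefficients for the linear mechanism on vina6 (scaled
#: so y lands roughly on the 2-12 pK range for default geometry)
_LINEAR_BETA_VINA6 = np.array([0.05, -0.02, 0.002, 0.15, 0.4, -0.1])


def _nonlinear_response(Z: np.ndarray) -> np.ndarray:
    """Fixed nonlinear recipe on standardised features (first 6 columns used).

    Interactions and thresholded terms keep the response outside any linear
    span of the features.
    """
    z = Z[:, :6]
    return (
        1.0 * z[:, 0]
        - 0.8 * z[:, 2]
        + 0.9 * z[:, 0] * z[:, 1]
        - 0.7 * z[:, 3] * z[:, 4]
        + 1.2 * np.maximum(z[:, 1], 0.0)
        + 0.8 * np.where(z[:, 4] > 0.5, z[:, 2], -z[:, 2])
    )


def gen_labels(
    features: pd.DataFrame,
    spec: LabelGenSpec,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Labels for a feature table; returns (y, generating parameters)."""
    rng = np.random.default_rng(seed)
    X = features.to_numpy(dtype=float)
    if spec.mechanism == "linear":
        beta = (
            np.asarray(spec.coefficients, dtype=float)
            if spec.coefficients is not None
            else _LINEAR_BETA_VINA6[: X.shape[1]].copy()
        )
        if len(beta) != X.shape[1]:
            raise ValueError("coefficient length must match feature count")
        signal = spec.intercept + X @ beta
        params = {"mechanism": "linear", "intercept": spec.intercept, "beta": beta}
    else:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        signal = spec.intercept + _nonlinear_response(Z)
        params = {"mechanism": "nonlinear", "intercept": spec.intercept, "mu": mu, "sd": sd}
    noise = rng.normal(0.0, spec.noise_sd, size=len(signal)) if spec.noise_sd > 0 else 0.0
    params["noise_sd"] = spec.noise_sd
    return signal + noise, params


# -- degradation ------------------------------------------------------------


def degrade(
    complexes: list[MolecularComplex],
    labels: np.ndarray,
    spec: DegradeSpec,
    seed: int,
) -> tuple[list[MolecularComplex], np.ndarray, pd.DataFrame]:
    """Degraded copies of a data set plus per-record quality annotations.

    A ``fraction`` of records (chosen by the rng) get coordinate jitter and
    label bias + noise; the returned annotation table carries the implied
    resolution and measurement kind so curation places each record in the
    right quality tier.  Inputs are never mutated.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=float)
    n = len(complexes)
    if len(labels) != n:
        raise ValueError("labels length must match complexes")
    chosen = rng.random(n) < spec.fraction

    out_complexes: list[MolecularComplex] = []
    out_labels = labels.copy()
    ann_rows = []
    for i, cplx in enumerate(complexes):
        if chosen[i] and (spec.jitter_sd > 0 or spec.label_noise_sd > 0 or spec.label_bias_sd > 0):
            new_prot = [
                replace_atom(a, a.coords + rng.normal(0, spec.jitter_sd, 3))
                for a in cplx.protein_atoms
            ] if spec.jitter_sd > 0 else [replace_atom(a, a.coords) for a in cplx.protein_atoms]
            new_lig = [
                replace_atom(a, a.coords + rng.normal(0, spec.jitter_sd, 3))
                for a in cplx.ligand_atoms
            ] if spec.jitter_sd > 0 else [replace_atom(a, a.coords) for a in cplx.ligand_atoms]
            out_complexes.append(
                MolecularComplex(
                    id=cplx.id,
                    protein_atoms=new_prot,
                    ligand_atoms=new_lig,
                    n_rotatable_bonds=cplx.n_rotatable_bonds,
                )
            )
            bias = rng.normal(0, spec.label_bias_sd) if spec.label_bias_sd > 0 else 0.0
            noise = rng.normal(0, spec.label_noise_sd) if spec.label_noise_sd > 0 else 0.0
            out_labels[i] = labels[i] + bias + noise
            ann_rows.append(
                {
                    "id": cplx.id,
                    "degraded": True,
                    "resolution": spec.implied_resolution if spec.jitter_sd > 0 else 2.0,
                    "measure_kind": "IC50",
                }
            )
        else:
            out_complexes.append(cplx)
            ann_rows.append(
                {"id": cplx.id, "degraded": False, "resolution": 2.0, "measure_kind": "Kd"}
            )
    return out_complexes, out_labels, pd.DataFrame(ann_rows).set_index("id")


def replace_atom(atom: TypedAtom, coords: np.ndarray) -> TypedAtom:
    return TypedAtom(
        element=atom.element,
        coords=np.asarray(coords, dtype=float),
        role=atom.role,
        pdbqt_type=atom.pdbqt_type,
        is_hydrophobic=atom.is_hydrophobic,
        is_hbond_donor=atom.is_hbond_donor,
        is_hbond_acceptor=atom.is_hbond_acceptor,
        vdw_radius=atom.vdw_radius,
    )


# -- index fixtures ----------------------------------------------------------

_CODE_ALPHABET = string.digits + string.ascii_lowercase


def _pdb_code(i: int) -> str:
    """Deterministic 4-char pseudo PDB code: digit + three base-36 chars."""
    tail = []
    x = i
    for _ in range(3):
        tail.append(_CODE_ALPHABET[x % 36])
        x //= 36
    return f"{(i % 9) + 1}{''.join(reversed(tail))}"


#: defect class -> how it is realised on the emitted record
_DEFECT_REALISATION = {
    "clean": {},
    "non_protein_ligand": {"flags": {"non_protein_ligand"}},
    "conversion_failed": {"flags": {"conversion_failed"}},
    "approximate": {"exact": False},
    "nmr": {"nmr": True},
    "covalent": {"flags": {"covalent"}},
    "uncommon_element": {"flags": {"uncommon_element"}},
    "peptide_ge10": {"flags": {"peptide_ge10"}},
    "nucleotide_ge4": {"flags": {"nucleotide_ge4"}},
    "incomplete": {"flags": {"incomplete"}},
    "multi_ligand": {"flags": {"multi_ligand"}},
}

_QUALIFIERS_APPROX = ("~", "<", ">", "<=", ">=")
_UNITS = ("pM", "nM", "uM", "mM")


def gen_index(
    composition: dict[str, int],
    seed: int,
) -> tuple[str, dict[str, list[str]]]:
    """Synthetic index text with exact per-defect-class counts.

    ``composition`` maps class names (``clean`` plus any key of the defect
    realisation table) to record counts.  Classes are disjoint by
    construction; record order is a deterministic shuffle.  Returns the index
    text and the bookkeeping map class -> emitted codes (the oracle for
    filter-accounting tests).
    """
    unknown = set(composition) - set(_DEFECT_REALISATION)
    if unknown:
        raise ValueError(f"unknown composition classes: {sorted(unknown)}")
    if any(v < 0 for v in composition.values()):
        raise ValueError("composition counts must be >= 0")

    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str]] = []  # (class, line)
    bookkeeping: dict[str, list[str]] = {cls: [] for cls in composition}
    counter = itertools.count()
    for cls, count in composition.items():
        real = _DEFECT_REALISATION[cls]
        for _ in range(count):
            code = _pdb_code(next(counter))
            bookkeeping[cls].append(code)
            nmr = real.get("nmr", False)
            res_tok = "NMR" if nmr else f"{rng.uniform(1.2, 4.2):.2f}"
            year = int(rng.integers(1995, 2013))
            paff = rng.uniform(2.0, 11.0)
            kind = rng.choice(("Kd", "Ki", "IC50"), p=(0.35, 0.3, 0.35))
            qualifier = "=" if real.get("exact", True) else str(rng.choice(_QUALIFIERS_APPROX))
            value = f"{rng.uniform(0.1, 900):.1f}"
            unit = str(rng.choice(_UNITS))
            flags = real.get("flags", set())
            flag_tok = f"  flags={','.join(sorted(flags))}" if flags else ""
            line = f"{code}  {res_tok}  {year}  {paff:.2f}  {kind}{qualifier}{value}{unit}{flag_tok}"
            entries.append((cls, line))
    rng.shuffle(entries)
    header = "# code  resolution  year  -logKd/Ki  affinity  [flags=...]\n"
    text = header + "\n".join(line for _, line in entries) + "\n"
    return text, bookkeeping


# -- convenience pipeline ----------------------------------------------------


def gen_dataset(
    n: int,
    seed: int,
    scheme: str = "vina6",
    complex_spec: ComplexGenSpec | None = None,
    label_spec: LabelGenSpec | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[MolecularComplex], dict]:
    """Complexes -> features -> labels in one call.

    Returns (feature table, labels, complexes, label-generating parameters).
    """
    complex_spec = complex_spec or ComplexGenSpec()
    label_spec = label_spec or LabelGenSpec()
    complexes = gen_complexes(n, complex_spec, seed)
    table, rejects = featurize_set(complexes, scheme=scheme)
    if rejects:
        raise RuntimeError(f"synthetic featurization rejected {len(rejects)} complexes")
    y, params = gen_labels(table, label_spec, seed + 1)
    return table, y, complexes, params
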
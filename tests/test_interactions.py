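"""Descriptor tests: closed forms, brute-force oracles and geometric invariances."""

import math

import numpy as np
import pytest

from conftest import random_rotation
from vinarf.config import LIGAND_ELEMENTS, PROTEIN_ELEMENTS, VinaWeights, vdw_radius
from vinarf.interactions import (
    COUNT_NAMES,
    VINA6_NAMES,
    FeaturizationError,
    baseline_descriptors,
    featurize,
    featurize_set,
    rf_counts,
    surface_distance,
    vina_features,
    vina_pair_terms,
    vina_score,
)
from vinarf.simdata import ComplexGenSpec, gen_complex, replace_atom
from vinarf.structio import MolecularComplex, TypedAtom


def atom(element, xyz, role="ligand", **flags):
    return TypedAtom(element=element, coords=np.array(xyz, float), role=role, **flags)


# -- independent brute-force oracles (plain loops, formulas inlined) ---------

def brute_counts(cplx, cutoff=12.0):
    counts = {(p, l): 0 for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS}
    for pa in cplx.protein_atoms:
        for la in cplx.ligand_atoms:
            key = (pa.element, la.element)
            if key in counts and math.dist(pa.coords, la.coords) <= cutoff:
                counts[key] += 1
    return np.array([counts[(p, l)] for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS], float)


def brute_vina(cplx, cutoff=8.0):
    sums = np.zeros(5)
    for pa in cplx.protein_atoms:
        for la in cplx.ligand_atoms:
            d = math.dist(pa.coords, la.coords) - pa.vdw_radius - la.vdw_radius
            if d > cutoff:
                continue
            sums[0] += math.exp(-((d / 0.5) ** 2))
            sums[1] += math.exp(-(((d - 3.0) / 2.0) ** 2))
            if d < 0:
                sums[2] += d * d
            if pa.is_hydrophobic and la.is_hydrophobic:
                sums[3] += min(1.0, max(0.0, (1.5 - d) / 1.0))
            if (pa.is_hbond_donor and la.is_hbond_acceptor) or (
                pa.is_hbond_acceptor and la.is_hbond_donor
            ):
                sums[4] += min(1.0, max(0.0, (0.0 - d) / 0.7))
    return np.append(sums, cplx.n_rotatable_bonds)


class TestSurfaceDistance:
    def test_two_carbons_touching(self):
        a = atom("C", [0, 0, 0])
        b = atom("C", [3.8, 0, 0])
        assert surface_distance(a, b) == pytest.approx(0.0)

    def test_coincident_atoms(self):
        a = atom("C", [1, 1, 1])
        b = atom("O", [1, 1, 1])
        assert surface_distance(a, b) == pytest.approx(-(1.9 + 1.7))

    def test_matches_recomputation_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e1, e2 = rng.choice(list("CNOS"), 2)
            p1, p2 = rng.normal(size=(2, 3)) * 5
            a, b = atom(e1, p1), atom(e2, p2)
            expected = math.dist(p1, p2) - vdw_radius(e1) - vdw_radius(e2)
            assert surface_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestVinaPairTerms:
    def test_closed_form_values(self):
        assert vina_pair_terms(0.0)[0] == pytest.approx(1.0)  # gauss1
        assert vina_pair_terms(3.0)[1] == pytest.approx(1.0)  # gauss2
        assert vina_pair_terms(-1.0)[2] == pytest.approx(1.0)  # repulsion
        assert vina_pair_terms(1.0, hydrophobic_pair=True)[3] == pytest.approx(0.5)
        assert vina_pair_terms(-0.35, donor_acceptor_pair=True)[4] == pytest.approx(0.5)

    def test_ineligible_pairs_get_zero_ramps(self):
        t = vina_pair_terms(1.0, hydrophobic_pair=False, donor_acceptor_pair=False)
        assert t[3] == 0.0 and t[4] == 0.0

    def test_term_ranges(self):
        for d in np.linspace(-3, 8, 60):
            g1, g2, rep, hyd, hb = vina_pair_terms(
                d, hydrophobic_pair=True, donor_acceptor_pair=True
            )
            assert 0 < g1 <= 1 and 0 < g2 <= 1
            assert rep >= 0 and 0 <= hyd <= 1 and 0 <= hb <= 1


class TestVinaFeatures:
    def test_out_of_range_pair_gives_zero_terms(self):
        cplx = MolecularComplex(
            id="far",
            protein_atoms=[atom("C", [0, 0, 0], "protein")],
            ligand_atoms=[atom("C", [50, 0, 0])],
            n_rotatable_bonds=4,
        )
        fv = vina_features(cplx)
        np.testing.assert_array_equal(fv.values[:5], 0.0)
        assert fv["nrot"] == 4

    def test_single_pair_equals_pair_terms(self):
        p = atom("C", [0, 0, 0], "protein", is_hydrophobic=True)
        l = atom("C", [4.2, 0, 0], is_hydrophobic=True)
        cplx = MolecularComplex(id="one", protein_atoms=[p], ligand_atoms=[l])
        d = surface_distance(p, l)
        expected = vina_pair_terms(d, hydrophobic_pair=True)
        np.testing.assert_allclose(vina_features(cplx).values[:5], expected, atol=1e-12)

    def test_empty_atom_list_raises(self, small_complex):
        bad = MolecularComplex(id="e", protein_atoms=small_complex.protein_atoms,
                               ligand_atoms=[])
        with pytest.raises(FeaturizationError):
            vina_features(bad)

    def test_matches_brute_force_on_random_complex(self):
        cplx = gen_complex(ComplexGenSpec(n_protein_atoms=45, n_ligand_atoms=15), seed=9)
        np.testing.assert_allclose(
            vina_features(cplx).values, brute_vina(cplx), atol=1e-10
        )


class TestRfCounts:
    def test_single_pair_in_range(self):
        cplx = MolecularComplex(
            id="cn",
            protein_atoms=[atom("C", [0, 0, 0], "protein")],
            ligand_atoms=[atom("N", [0, 0, 4])],
        )
        fv = rf_counts(cplx)
        assert fv["C.N"] == 1
        assert fv.values.sum() == 1

    def test_unlisted_elements_ignored(self):
        cplx = MolecularComplex(
            id="zn",
            protein_atoms=[atom("Zn", [0, 0, 0], "protein")],
            ligand_atoms=[atom("C", [0, 0, 4])],
        )
        assert rf_counts(cplx).values.sum() == 0

    def test_matches_brute_force_exactly(self):
        cplx = gen_complex(ComplexGenSpec(n_protein_atoms=150, n_ligand_atoms=50), seed=3)
        np.testing.assert_array_equal(rf_counts(cplx).values, brute_counts(cplx))

    def test_cutoff_monotonicity(self, small_complex):
        prev = rf_counts(small_complex, cutoff=4.0).values
        for cutoff in (6.0, 8.0, 12.0, 20.0):
            cur = rf_counts(small_complex, cutoff=cutoff).values
            assert np.all(cur >= prev)
            prev = cur


class TestVinaScore:
    def test_zero_terms_give_zero_prediction(self):
        cplx = MolecularComplex(
            id="far",
            protein_atoms=[atom("C", [0, 0, 0], "protein")],
            ligand_atoms=[atom("C", [90, 0, 0])],
        )
        assert vina_score(cplx) == pytest.approx(0.0)

    def test_single_pair_hand_computation(self):
        p = atom("C", [0, 0, 0], "protein")
        l = atom("C", [4.2, 0, 0])
        cplx = MolecularComplex(id="one", protein_atoms=[p], ligand_atoms=[l])
        d = 4.2 - 1.9 - 1.9
        w = VinaWeights()
        e = (
            w.w_gauss1 * math.exp(-((d / 0.5) ** 2))
            + w.w_gauss2 * math.exp(-(((d - 3.0) / 2.0) ** 2))
        )  # no repulsion (d>0), no ramps (flags off)
        assert vina_score(cplx) == pytest.approx(-e / 1.3637, abs=1e-12)

    def test_linearity_in_weights(self, small_complex):
        w1 = VinaWeights()
        w2 = VinaWeights(
            w_gauss1=2 * w1.w_gauss1, w_gauss2=2 * w1.w_gauss2,
            w_repulsion=2 * w1.w_repulsion, w_hydrophobic=2 * w1.w_hydrophobic,
            w_hbond=2 * w1.w_hbond, w_nrot=w1.w_nrot,
        )
        assert vina_score(small_complex, w2) == pytest.approx(
            2 * vina_score(small_complex, w1), rel=1e-12
        )


class TestBaselines:
    def test_nha_is_ligand_heavy_atom_count(self, small_complex):
        nha, _ = baseline_descriptors(small_complex)
        assert nha == len(small_complex.ligand_atoms)

    def test_single_carbon_mwt(self):
        cplx = MolecularComplex(
            id="c1",
            protein_atoms=[atom("C", [0, 0, 0], "protein")],
            ligand_atoms=[atom("C", [4, 0, 0])],
        )
        assert baseline_descriptors(cplx) == (1, pytest.approx(12.011))


class TestFeaturizeSet:
    def test_shapes_and_scheme_consistency(self, small_complex):
        complexes = [
            gen_complex(ComplexGenSpec(n_protein_atoms=20, n_ligand_atoms=8), seed=s)
            for s in range(3)
        ]
        t6, rej6 = featurize_set(complexes, "vina6")
        t42, rej42 = featurize_set(complexes, "vinaelem42")
        assert t6.shape == (3, 6) and t42.shape == (3, 42)
        assert not rej6 and not rej42
        np.testing.assert_array_equal(t42.iloc[:, :6].to_numpy(), t6.to_numpy())

    def test_csv_round_trip_is_exact(self, tmp_path, small_complex):
        import pandas as pd

        table, _ = featurize_set([small_complex], "vinaelem42",
                                 out_csv=str(tmp_path / "f.csv"))
        back = pd.read_csv(tmp_path / "f.csv", index_col=0, float_precision="round_trip")
        np.testing.assert_array_equal(back.to_numpy(), table.to_numpy())

    def test_failures_reported_not_dropped_silently(self, small_complex):
        bad = MolecularComplex(id="empty", protein_atoms=small_complex.protein_atoms,
                               ligand_atoms=[])
        table, rejects = featurize_set([small_complex, bad], "vina6")
        assert len(table) == 1
        assert rejects and rejects[0][0] == "empty"


class TestGeometricInvariance:
    def test_rigid_motion_leaves_all_42_features_unchanged(self, small_complex):
        base = featurize(small_complex, "vinaelem42").values
        rng = np.random.default_rng(5)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(size=3) * 10
            moved = MolecularComplex(
                id=small_complex.id,
                protein_atoms=[replace_atom(a, R @ a.coords + t)
                               for a in small_complex.protein_atoms],
                ligand_atoms=[replace_atom(a, R @ a.coords + t)
                              for a in small_complex.ligand_atoms],
                n_rotatable_bonds=small_complex.n_rotatable_bonds,
            )
            got = featurize(moved, "vinaelem42").values
            np.testing.assert_array_equal(got[6:], base[6:])  # counts exact
            np.testing.assert_allclose(got[:6], base[:6], atol=1e-9)

    def test_role_swap_symmetry(self):
        """Swapping roles transposes the count grid and preserves gauss sums."""
        spec = ComplexGenSpec(
            n_protein_atoms=20, n_ligand_atoms=20,
            ligand_freqs={"C": 0.6, "N": 0.18, "O": 0.2, "S": 0.02},
        )
        cplx = gen_complex(spec, seed=17)

        def with_role(a, role):
            return TypedAtom(
                element=a.element, coords=a.coords.copy(), role=role,
                pdbqt_type=a.pdbqt_type, is_hydrophobic=a.is_hydrophobic,
                is_hbond_donor=a.is_hbond_donor,
                is_hbond_acceptor=a.is_hbond_acceptor, vdw_radius=a.vdw_radius,
            )

        swapped = MolecularComplex(
            id="swap",
            protein_atoms=[with_role(a, "protein") for a in cplx.ligand_atoms],
            ligand_atoms=[with_role(a, "ligand") for a in cplx.protein_atoms],
            n_rotatable_bonds=cplx.n_rotatable_bonds,
        )
        fwd, rev = vina_features(cplx).values, vina_features(swapped).values
        np.testing.assert_allclose(fwd[:3], rev[:3], atol=1e-9)  # gauss1/2, repulsion
        c_fwd = rf_counts(cplx).values.reshape(4, 9)
        c_rev = rf_counts(swapped).values.reshape(4, 9)
        shared = ["C", "N", "O", "S"]
        for i, p in enumerate(shared):
            for j, l in enumerate(shared):
                assert c_fwd[i, LIGAND_ELEMENTS.index(l)] == c_rev[
                    shared.index(l), LIGAND_ELEMENTS.index(p)
                ]
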
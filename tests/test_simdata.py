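"""Generator determinism, geometric constraints and degradation behaviour."""

import numpy as np
import pandas as pd
import pytest

from vinarf.curation import is_refined_quality, parse_index
from vinarf.interactions import featurize_set, rf_counts
from vinarf.models import fit_mlr, predict
from vinarf.simdata import (
    ComplexGenSpec,
    DegradeSpec,
    LabelGenSpec,
    degrade,
    gen_complex,
    gen_complexes,
    gen_dataset,
    gen_index,
    gen_labels,
)

SMALL = ComplexGenSpec(n_protein_atoms=25, n_ligand_atoms=8)


class TestGenComplex:
    def test_deterministic_given_seed(self):
        a = gen_complex(SMALL, seed=3)
        b = gen_complex(SMALL, seed=3)
        np.testing.assert_array_equal(
            [x.coords for x in a.protein_atoms], [x.coords for x in b.protein_atoms]
        )
        assert [x.element for x in a.ligand_atoms] == [x.element for x in b.ligand_atoms]
        assert a.n_rotatable_bonds == b.n_rotatable_bonds

    def test_min_separation_respected(self):
        cplx = gen_complex(SMALL, seed=11)
        coords = np.array(
            [a.coords for a in cplx.protein_atoms + cplx.ligand_atoms]
        )
        from scipy.spatial.distance import pdist

        assert pdist(coords).min() >= SMALL.min_separation - 1e-12

    def test_all_carbon_ligand_populates_only_carbon_columns(self):
        spec = ComplexGenSpec(n_protein_atoms=25, n_ligand_atoms=8,
                              ligand_freqs={"C": 1.0})
        cplx = gen_complex(spec, seed=2)
        counts = rf_counts(cplx)
        grid = counts.values.reshape(4, 9)
        assert grid[:, 0].sum() > 0  # (., C) column
        assert grid[:, 1:].sum() == 0

    def test_retry_cap_raises_helpful_error(self):
        cramped = ComplexGenSpec(
            n_protein_atoms=5, n_ligand_atoms=60, pocket_radius=2.0,
            max_retries=50,
        )
        with pytest.raises(RuntimeError, match="larger box"):
            gen_complex(cramped, seed=1)


class TestGenLabels:
    def test_noise_free_linear_is_exactly_recoverable(self):
        table, _ = featurize_set(gen_complexes(120, SMALL, 5), "vina6")
        spec = LabelGenSpec(mechanism="linear", noise_sd=0.0)
        y, params = gen_labels(table, spec, seed=1)
        lm = fit_mlr(table, y)
        np.testing.assert_allclose(lm.coefficients, params["beta"], atol=1e-8)

    def test_same_seed_same_labels(self):
        table, _ = featurize_set(gen_complexes(30, SMALL, 5), "vina6")
        spec = LabelGenSpec(noise_sd=0.7)
        y1, _ = gen_labels(table, spec, seed=9)
        y2, _ = gen_labels(table, spec, seed=9)
        np.testing.assert_array_equal(y1, y2)

    def test_nonlinear_labels_not_in_linear_span(self):
        table, _ = featurize_set(gen_complexes(300, SMALL, 6), "vina6")
        y, _ = gen_labels(table, LabelGenSpec(mechanism="nonlinear", noise_sd=0.0), 2)
        lm = fit_mlr(table, y)
        resid = y - predict(lm, table)
        assert np.sqrt(np.mean(resid**2)) > 0.1


class TestDegrade:
    def test_zero_degradation_is_identity(self):
        complexes = gen_complexes(10, SMALL, 7)
        y = np.linspace(2, 10, 10)
        out_c, out_y, ann = degrade(
            complexes, y, DegradeSpec(jitter_sd=0.0, label_noise_sd=0.0, label_bias_sd=0.0), 1
        )
        np.testing.assert_array_equal(out_y, y)
        for a, b in zip(complexes, out_c):
            np.testing.assert_array_equal(
                [x.coords for x in a.ligand_atoms], [x.coords for x in b.ligand_atoms]
            )

    def test_jitter_changes_counts_only_near_cutoff(self):
        complexes = gen_complexes(20, SMALL, 8)
        y = np.zeros(20)
        spec = DegradeSpec(jitter_sd=0.3, label_noise_sd=0.0, label_bias_sd=0.0)
        out_c, _, _ = degrade(complexes, y, spec, 3)
        from scipy.spatial.distance import cdist

        for before, after in zip(complexes, out_c):
            delta = int(
                abs(rf_counts(after).values.sum() - rf_counts(before).values.sum())
            )
            pc = np.array([a.coords for a in before.protein_atoms])
            lc = np.array([a.coords for a in before.ligand_atoms])
            d = cdist(pc, lc)
            # only pairs within a few jitter sds of the 12 A boundary can flip
            margin = 6 * spec.jitter_sd
            near_boundary = int(((d > 12 - margin) & (d < 12 + margin)).sum())
            assert delta <= near_boundary

    def test_degraded_annotations_fail_refined_quality(self):
        complexes = gen_complexes(5, SMALL, 9)
        y = np.zeros(5)
        spec = DegradeSpec(jitter_sd=0.3, label_noise_sd=0.5, label_bias_sd=0.5)
        _, _, ann = degrade(complexes, y, spec, 4)
        assert spec.implied_resolution == pytest.approx(3.0)
        assert (ann["degraded"]).all()
        assert (ann["resolution"] > 2.5).all()
        assert (ann["measure_kind"] == "IC50").all()

    def test_inputs_not_mutated(self):
        complexes = gen_complexes(5, SMALL, 10)
        before = [a.coords.copy() for a in complexes[0].ligand_atoms]
        y = np.zeros(5)
        degrade(complexes, y, DegradeSpec(jitter_sd=0.5), 5)
        np.testing.assert_array_equal(
            before, [a.coords for a in complexes[0].ligand_atoms]
        )


class TestGenIndex:
    def test_all_clean_composition_retained(self):
        from vinarf.curation import apply_general_filters

        text, _ = gen_index({"clean": 10}, seed=1)
        retained, removed = apply_general_filters(parse_index(text))
        assert len(retained) == 10 and sum(removed.values()) == 0

    def test_mixed_composition_counts(self):
        from vinarf.curation import apply_general_filters

        text, book = gen_index({"clean": 5, "nmr": 2}, seed=2)
        retained, removed = apply_general_filters(parse_index(text))
        assert len(retained) == 5 and removed["nmr"] == 2
        assert {r.pdb_code for r in retained} == set(book["clean"])

    def test_every_defect_class_emittable(self):
        composition = {cls: 2 for cls in (
            "clean", "non_protein_ligand", "conversion_failed", "approximate",
            "nmr", "covalent", "uncommon_element", "peptide_ge10",
            "nucleotide_ge4", "incomplete", "multi_ligand",
        )}
        text, book = gen_index(composition, seed=3)
        recs = parse_index(text)
        assert len(recs) == sum(composition.values())
        by_code = {r.pdb_code: r for r in recs}
        for cls in ("covalent", "multi_ligand", "incomplete"):
            for code in book[cls]:
                assert not is_refined_quality(by_code[code])

    def test_deterministic(self):
        a, _ = gen_index({"clean": 8, "approximate": 3}, seed=4)
        b, _ = gen_index({"clean": 8, "approximate": 3}, seed=4)
        assert a == b


class TestEndToEnd:
    def test_noise_free_linear_pipeline_recovers_labels(self):
        """Generator -> featurize -> labels -> OLS -> predictions, loss-free."""
        table, y, _, params = gen_dataset(
            300, seed=21, scheme="vina6",
            complex_spec=SMALL,
            label_spec=LabelGenSpec(mechanism="linear", noise_sd=0.0),
        )
        train, test = table.iloc[:250], table.iloc[250:]
        lm = fit_mlr(train, y[:250])
        rmse = np.sqrt(np.mean((predict(lm, test) - y[250:]) ** 2))
        assert rmse < 1e-6
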
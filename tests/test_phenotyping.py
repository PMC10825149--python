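import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lambdascape import core, phenotyping, synthetic

finite_rates = st.floats(min_value=-20, max_value=20)


class TestSpecializationIndex:
    def test_equal_rates_give_zero(self):
        assert phenotyping.specialization_index(0.7, 0.7) == pytest.approx(0.0)

    def test_twofold_growth_ratio_is_one_third(self):
        si = phenotyping.specialization_index(np.log(2), 0.0)
        assert si == pytest.approx(1 / 3, rel=1e-12)
        assert round(si, 2) == 0.33

    def test_extreme_specialist_limit(self):
        assert phenotyping.specialization_index(0.0, 50.0) == pytest.approx(-1.0)
        assert phenotyping.specialization_index(50.0, 0.0) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=200)
    @given(finite_rates, finite_rates)
    def test_antisymmetric_and_bounded(self, a, b):
        si = phenotyping.specialization_index(a, b)
        assert abs(si) <= 1.0
        assert si == pytest.approx(-phenotyping.specialization_index(b, a), abs=1e-12)

    def test_missing_rate_propagates(self):
        assert np.isnan(phenotyping.specialization_index(np.nan, 0.0))


class TestClassification:
    def test_threshold_is_strict(self):
        assert phenotyping.classify_phenotype(0.33) == "generalist"
        assert phenotyping.classify_phenotype(-0.33) == "generalist"
        assert phenotyping.classify_phenotype(0.331) == "L_specialist"
        assert phenotyping.classify_phenotype(-0.99) == "O_specialist"
        assert phenotyping.classify_phenotype(np.nan) == "undefined"

    def test_threshold_bounds_enforced(self):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(core.ValidationError):
                phenotyping.classify_phenotype(0.5, threshold=bad)


class TestMutationEffects:
    def test_additive_truth_recovers_site_effects_exactly(self):
        d_lamb = np.linspace(-0.9, -0.1, 9)
        model = synthetic.GroundTruthModel(d_lamb=d_lamb, d_ompf=np.zeros(9))
        landscapes = synthetic.generate_true_landscapes(model)
        frame, summary = phenotyping.mutation_effect_distributions(
            landscapes["A"], landscapes["E"]
        )
        assert summary["n_pairs_L"] == 9 * 256
        for site in range(1, 10):
            deltas = frame.loc[frame["site"] == site, "delta_S_L"]
            np.testing.assert_allclose(deltas, d_lamb[site - 1])
        np.testing.assert_allclose(frame["delta_S_O"], 0.0)

    def test_empty_landscape_gives_empty_table(self):
        empty = core.FitnessLandscape(core.ENVIRONMENTS["A"])
        frame, summary = phenotyping.mutation_effect_distributions(empty, empty)
        assert len(frame) == 0
        assert summary["n_pairs_L"] == 0


class TestSpecialistSelection:
    def test_empty_when_nothing_crosses_threshold(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "genotype": ["000000000", "100000000"],
                "S_L": [0.0, 0.1],
                "S_O": [0.0, 0.1],
                "SI": [0.0, 0.0],
                "phenotype_class": ["generalist", "generalist"],
            }
        )
        l_panel, o_panel = phenotyping.select_specialists(records)
        assert len(l_panel) == 0 and len(o_panel) == 0

    def test_panel_sizes_and_pair_count(self, phenotypes):
        l_panel, o_panel = phenotyping.select_specialists(phenotypes, k=27)
        assert len(l_panel) == 27
        assert len(o_panel) == 27
        trios, _ = phenotyping.hybrid_analysis(phenotypes, k=27)
        assert len(trios) == 27 * 27

    def test_missing_receptor_rate_excludes_record(self, phenotypes):
        records = phenotypes.copy()
        best = records["SI"].idxmax()
        records.loc[best, "S_O"] = np.nan
        l_panel, _ = phenotyping.select_specialists(records, k=27)
        assert records.loc[best, "genotype"] not in set(l_panel["genotype"])


class TestHybridGeometry:
    def test_collinear_hybrid_has_zero_displacement(self):
        d = phenotyping.hybrid_displacement((0.0, 1.0), (1.0, 0.0), (0.5, 0.5))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_point_line_example(self):
        d = phenotyping.hybrid_displacement((0.0, 1.0), (1.0, 0.0), (0.0, 0.0))
        assert d == pytest.approx(-1 / np.sqrt(2))

    def test_normal_offset_magnitude(self):
        p1, p2 = np.array([0.0, 1.0]), np.array([1.0, 0.0])
        mid = (p1 + p2) / 2
        normal = np.array([1.0, 1.0]) / np.sqrt(2)
        for offset in (0.4, -0.7):
            d = phenotyping.hybrid_displacement(p1, p2, mid + offset * normal)
            assert d == pytest.approx(offset)

    def test_coincident_parents_rejected(self):
        with pytest.raises(core.ValidationError):
            phenotyping.hybrid_displacement((1.0, 1.0), (1.0, 1.0), (0.0, 0.0))

    def test_against_least_squares_projection_oracle(self):
        """Signed distance agrees with an independent normal-equation oracle."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            p1, p2, h = rng.normal(0, 2, (3, 2))
            if np.allclose(p1, p2):
                continue
            d = phenotyping.hybrid_displacement(p1, p2, h)
            # oracle: project h onto the line via lstsq, measure residual
            t, *_ = np.linalg.lstsq(
                (p2 - p1).reshape(2, 1), (h - p1).reshape(2), rcond=None
            )
            foot = p1 + t[0] * (p2 - p1)
            residual = h - foot
            magnitude = np.hypot(*residual)
            sign = np.sign(residual.sum()) if magnitude > 1e-12 else 0.0
            assert d == pytest.approx(sign * magnitude, abs=1e-9)


class TestHybridAnalysis:
    def test_union_equal_to_parent_is_invalid(self):
        import pandas as pd

        rows = []
        for key, s_l, s_o in [
            ("100000000", 1.0, -1.0),  # L specialist
            ("110000000", 1.2, -1.2),  # L specialist containing the O parent? no:
            ("010000000", -1.0, 1.0),  # O specialist
        ]:
            si = phenotyping.specialization_index(s_l, s_o)
            rows.append((key, s_l, s_o, si, phenotyping.classify_phenotype(si)))
        records = pd.DataFrame(
            rows, columns=["genotype", "S_L", "S_O", "SI", "phenotype_class"]
        )
        # complete the 512-genotype table with NaN rows so hybrids resolve
        all_rows = pd.DataFrame(
            {
                "genotype": core.all_genotypes(),
                "S_L": np.nan,
                "S_O": np.nan,
                "SI": np.nan,
                "phenotype_class": "undefined",
            }
        ).set_index("genotype")
        for _, row in records.iterrows():
            all_rows.loc[row["genotype"]] = row[1:].tolist()
        table = all_rows.reset_index()
        trios, _ = phenotyping.hybrid_analysis(table)
        # hybrid of 110000000 x 010000000 is 110000000 itself -> invalid
        mask = (trios["parent_L"] == "110000000") & (trios["parent_O"] == "010000000")
        assert not trios.loc[mask, "valid"].item()

    def test_incompatibility_drives_hybrids_below(self, phenotypes):
        trios, fraction_below = phenotyping.hybrid_analysis(phenotypes, k=27)
        assert trios["valid"].sum() > 500
        assert fraction_below >= 0.7

    def test_exponentiated_plane_option_runs(self, phenotypes):
        _, fraction_log = phenotyping.hybrid_analysis(phenotypes, k=5)
        _, fraction_exp = phenotyping.hybrid_analysis(
            phenotypes, k=5, exponentiate=True
        )
        assert np.isfinite(fraction_log) and np.isfinite(fraction_exp)
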
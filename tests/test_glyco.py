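import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from glycotrack import (
    DataIntegrityError,
    DegenerateInputError,
    GlycoSimConfig,
    NullRatioModel,
    UnpairedRecordError,
    aggregate_glycosites,
    classify_fold_change,
    compare_multiplicity,
    compute_log_ratio,
    compute_log_ratios,
    fit_null_model,
    glycoproteome_report,
    peptide_site_to_protein,
    select_candidates,
    simulate_flowthrough_ratios,
    simulate_glyco_dataset,
    summarize_proteins,
)
from .conftest import make_records

T3 = math.log10(3)


class TestLogRatio:
    @pytest.mark.parametrize(
        "medium,light,expected",
        [
            (100.0, 100.0, 0.0),
            (200.0, 100.0, -0.30103),
            # a 50-fold drop in the mutant, the strongest site-level change
            (5000.0, 100.0, -1.69897),
        ],
    )
    def test_values(self, medium, light, expected):
        rec = {"intensity_medium": medium, "intensity_light": light, "paired": True}
        assert compute_log_ratio(rec) == pytest.approx(expected, abs=1e-5)

    def test_unpaired_is_unquantifiable_not_zero(self):
        rec = {"intensity_medium": 100.0, "intensity_light": np.nan, "paired": False}
        with pytest.raises(UnpairedRecordError):
            compute_log_ratio(rec)

    def test_vectorised_nan_for_unpaired(self, records_small):
        r = compute_log_ratios(records_small)
        assert r.notna().sum() == 3
        assert np.isnan(r.iloc[3])


class TestNullModel:
    def test_cutoff_recovers_three_sigma(self):
        r = simulate_flowthrough_ratios(100_000, sigma=0.55 / 3, seed=3)
        model = fit_null_model(r)
        assert model.cutoff == pytest.approx(0.55, abs=0.01)
        assert model.mu == pytest.approx(0.0, abs=0.005)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            fit_null_model(np.zeros(100))
        with pytest.raises(DegenerateInputError):
            fit_null_model(np.arange(10.0))

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            NullRatioModel(mu=0.0, sigma=0.0, cutoff=1.0)
        with pytest.raises(ValueError):
            NullRatioModel(mu=0.0, sigma=1.0, cutoff=-1.0)


class TestCandidateSelection:
    def test_boundary_is_strictly_excluded(self):
        model = NullRatioModel(mu=0.0, sigma=0.55 / 3, cutoff=0.55)
        df = pd.DataFrame({"log_ratio": [0.0, 0.55, -0.55, 0.5501, -0.56, np.nan]})
        sel = select_candidates(df, model)
        assert sel["log_ratio"].tolist() == [0.5501, -0.56]

    def test_spiked_effects_all_selected(self):
        rng = np.random.default_rng(4)
        null = rng.normal(0, 0.1, 5000)
        spiked = rng.choice([-1.0, 1.0], 200) + rng.normal(0, 0.1, 200)
        df = pd.DataFrame(
            {"log_ratio": np.concatenate([null, spiked]),
             "is_spiked": [False] * 5000 + [True] * 200}
        )
        model = fit_null_model(null)
        sel = select_candidates(df, model)
        assert sel.loc[sel["is_spiked"]].shape[0] == 200

    def test_null_false_positive_rate(self):
        n = 200_000
        null = simulate_flowthrough_ratios(n, sigma=0.55 / 3, seed=5)
        model = fit_null_model(simulate_flowthrough_ratios(n, sigma=0.55 / 3, seed=6))
        sel = select_candidates(pd.DataFrame({"log_ratio": null}), model)
        p = 1 - 0.9973
        se = math.sqrt(p * (1 - p) / n)
        assert len(sel) / n == pytest.approx(p, abs=3 * se)


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.0, "unchanged"),
            (0.3, "unchanged"),
            (-math.log10(13), "down10"),   # 13-fold reduction
            (-math.log10(5), "down3"),     # 5-fold reduction
            (-math.log10(50), "down10"),   # 50-fold reduction
            (T3, "up3"),                   # boundary inclusive at 3x
            (1.0, "up10"),                 # boundary inclusive at 10x
            (-1.0, "down10"),
            (0.9999, "up3"),
        ],
    )
    def test_categories(self, ratio, expected):
        assert classify_fold_change(ratio) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_fold_change(float("nan"))
        with pytest.raises(ValueError):
            classify_fold_change(np.array([0.1, np.inf]))

    @given(st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_sign_mirror(self, r):
        mirror = {"up3": "down3", "down3": "up3", "up10": "down10",
                  "down10": "up10", "unchanged": "unchanged"}
        assert classify_fold_change(-r) == mirror[classify_fold_change(r)]

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_ten_fold_nested_in_three_fold(self, r):
        cat = classify_fold_change(r)
        if cat in ("up10", "down10"):
            assert abs(r) >= T3


class TestChannelSwapAntisymmetry:
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1e-3, max_value=1e9),
                st.floats(min_value=1e-3, max_value=1e9),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_swap_negates_ratios_and_mirrors_categories(self, intensities):
        rows = [("P1", i + 1, "T", "Tn", m, l) for i, (m, l) in enumerate(intensities)]
        fwd = make_records(rows)
        rev = fwd.rename(
            columns={"intensity_medium": "intensity_light",
                     "intensity_light": "intensity_medium"}
        )
        r_fwd = compute_log_ratios(fwd).to_numpy()
        r_rev = compute_log_ratios(rev).to_numpy()
        np.testing.assert_allclose(r_rev, -r_fwd, atol=1e-12)
        mirror = {"up3": "down3", "down3": "up3", "up10": "down10",
                  "down10": "up10", "unchanged": "unchanged"}
        for a, b in zip(classify_fold_change(r_fwd), classify_fold_change(r_rev)):
            assert b == mirror[a]


class TestSiteAggregation:
    def test_median_of_psm_ratios(self):
        rec = make_records(
            [
                ("P1", 10, "T", "Tn", 1.0, 0.1),
                ("P1", 10, "T", "Tn", 1.0, 0.01),
                ("P1", 10, "T", "Tn", 1.0, 0.001),
            ]
        )
        site = aggregate_glycosites(rec)
        assert site.loc[0, "log_ratio_Tn"] == pytest.approx(-2.0)

    def test_both_glycoforms_classify_site_as_both(self, records_small):
        site = aggregate_glycosites(records_small)
        s = site.set_index(["protein_id", "site_position"])
        assert s.loc[("P1", 10), "glycoform_class"] == "both"
        assert s.loc[("P1", 50), "glycoform_class"] == "Tn-only"

    def test_unpaired_only_site_is_unquantified(self, records_small):
        site = aggregate_glycosites(records_small)
        row = site.set_index("protein_id").loc["P2"]
        assert row["category_Tn"] == "unquantified"
        assert np.isnan(row["log_ratio_Tn"])

    def test_residue_conflict_raises(self):
        rec = make_records(
            [("P1", 10, "T", "Tn", 1.0, 1.0), ("P1", 10, "S", "Tn", 1.0, 1.0)]
        )
        with pytest.raises(DataIntegrityError):
            aggregate_glycosites(rec)

    def test_peptide_coordinate_helper(self):
        assert peptide_site_to_protein(peptide_start=100, position_in_peptide=3) == 102
        with pytest.raises(ValueError):
            peptide_site_to_protein(0, 1)


class TestProteinSummary:
    def test_counts_and_class(self):
        rec = make_records(
            [
                ("P1", 10, "T", "Tn", 1.0, 1.0),
                ("P1", 20, "S", "Tn", 1.0, 1.0),
                ("P2", 5, "T", "T", 1.0, 1.0),
            ]
        )
        prot = summarize_proteins(aggregate_glycosites(rec)).set_index("protein_id")
        assert prot.loc["P1", "n_glycosites"] == 2
        assert prot.loc["P1", "glycoform_class"] == "Tn-only"
        assert prot.loc["P2", "glycoform_class"] == "T-only"

    def test_direct_target_requires_down_plus_unchanged_site(self):
        rec = make_records(
            [
                ("P1", 10, "T", "T", 1000.0, 50.0),  # down10
                ("P1", 20, "S", "Tn", 100.0, 100.0),  # unchanged
                ("P2", 5, "T", "T", 1000.0, 50.0),   # down10, single site
            ]
        )
        prot = summarize_proteins(aggregate_glycosites(rec)).set_index("protein_id")
        assert bool(prot.loc["P1", "direct_target"])
        assert not bool(prot.loc["P2", "direct_target"])
        # direct_target implies >= 2 sites
        assert (prot.loc[prot["direct_target"], "n_glycosites"] >= 2).all()


class TestReport:
    def test_all_tn_input_is_fully_tn_only(self):
        rec = make_records(
            [("P1", 10, "T", "Tn", 1.0, 1.0), ("P2", 4, "S", "Tn", 1.0, 1.0)]
        )
        site = aggregate_glycosites(rec)
        report = glycoproteome_report(site, summarize_proteins(site))
        assert report["pct_sites_by_class"]["Tn-only"] == 100
        assert report["pct_proteins_by_class"]["Tn-only"] == 100

    def test_percentage_axes_sum_to_100(self):
        rec, _ = simulate_glyco_dataset(GlycoSimConfig(n_proteins=80, seed=13))
        site = aggregate_glycosites(rec)
        report = glycoproteome_report(site, summarize_proteins(site))
        for axis in ("pct_sites_by_class", "pct_proteins_by_class",
                     "pct_proteins_by_n_sites", "pct_residues"):
            assert sum(report[axis].values()) == pytest.approx(100, abs=0.1)

    def test_spiked_counts_match_ground_truth(self):
        # 20-fold effects sit decisively past both thresholds, so the
        # report counts must equal the ground-truth spiked protein count
        cfg = GlycoSimConfig(
            n_proteins=120, frac_changed=0.2,
            effect_log10=(-math.log10(20), math.log10(20)),
            null_sigma=0.05, singleton_rate=0.0, seed=17,
        )
        rec, truth = simulate_glyco_dataset(cfg)
        site = aggregate_glycosites(rec)
        prot = summarize_proteins(site)
        report = glycoproteome_report(site, prot)
        expected = truth.loc[truth["effect_log10"] != 0, "protein_id"].nunique()
        assert report["n_proteins_over_3x"] == expected
        assert report["n_proteins_over_10x"] == expected


class TestMultiplicityComparison:
    def test_identical_samples_give_p_near_one(self):
        counts = [1, 2, 3, 4, 5] * 10
        assert compare_multiplicity(counts, counts) >= 0.99

    def test_shifted_sample_detected(self):
        rng = np.random.default_rng(19)
        base = rng.integers(1, 6, size=50)
        assert compare_multiplicity(base + 3, base) < 0.01

    def test_agrees_with_permutation_oracle(self):
        x = [1, 1, 2, 2, 3, 3, 4, 5, 6, 8]
        y = [1, 1, 1, 2, 2, 2, 3, 3, 4, 4]
        observed = compare_multiplicity(x, y)
        # brute-force permutation null of the U statistic
        pooled = np.array(x + y, float)
        n = len(x)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        dev_obs = abs(u_obs - n * (len(y)) / 2)
        count = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2
            if abs(u - n * len(y) / 2) >= dev_obs - 1e-9:
                count += 1
            total += 1
        assert observed == pytest.approx(count / total, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_multiplicity([], [1, 2])
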
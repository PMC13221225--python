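"""Generator contracts: determinism, planted effects, fragment physics,
mixtures, and clinical coupling."""

import numpy as np
import pandas as pd
import pytest

from cfmesa.io import beta_matrix
from cfmesa.regions import AnnotationSet, GenomicRegion
from cfmesa.simulate import (
    ClinicalCoupling,
    CohortDesign,
    FragmentModel,
    PlantedDMR,
    generate_atlas,
    generate_clinical,
    generate_cohort,
    generate_fragments,
    generate_multimodal_dataset,
    spike_in_mixture,
)


class TestCohort:
    def test_null_design_has_empty_truth_and_small_group_difference(self):
        design = CohortDesign(
            n_per_group={"sALS": 10, "control": 10}, n_cpgs=500, seed=0
        )
        samples, truth = generate_cohort(design)
        assert len(truth["dmcs"]) == 0 and len(truth["dmrs"]) == 0
        beta = beta_matrix(samples)
        diff = beta.iloc[:10].mean() - beta.iloc[10:].mean()
        assert np.abs(diff).mean() < 0.05

    def test_planted_delta_realized_within_tolerance(self):
        planted = PlantedDMR("chr1", 30_000, 30_500, n_cpgs=12, delta_beta=-0.14)
        design = CohortDesign(n_cpgs=400, planted_dmrs=[planted], seed=4)
        samples, truth = generate_cohort(design)
        beta = beta_matrix(samples)
        labels = pd.Series({s.sample_id: s.group for s in samples})
        cols = [c for c in beta.columns if c[1] in set(truth["dmcs"]["pos"])]
        sub = beta[cols]
        realized = (
            sub[labels == "sALS"].mean().mean()
            - sub[labels == "control"].mean().mean()
        )
        assert realized == pytest.approx(-0.14, abs=0.03)

    def test_same_seed_reproduces_identical_cohort(self):
        design = CohortDesign(n_cpgs=200, seed=11)
        a, _ = generate_cohort(design)
        b, _ = generate_cohort(design)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.calls, sb.calls)

    def test_mean_depth_matches_design(self):
        design = CohortDesign(
            n_per_group={"control": 3}, n_cpgs=2000, mean_depth=45.0, seed=2
        )
        samples, _ = generate_cohort(design)
        assert samples[0].mean_depth == pytest.approx(45.0, abs=1.0)

    def test_overlapping_planted_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CohortDesign(
                planted_dmrs=[
                    PlantedDMR("chr1", 100, 800, 10, 0.1),
                    PlantedDMR("chr1", 700, 1500, 10, 0.1),
                ]
            )

    def test_planted_region_needs_ten_cpgs(self):
        with pytest.raises(ValueError, match="10"):
            PlantedDMR("chr1", 100, 800, n_cpgs=9, delta_beta=0.1)


class TestFragments:
    def _setup(self):
        design = CohortDesign(n_per_group={"control": 1}, n_cpgs=300, seed=8)
        samples, _ = generate_cohort(design)
        region = AnnotationSet(
            "target", [GenomicRegion("chr1", 0, 20_000, "t", "target")]
        )
        return samples[0], region

    def test_length_mode_near_mononucleosome(self):
        sample, region = self._setup()
        frags = generate_fragments(sample, FragmentModel(), region, 10_000, seed=1)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        hist, edges = np.histogram(lengths, bins=np.arange(100, 502, 4))
        mode = edges[np.argmax(hist)]
        assert 160 <= mode <= 180

    def test_no_dinucleosome_component_caps_length(self):
        sample, region = self._setup()
        model = FragmentModel(di_weight=0.0)
        frags = generate_fragments(sample, model, region, 5000, seed=2)
        assert (frags["end"] - frags["start"]).max() <= 250

    def test_unmethylated_sample_yields_no_M_states(self):
        sample, region = self._setup()
        sample.calls["meth"] = 0
        sample.calls["beta"] = np.where(sample.calls["total"] > 0, 0.0, np.nan)
        frags = generate_fragments(sample, FragmentModel(), region, 2000, seed=3)
        assert not frags["cpg_states"].str.contains("M").any()

    def test_short_regions_skipped(self, caplog):
        sample, _ = self._setup()
        regions = AnnotationSet(
            "target",
            [
                GenomicRegion("chr1", 0, 300, "short", "target"),
                GenomicRegion("chr1", 1000, 3000, "long", "target"),
            ],
        )
        frags = generate_fragments(sample, FragmentModel(), regions, 500, seed=4)
        centers = (frags["start"] + frags["end"]) // 2
        assert (centers > 900).all()


class TestAtlas:
    def test_shape_and_grouping_contract(self):
        atlas, _, frags = generate_atlas(
            n_cell_types=7, n_markers_per_type=5, n_samples_per_type=1,
            n_fragments_per_marker=20, seed=0,
        )
        assert atlas.u_fractions.shape == (7, 35)
        assert len(set(atlas.grouping.values())) == 7
        assert set(frags) == set(atlas.cell_types)

    def test_degenerate_u_levels_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            generate_atlas(u_high=0.3, u_low=0.3)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError, match="n_markers_per_type"):
            generate_atlas(n_markers_per_type=0)

    def test_empirical_u_fraction_matches_atlas_entry(self):
        from cfmesa.deconvolution import compute_u_fractions

        atlas, _, frags = generate_atlas(
            n_cell_types=3, n_markers_per_type=2, n_samples_per_type=1,
            n_fragments_per_marker=2000, seed=9,
        )
        ctype = atlas.cell_types[0]
        observed = compute_u_fractions(frags[ctype][0], atlas.markers)
        expected = atlas.u_fractions.loc[ctype]
        assert np.abs(observed - expected).max() <= 0.05


class TestSpikeIn:
    def _pools(self, rng):
        def pool(n, sid):
            starts = rng.integers(0, 10**5, size=n)
            return pd.DataFrame(
                {
                    "chrom": "chr1", "start": starts, "end": starts + 160,
                    "cpg_states": "MMM", "sample_id": sid,
                }
            )
        return pool(3000, "bg"), pool(1500, "tg")

    def test_zero_fraction_all_background(self, rng):
        bg, tg = self._pools(rng)
        mix = spike_in_mixture(bg, tg, 0.0, 1000, seed=0)
        assert (mix["origin"] == "background").all()

    def test_exact_target_count(self, rng):
        bg, tg = self._pools(rng)
        mix = spike_in_mixture(bg, tg, 0.05, 2000, seed=0)
        assert (mix["origin"] == "target").sum() == 100
        assert len(mix) == 2000

    def test_counts_constant_compositions_differ_across_seeds(self, rng):
        bg, tg = self._pools(rng)
        picks = []
        for seed in range(10):
            mix = spike_in_mixture(bg, tg, 0.05, 2000, seed=seed)
            assert (mix["origin"] == "target").sum() == 100
            picks.append(tuple(sorted(mix[mix["origin"] == "target"]["start"])))
        assert len(set(picks)) > 1

    def test_pool_exhaustion_raises(self, rng):
        bg, tg = self._pools(rng)
        with pytest.raises(ValueError, match="exhausted"):
            spike_in_mixture(bg, tg, 0.9, 2000, seed=0)


class TestClinical:
    def _meth(self, n, rng):
        ids = [f"sALS_{i:02d}" for i in range(n)]
        return pd.Series(rng.beta(10, 10, size=n), index=ids)

    def test_perfect_coupling_without_noise_is_exact(self, rng):
        meth = self._meth(19, rng)
        coupling = ClinicalCoupling(gene="g", rho_slope=1.0, noise=0.0)
        sheet = generate_clinical(
            meth.index, ["sALS"] * 19, meth, coupling, seed=0
        )
        from cfmesa.clinical import add_progression_slopes
        from scipy.stats import spearmanr

        slopes = add_progression_slopes(sheet).set_index("sample_id")["slope"]
        assert spearmanr(meth, slopes[meth.index]).statistic == pytest.approx(1.0)

    def test_null_coupling_stays_inside_permutation_band(self, rng):
        from cfmesa.clinical import add_progression_slopes
        from scipy.stats import spearmanr

        inside = 0
        for seed in range(20):
            meth = self._meth(19, rng)
            coupling = ClinicalCoupling(gene="g", rho_slope=0.0)
            sheet = generate_clinical(meth.index, ["sALS"] * 19, meth, coupling, seed=seed)
            slopes = add_progression_slopes(sheet).set_index("sample_id")["slope"]
            rho = spearmanr(meth, slopes[meth.index]).statistic
            inside += abs(rho) < 0.45
        assert inside >= 18

    def test_slope_identity_survives_score_rounding(self, rng):
        meth = self._meth(10, rng)
        coupling = ClinicalCoupling(gene="g", rho_slope=0.8)
        sheet = generate_clinical(meth.index, ["sALS"] * 10, meth, coupling, seed=3)
        ok = sheet.dropna(subset=["alsfrs_r_at_draw"])
        slope = (48 - ok["alsfrs_r_at_draw"]) / ok["months_from_onset"]
        assert (ok["months_from_onset"] > 0).all()
        assert np.isfinite(slope).all()

    def test_controls_get_missing_clinical_values(self, rng):
        meth = pd.Series(rng.beta(10, 10, size=4), index=["a", "b", "c", "d"])
        sheet = generate_clinical(
            ["a", "b", "c", "d"],
            ["sALS", "control", "C9-carrier", "C9-ALS"],
            meth, ClinicalCoupling(gene="g"), seed=0,
        )
        by_id = sheet.set_index("sample_id")
        assert np.isnan(by_id.loc["b", "alsfrs_r_at_draw"])
        assert np.isnan(by_id.loc["c", "pnfh_csf"])
        assert not np.isnan(by_id.loc["a", "pnfh_csf"])

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            ClinicalCoupling(gene="g", rho_slope=1.5)


class TestMultimodal:
    def test_scheme_seed_fixes_generative_process(self):
        kw = dict(
            n_per_group={"sALS": 5, "control": 5},
            n_features={"cgi_meth": 10, "dhs_meth": 10, "occupancy": 5, "wps": 5},
            n_informative={"cgi_meth": 3},
            delta_beta=0.3,
        )
        a, _, truth_a = generate_multimodal_dataset(seed=1, scheme_seed=42, **kw)
        b, _, truth_b = generate_multimodal_dataset(seed=2, scheme_seed=42, **kw)
        assert truth_a == truth_b
        # same scheme, different sampling noise
        assert not np.allclose(
            a["cgi_meth"].values.to_numpy(), b["cgi_meth"].values.to_numpy()
        )
        # informative case-control separation has consistent sign across cohorts
        for mats in (a, b):
            X = mats["cgi_meth"].values
            labels = X.index.str.startswith("sALS")
            diff = X.loc[labels].mean() - X.loc[~labels].mean()
            assert np.abs(diff[truth_a["cgi_meth"]]).mean() > 0.1

    def test_betas_stay_in_unit_interval(self):
        mats, _, _ = generate_multimodal_dataset(
            n_per_group={"sALS": 5, "control": 5}, seed=0
        )
        values = mats["cgi_meth"].values.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0
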
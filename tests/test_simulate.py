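"""Synthetic-data generators: distributions, determinism, round trips."""

import numpy as np
import pytest
from scipy import stats

import minmod as mm
from minmod import datasets
from minmod.effects import PointMassEffect


class TestControlCohort:
    def test_empty_cohort(self, colony):
        assert mm.simulate_control_cohort(colony, 0, seed=1) == []

    def test_negative_size_rejected(self, colony):
        with pytest.raises(ValueError):
            mm.simulate_control_cohort(colony, -1, seed=1)

    def test_nb_moments_at_scale(self, colony):
        """Sample mean within 1% of 99.8 and variance within 3% of
        99.8 + 99.8^2/9.8 at n = 1e5."""
        cohort = mm.simulate_control_cohort(colony, 100_000, seed=42)
        counts = np.array([a.tumor_count for a in cohort])
        assert counts.mean() == pytest.approx(99.8, rel=0.01)
        expected_var = 99.8 + 99.8**2 / 9.8
        assert counts.var(ddof=1) == pytest.approx(expected_var, rel=0.03)

    def test_nb_goodness_of_fit(self, colony, baseline):
        """Chi-square GOF of simulated counts against the NB pmf at n=1e5."""
        cohort = mm.simulate_control_cohort(colony, 100_000, seed=7)
        counts = np.array([a.tumor_count for a in cohort])
        edges = np.unique(baseline.ppf(np.linspace(0.02, 0.98, 25)))
        bins = np.concatenate(([-0.5], edges + 0.5, [np.inf]))
        observed, _ = np.histogram(counts, bins=bins)
        cdf_vals = np.concatenate(
            ([0.0], [baseline.cdf(e) for e in edges], [1.0])
        )
        expected = np.diff(cdf_vals) * len(counts)
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_survival_negatively_linked_to_burden(self, colony):
        cohort = mm.simulate_control_cohort(colony, 5000, seed=3)
        counts = [a.tumor_count for a in cohort]
        lifespans = [a.lifespan_days for a in cohort]
        rho = stats.spearmanr(counts, lifespans).statistic
        assert rho < -0.3

    def test_seed_determinism(self, colony):
        a = mm.simulate_control_cohort(colony, 500, seed=9)
        b = mm.simulate_control_cohort(colony, 500, seed=9)
        assert a == b


class TestKindreds:
    def test_degenerate_mixture_all_unaffected(self, colony):
        classes = mm.ModifierClassParams(class_weights=(1.0, 0.0, 0.0))
        kins = mm.simulate_kindreds(colony, classes, 50, 5, seed=1)
        assert all(k.latent_class == "none" and k.fold_effect == 1.0 for k in kins)
        assert not any(a.is_carrier for k in kins for a in k.animals)

    def test_fixed_enhancer_carrier_moments(self, colony):
        """All-enhancer mixture at fixed fold 2: carrier fraction ~1/2 and
        carrier mean ~199.6 over 1e5 progeny."""
        classes = mm.ModifierClassParams(
            class_weights=(0.0, 0.0, 1.0),
            enhancer_effect=PointMassEffect(2.0),
        )
        kins = mm.simulate_kindreds(colony, classes, 100, 1000, seed=5)
        carriers = np.array([a.is_carrier for k in kins for a in k.animals])
        counts = np.array([a.tumor_count for k in kins for a in k.animals])
        assert carriers.mean() == pytest.approx(0.5, abs=0.005)
        assert counts[carriers].mean() == pytest.approx(199.6, rel=0.02)
        assert counts[~carriers].mean() == pytest.approx(99.8, rel=0.02)

    def test_class_frequencies_recover_weights(self, colony):
        """Latent class draws match the published weight estimates within
        binomial error at 1e4 kindreds."""
        classes = mm.ModifierClassParams()
        kins = mm.simulate_kindreds(colony, classes, 10_000, 1, seed=11)
        freq = {
            c: sum(1 for k in kins if k.latent_class == c) / len(kins)
            for c in ("none", "suppressor", "enhancer")
        }
        for target, name in zip(datasets.MODIFIER_CLASS_WEIGHTS, freq):
            se = np.sqrt(target * (1 - target) / 10_000)
            assert abs(freq[name] - target) < 4 * se

    def test_invalid_weights_rejected(self, colony):
        with pytest.raises(ValueError):
            mm.ModifierClassParams(class_weights=(0.5, 0.5, 0.1))

    def test_fold_consistency_invariant(self, colony):
        kins = mm.simulate_kindreds(colony, mm.ModifierClassParams(), 200, 3, seed=2)
        for k in kins:
            assert (k.latent_class == "none") == (k.fold_effect == 1.0)
            if k.latent_class == "suppressor":
                assert 0 < k.fold_effect < 1
            if k.latent_class == "enhancer":
                assert k.fold_effect > 1

    def test_seed_determinism(self, colony):
        classes = mm.ModifierClassParams()
        a = mm.simulate_kindreds(colony, classes, 30, 4, seed=13)
        b = mm.simulate_kindreds(colony, classes, 30, 4, seed=13)
        assert a == b


class TestVariantLines:
    sizes = mm.ChromSizes({"1": 1_000_000_000, "2": 1_000_000_000})

    def test_zero_rate_empty(self):
        t = mm.simulate_variant_lines(self.sizes, rate_per_bp=0.0, n_lines=2,
                                      line_names=("a", "b"), seed=1)
        assert len(t) == 0

    def test_poisson_count(self):
        """One line over 2e9 bp at 1.1e-6/bp: count within 3 SD of 2200."""
        t = mm.simulate_variant_lines(self.sizes, rate_per_bp=1.1e-6, n_lines=1,
                                      line_names=("a",), seed=8)
        lam = 1.1e-6 * 2e9
        assert abs(len(t) - lam) < 3 * np.sqrt(lam)

    def test_spectrum_shares_match_input(self):
        t = mm.simulate_variant_lines(self.sizes, rate_per_bp=5e-6, n_lines=1,
                                      line_names=("a",), seed=21)
        spec = mm.mutation_spectrum(t.records)
        total = sum(datasets.ENU_SPECTRUM_COUNTS.values())
        n = len(t)
        for pair, count in datasets.ENU_SPECTRUM_COUNTS.items():
            p = count / total
            se = np.sqrt(p * (1 - p) / n)
            observed = spec.loc[pair, "count"] / n
            assert abs(observed - p) < 5 * se

    def test_related_pair_sharing(self):
        t = mm.simulate_variant_lines(self.sizes, rate_per_bp=2e-6, n_lines=3,
                                      line_names=("a", "g", "h"),
                                      related_pair=("g", "h"), seed=3)
        part = mm.partition_line_specific(t, related_pair=("g", "h"))
        n_shared = len(part.shared_pair)
        n_excl = len(part.exclusive["g"]) + len(part.exclusive["h"])
        share = n_shared / (n_shared + n_excl)
        assert share == pytest.approx(792 / (792 + 1225 + 2520), rel=0.2)

    def test_residual_heterozygosity_rate(self):
        t = mm.simulate_variant_lines(self.sizes, rate_per_bp=2e-6, n_lines=1,
                                      line_names=("a",), residual_het_rate=0.14,
                                      seed=5)
        het = (t.records["zygosity"] == "het").mean()
        assert het == pytest.approx(0.14, abs=0.02)

    def test_seed_determinism(self):
        a = mm.simulate_variant_lines(self.sizes, rate_per_bp=1e-6, n_lines=2,
                                      line_names=("a", "b"), seed=17)
        b = mm.simulate_variant_lines(self.sizes, rate_per_bp=1e-6, n_lines=2,
                                      line_names=("a", "b"), seed=17)
        assert a.records.equals(b.records)


class TestGenotypingFixture:
    def test_empty(self):
        assert mm.simulate_genotyping_fixture({}, seed=1) == []

    def test_singleton_round_trip(self):
        fx = mm.simulate_genotyping_fixture({"validated_homozygous": 1}, seed=1)
        assert len(fx) == 1
        assert mm.classify_site(fx[0]) == "validated_homozygous"

    def test_published_accounting_round_trip(self):
        """The five Sequenom outcome categories (8, 5, 1, 11, 123) are
        recovered exactly by the classifier."""
        fx = mm.simulate_genotyping_fixture(datasets.VALIDATION_CATEGORY_COUNTS, seed=4)
        counts = mm.summarize_validation([mm.classify_site(r) for r in fx])
        assert counts == datasets.VALIDATION_CATEGORY_COUNTS

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mm.simulate_genotyping_fixture({"assay_failure": -1}, seed=1)
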
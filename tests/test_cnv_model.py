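import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from itertools import product

from cnvdn.cnv_model import (
    FamilyData,
    LatentGenotype,
    ModelConfig,
    OffspringState,
    collapse_variants,
    compose_offspring_cn,
    enumerate_family_posterior,
    log_likelihood_measurements,
    log_prior_latent,
)

FIXED = dict(sigma_mode="fixed", sigma_fixed=0.15)


def two_kid_family(child1, child2=(2.0, 2.0), parents=(2.0, 2.0)):
    return FamilyData(
        "fam",
        father_reps=np.asarray(parents, dtype=float),
        mother_reps=np.asarray(parents, dtype=float),
        offspring=[
            ("c1", np.asarray(child1, dtype=float)),
            ("c2", np.asarray(child2, dtype=float)),
        ],
    )


class TestCompose:
    @pytest.mark.parametrize(
        "af,am,kf,km,ti,td,expected",
        [
            ((1, 1), (1, 1), 0, 0, 0, 0, 2),   # homozygous normal
            ((1, 1), (1, 1), 1, 1, 0, 0, 2),
            ((1, 1), (1, 1), 0, 1, 1, 0, 3),   # forced gain
            # hand evaluation: k_f=0 takes max=2, k_m=1 takes min=0,
            # gain and loss cancel -> 2 + 0 + 1 - 1 = 2
            ((1, 2), (0, 1), 0, 1, 1, 1, 2),
            ((0, 0), (0, 0), 1, 1, 0, 1, 0),   # clamped at zero
        ],
    )
    def test_examples(self, af, am, kf, km, ti, td, expected):
        assert compose_offspring_cn(af, am, kf, km, ti, td) == expected

    def test_negative_allele_rejected(self):
        with pytest.raises(ValueError):
            compose_offspring_cn((-1, 1), (1, 1), 0, 0, 0, 0)

    @given(
        af=st.tuples(st.integers(0, 4), st.integers(0, 4)),
        am=st.tuples(st.integers(0, 4), st.integers(0, 4)),
        kf=st.integers(0, 1),
        km=st.integers(0, 1),
        ti=st.integers(0, 1),
        td=st.integers(0, 1),
    )
    def test_matches_formula_and_stays_non_negative(self, af, am, kf, km, ti, td):
        got = compose_offspring_cn(af, am, kf, km, ti, td)
        raw = (
            kf * min(af) + (1 - kf) * max(af)
            + km * min(am) + (1 - km) * max(am)
            + ti - td
        )
        assert got == max(raw, 0) >= 0


class TestMeasurementLikelihood:
    def test_zero_residual(self):
        ll = log_likelihood_measurements(np.array([2.0, 2.0]), 2, 0.2)
        assert ll == pytest.approx(2 * np.log(1 / (0.2 * np.sqrt(2 * np.pi))))

    def test_closed_form_log_ratio(self):
        x = np.array([2.3])
        ratio = log_likelihood_measurements(x, 2, 0.15) - log_likelihood_measurements(
            x, 3, 0.15
        )
        assert ratio == pytest.approx((0.7**2 - 0.3**2) / (2 * 0.15**2))

    @given(st.lists(st.floats(-1, 5), min_size=1, max_size=6), st.integers(0, 6))
    def test_permutation_invariance(self, reps, cn):
        a = log_likelihood_measurements(np.array(reps), cn, 0.2)
        b = log_likelihood_measurements(np.array(reps[::-1]), cn, 0.2)
        assert a == pytest.approx(b)

    def test_untyped_individual_contributes_zero(self):
        assert log_likelihood_measurements(np.array([]), 2, 0.2) == 0.0

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            log_likelihood_measurements(np.array([2.0]), 2, 0.0)


class TestLatentPrior:
    cfg = ModelConfig(mutation_prior=0.005)

    def geno(self, ti=0, td=0):
        return LatentGenotype(
            {"f": (1, 1), "m": (1, 1)}, {"c1": OffspringState(0, 0, ti, td)}
        )

    def test_no_mutation_factor(self):
        diff = log_prior_latent(self.geno(), self.cfg) - log_prior_latent(
            self.geno(ti=1), self.cfg
        )
        assert diff == pytest.approx(np.log(0.995) - np.log(0.005))

    def test_doubling_mutation_prior_shifts_gain_by_log2(self):
        lo = log_prior_latent(self.geno(ti=1), ModelConfig(mutation_prior=0.005))
        hi = log_prior_latent(self.geno(ti=1), ModelConfig(mutation_prior=0.010))
        assert hi - lo == pytest.approx(np.log(2), abs=0.02)

    def test_inheritance_indicators_uniform(self):
        base = log_prior_latent(self.geno(), self.cfg)
        for kf, km in [(0, 1), (1, 0), (1, 1)]:
            g = LatentGenotype(
                {"f": (1, 1), "m": (1, 1)}, {"c1": OffspringState(kf, km, 0, 0)}
            )
            assert log_prior_latent(g, self.cfg) == pytest.approx(base)

    def test_allele_beyond_support_rejected(self):
        g = LatentGenotype({"f": (5, 1), "m": (1, 1)}, {})
        with pytest.raises(ValueError):
            log_prior_latent(g, self.cfg)


def brute_force_posterior(fam, cfg, sigma):
    """Independent slow oracle: ordered allele tuples x explicit indicator
    products, combined through the elementary model functions."""
    A = cfg.max_allele
    logs, tags = [], []
    for af in product(range(A + 1), repeat=2):
        for am in product(range(A + 1), repeat=2):
            for combos in product(
                product((0, 1), repeat=4), repeat=len(fam.offspring)
            ):
                if any(
                    kf * min(af) + (1 - kf) * max(af)
                    + km * min(am) + (1 - km) * max(am) + ti - td < 0
                    for kf, km, ti, td in combos
                ):
                    continue  # excluded state: raw copy number below zero
                states = {
                    oid: OffspringState(*c)
                    for (oid, _), c in zip(fam.offspring, combos)
                }
                lp = log_prior_latent(LatentGenotype({"f": af, "m": am}, states), cfg)
                lp += log_likelihood_measurements(fam.father_reps, sum(af), sigma)
                lp += log_likelihood_measurements(fam.mother_reps, sum(am), sigma)
                for (oid, reps), c in zip(fam.offspring, combos):
                    lp += log_likelihood_measurements(
                        reps, compose_offspring_cn(af, am, *c), sigma
                    )
                logs.append(lp)
                tags.append(combos)
    logs = np.array(logs)
    w = np.exp(logs - logs.max())
    w /= w.sum()
    out = {}
    for j, (oid, _) in enumerate(fam.offspring):
        out[oid] = {
            "p_ins": float(sum(wi for wi, c in zip(w, tags) if c[j][2] == 1)),
            "p_del": float(sum(wi for wi, c in zip(w, tags) if c[j][3] == 1)),
        }
    return out


class TestEnumeration:
    def test_agrees_with_brute_force(self):
        cfg = ModelConfig(mutation_prior=0.01, max_allele=2, sigma_mode="fixed",
                          sigma_fixed=0.2)
        fam = FamilyData(
            "f",
            np.array([2.1, 1.9]),
            np.array([2.0, 2.2]),
            [("c1", np.array([2.8, 3.1])), ("c2", np.array([1.2, 0.9]))],
        )
        post = enumerate_family_posterior(fam, cfg)
        brute = brute_force_posterior(fam, cfg, 0.2)
        for oid in ("c1", "c2"):
            assert post.p_ins[oid] == pytest.approx(brute[oid]["p_ins"], abs=1e-12)
            assert post.p_del[oid] == pytest.approx(brute[oid]["p_del"], abs=1e-12)

    def test_gain_family_posterior(self):
        # A clean de novo gain: child at 3, everyone else at 2.  The gain
        # indicator competes with the equally-weighted inherited route
        # (a parent with haplotypes {0,2} transmitting the 2), so its
        # posterior sits near one half rather than near one -- but it
        # dominates the deletion indicator by an order of magnitude.
        cfg = ModelConfig(mutation_prior=0.005, **FIXED)
        post = enumerate_family_posterior(two_kid_family((3.0, 3.0)), cfg)
        assert 0.4 < post.p_ins["c1"] < 0.65
        assert post.p_ins["c1"] > 8 * post.p_del["c1"]
        assert post.cn_pmf["c1"][3] > 0.99

    def test_null_family(self):
        cfg = ModelConfig(mutation_prior=0.005, **FIXED)
        post = enumerate_family_posterior(two_kid_family((2.0, 2.0)), cfg)
        for oid in ("c1", "c2"):
            assert post.p_gain[oid] < 0.01
            assert post.p_loss[oid] < 0.01

    def test_normalization_and_mean_identity(self):
        cfg = ModelConfig(mutation_prior=0.005, **FIXED)
        post = enumerate_family_posterior(two_kid_family((2.4, 2.6)), cfg)
        for oid, pmf in post.cn_pmf.items():
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
            assert post.mean_cn[oid] == pytest.approx(
                float(pmf @ post.cn_grid), abs=1e-12
            )

    def test_parent_swap_symmetry(self):
        cfg = ModelConfig(mutation_prior=0.005, **FIXED)
        f1 = FamilyData("f", np.array([2.2, 2.1]), np.array([1.8, 2.0]),
                        [("c1", np.array([2.9, 3.0]))])
        f2 = FamilyData("f", np.array([1.8, 2.0]), np.array([2.2, 2.1]),
                        [("c1", np.array([2.9, 3.0]))])
        p1 = enumerate_family_posterior(f1, cfg)
        p2 = enumerate_family_posterior(f2, cfg)
        assert p1.p_ins["c1"] == pytest.approx(p2.p_ins["c1"], abs=1e-12)
        np.testing.assert_allclose(p1.cn_pmf["c1"], p2.cn_pmf["c1"], atol=1e-12)

    @pytest.mark.parametrize("mut", [1e-2, 1e-3, 1e-4])
    def test_mutation_posterior_vanishes_with_prior(self, mut):
        cfg = ModelConfig(mutation_prior=mut, **FIXED)
        post = enumerate_family_posterior(two_kid_family((2.0, 2.0)), cfg)
        total = post.p_ins["c1"] + post.p_del["c1"]
        cfg10 = ModelConfig(mutation_prior=mut / 10, **FIXED)
        post10 = enumerate_family_posterior(two_kid_family((2.0, 2.0)), cfg10)
        assert post10.p_ins["c1"] + post10.p_del["c1"] < total
        assert total < 10 * mut  # vanishes linearly with the prior

    def test_small_sigma_concentrates_on_integers(self):
        cfg = ModelConfig(mutation_prior=0.005, sigma_mode="fixed", sigma_fixed=0.02)
        fam = two_kid_family((3.0, 3.0), (1.0, 1.0))
        post = enumerate_family_posterior(fam, cfg)
        assert post.cn_pmf["c1"][3] > 0.999
        assert post.cn_pmf["c2"][1] > 0.999
        assert post.cn_pmf["father"][2] > 0.999

    def test_gain_loss_symmetry(self):
        cfg = ModelConfig(mutation_prior=0.005, **FIXED)
        up = enumerate_family_posterior(two_kid_family((2.4, 2.4)), cfg)
        down = enumerate_family_posterior(two_kid_family((1.6, 1.6)), cfg)
        assert up.p_ins["c1"] == pytest.approx(down.p_del["c1"], abs=1e-9)
        assert up.p_del["c1"] == pytest.approx(down.p_ins["c1"], abs=1e-9)

    def test_missing_parent_still_analyzable(self):
        cfg = ModelConfig(mutation_prior=0.005, **FIXED)
        fam = FamilyData(
            "f", np.empty(0), np.array([2.0, 2.0]),
            [("c1", np.array([2.0, 2.1]))], father_id=None,
        )
        post = enumerate_family_posterior(fam, cfg)
        assert post.cn_pmf["c1"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_sigma_grid_marginalization(self):
        cfg = ModelConfig(mutation_prior=0.005)  # default: sigma grid
        post = enumerate_family_posterior(two_kid_family((3.0, 3.1)), cfg)
        grid, weights = post.sigma_posterior
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)
        # posterior mass on sigma should sit near the empirical spread
        assert grid[np.argmax(weights)] < 0.3


class TestCollapse:
    @pytest.mark.parametrize(
        "cns,expected",
        [((2, 2, 2), 0), ((2, 3, 2), 1), ((1, 3, 2), 1), ((2,), 0), ((3,), 1)],
    )
    def test_examples(self, cns, expected):
        assert collapse_variants(np.array(cns)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            collapse_variants(np.array([]))

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=5))
    def test_zero_iff_all_two(self, cns):
        assert collapse_variants(np.array(cns)) == int(any(c != 2 for c in cns))
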
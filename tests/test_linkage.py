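"""Multipoint engine: HMM oracles, S_all, Kong-Cox, parametric, wiping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from sibscan.linkage import (FamilyClass, ParametricModel, affection_weights, build_loci,
                             class_emissions, detect_and_wipe_errors,
                             fit_disease_allele_freq, forward_backward,
                             hlod_curve, inheritance_posteriors, linkage_scan,
                             maximize_kong_cox)
from sibscan.panel import MarkerPanel, simulate_panel
from sibscan.pedio import Cohort, Sibship
from sibscan.simulate import degrade, simulate_cohort
from sibscan.util import haldane_theta
from tests.conftest import toy_panel


def sibpair_class():
    cls = FamilyClass(np.array([[0, 1], [0, 1]]), 2)
    cls.rows = np.array([[0, 1]])
    return cls


def brute_posterior(cls, E, cm):
    """Exhaustive enumeration over inheritance-vector paths."""
    T, V = E.shape
    theta = haldane_theta(np.diff(cm))
    n_bits = cls.n_bits

    def trans(u, v, th):
        d = bin(u ^ v).count("1")
        return (th ** d) * ((1 - th) ** (n_bits - d))

    post = np.zeros((T, V))
    total = 0.0
    for path in itertools.product(range(V), repeat=T):
        p = E[0, path[0]] / V
        for t in range(1, T):
            p *= trans(path[t - 1], path[t], theta[t - 1]) * E[t, path[t]]
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


class TestSall:
    def test_sibpair_values(self):
        """S_all on a sibpair is exactly 1 / 1.25 / 1.5 at IBD 0 / 1 / 2."""
        cls = sibpair_class()
        assert cls.sall[0b1100] == 1.0      # kids from opposite haplotypes
        assert cls.sall[0b1000] == 1.25     # shared paternal meiosis only
        assert cls.sall[0b0000] == 1.5      # identical meioses: IBD 2
        assert set(np.round(cls.sall, 10)) == {1.0, 1.25, 1.5}

    def test_sibpair_null_moments(self):
        cls = sibpair_class()
        assert cls.mu == pytest.approx(1.25)
        assert cls.sigma == pytest.approx(np.sqrt(0.03125))
        assert np.allclose(cls.null_mass, [0.25, 0.5, 0.25])

    def test_public_wrapper(self):
        sib = Sibship("f", ["a", "b"], np.array([0, 1]), ["p", "m"],
                      np.array([[0, 1], [0, 1]]))
        from sibscan.linkage import sall
        assert sall(sib, 0) == 1.5

    def test_halfsib_pair_scores_lower(self):
        """Half sibs share one parent: maximal S_all is below full-sib 1.5."""
        cls = FamilyClass(np.array([[0, 1], [2, 1]]), 3)
        assert cls.sall.max() == 1.25
        assert cls.sigma > 0


class TestPosteriors:
    @pytest.mark.parametrize("structure,n_founders", [
        ([[0, 1], [0, 1]], 2),              # full sibpair
        ([[0, 1], [0, 1], [0, 1]], 2),      # trio
        ([[0, 1], [2, 1]], 3),              # half-sib pair
    ])
    def test_hmm_matches_enumeration(self, structure, n_founders):
        rng = np.random.default_rng(17)
        panel = simulate_panel(3, [50.0], maf_mean=0.4, seed=5)
        loci = build_loci(panel)
        cls = FamilyClass(np.array(structure), n_founders)
        cls.rows = np.array([list(range(len(structure)))])
        genos = rng.integers(0, 3, size=(len(structure), 3)).astype(np.int8)
        genos[0, 1] = -1
        E = class_emissions(cls, genos, loci)
        cm = np.array([L.cm for L in loci])
        post, *_ = forward_backward(E, cm, cls.n_bits)
        expected = brute_posterior(cls, E[0].copy(), cm)
        assert np.abs(post[0] - expected).max() < 1e-9

    def test_uninformative_gives_null_ibd_prior(self, small_panel):
        genos = np.full((2, small_panel.n_markers), -1, dtype=np.int8)
        sib = Sibship("f", ["a", "b"], np.array([0, 1]), ["p", "m"],
                      np.array([[0, 1], [0, 1]]))
        out = inheritance_posteriors(sib, genos, build_loci(small_panel))
        cm, post = out[1]
        assert np.allclose(post, 1 / 16)
        # IBD distribution: (1/4, 1/2, 1/4)
        cls = sibpair_class()
        ibd2 = post[0] @ (cls.sall == 1.5)
        ibd1 = post[0] @ (cls.sall == 1.25)
        assert (ibd2, ibd1) == pytest.approx((0.25, 0.5))

    def test_fully_informative_marker_matches_founder_enumeration(self):
        """Both sibs identical heterozygotes at a 4-allele marker."""
        from sibscan.linkage import _emission_pass
        cls = sibpair_class()
        freqs = np.full(4, 0.25)
        C = np.zeros((1, 1, 2, 4, 4))
        for a in range(4):
            for b in range(4):
                C[0, 0, :, a, b] = 1.0 if {a, b} == {0, 1} else 0.0
        post = _emission_pass(cls, freqs[None, :], C)[0, 0]
        post = post / post.sum()
        oracle = np.zeros(16)
        for v in range(16):
            for combo in itertools.product(range(4), repeat=4):
                ok = all({combo[cls.SP[v, c]], combo[cls.SM[v, c]]} == {0, 1}
                         for c in range(2))
                oracle[v] += 0.25 ** 4 if ok else 0.0
        oracle /= oracle.sum()
        assert np.abs(post - oracle).max() < 1e-12

    def test_duplicate_marker_at_same_position_is_redundant(self):
        """Inserting a copy of a marker at the same cM leaves posteriors
        unchanged (zero recombination -> no extra information)."""
        rng = np.random.default_rng(23)
        base = toy_panel([10.0, 20.0, 30.0], freqs=[0.4, 0.5, 0.6])
        dup_df = pd.concat([
            base.markers,
            base.markers.iloc[[1]].assign(marker="m2dup"),
        ]).sort_values("cm", kind="stable").reset_index(drop=True)
        dup = MarkerPanel(dup_df)
        genos = rng.integers(0, 3, size=(2, 3)).astype(np.int8)
        genos_dup = np.column_stack([genos[:, 0], genos[:, 1], genos[:, 1],
                                     genos[:, 2]]).astype(np.int8)
        sib = Sibship("f", ["a", "b"], np.array([0, 1]), ["p", "m"],
                      np.array([[0, 1], [0, 1]]))
        p1 = inheritance_posteriors(sib, genos, build_loci(base))[1][1]
        p2 = inheritance_posteriors(sib, genos_dup, build_loci(dup))[1][1]
        assert np.abs(p1[0] - p2[0]).max() < 1e-9      # first marker
        assert np.abs(p1[2] - p2[3]).max() < 1e-9      # last marker

    def test_posteriors_normalized(self, null_cohort):
        sib = null_cohort.sibships()[0]
        out = inheritance_posteriors(sib, null_cohort.genotypes,
                                     build_loci(null_cohort.panel))
        for cm, post in out.values():
            assert np.abs(post.sum(axis=1) - 1).max() < 1e-9


class TestKongCox:
    def test_null_posteriors_give_zero(self):
        cls = sibpair_class()
        mass = np.tile(cls.null_mass, (3, 5, 1))       # 3 families, 5 positions
        lod, delta = maximize_kong_cox([(mass, cls.z_unique, cls.null_mass)])
        assert np.allclose(lod, 0.0) and np.allclose(delta, 0.0)

    def test_single_family_matches_grid_oracle(self):
        cls = sibpair_class()
        for target in (0, 1, 2):                       # IBD state
            mass = np.zeros((1, 1, 3))
            mass[0, 0, target] = 1.0
            lod, delta = maximize_kong_cox([(mass, cls.z_unique, cls.null_mass)])

            def neg(d):
                ez = np.exp(d * cls.z_unique)
                return -(np.log10(ez[target]) - np.log10(cls.null_mass @ ez))

            res = minimize_scalar(neg, bounds=(0, 3), method="bounded",
                                  options={"xatol": 1e-10})
            assert lod[0] == pytest.approx(max(0.0, -res.fun), abs=1e-5)

    def test_additivity_at_fixed_delta(self):
        from sibscan.linkage import _kc_loglik
        rng = np.random.default_rng(3)
        cls = sibpair_class()
        m1 = rng.dirichlet(np.ones(3), size=(4, 6))
        m2 = rng.dirichlet(np.ones(3), size=(2, 6))
        d = np.full(6, 0.7)
        both = _kc_loglik([(m1, cls.z_unique, cls.null_mass),
                           (m2, cls.z_unique, cls.null_mass)], d)
        sep = (_kc_loglik([(m1, cls.z_unique, cls.null_mass)], d)
               + _kc_loglik([(m2, cls.z_unique, cls.null_mass)], d))
        assert np.allclose(both, sep)

    def test_one_sided_on_sharing_deficit(self):
        cls = sibpair_class()
        mass = np.zeros((1, 4, 3))
        mass[0, :, 0] = 1.0                            # all mass on IBD 0
        lod, delta = maximize_kong_cox([(mass, cls.z_unique, cls.null_mass)])
        assert np.allclose(lod, 0.0) and np.allclose(delta, 0.0)
        # signed diagnostic version recovers the deficit
        lod_s, delta_s = maximize_kong_cox(
            [(mass, cls.z_unique, cls.null_mass)], delta_min=-3.0)
        assert (delta_s < 0).all()

    def test_allele_label_invariance(self, null_cohort):
        df = null_cohort.panel.markers.copy()
        flip = [3, 7, 11]
        df.loc[flip, "freq"] = 1.0 - df.loc[flip, "freq"]
        panel2 = MarkerPanel(df)
        genos2 = null_cohort.genotypes.copy()
        for j in flip:
            obs = genos2[:, j] >= 0
            genos2[obs, j] = 2 - genos2[obs, j]
        coh2 = Cohort(null_cohort.subjects, genos2, panel2)
        a = linkage_scan(null_cohort)
        b = linkage_scan(coh2)
        assert np.allclose(a["lod"], b["lod"], atol=1e-9)
        assert np.allclose(a["zmean"], b["zmean"], atol=1e-9)


class TestParametric:
    def test_disease_allele_freq_dominant(self):
        assert fit_disease_allele_freq(0.05, "dominant") == pytest.approx(
            0.022875, abs=1e-5)

    def test_disease_allele_freq_recessive(self):
        assert fit_disease_allele_freq(0.05, "recessive") == pytest.approx(
            0.212664, abs=1e-5)

    def test_prevalence_identity_plugback(self):
        for mode in ("dominant", "recessive"):
            for K in (0.002, 0.01, 0.05, 0.2):
                model = ParametricModel(mode, K)
                p_sus = (1 - (1 - model.q) ** 2 if mode == "dominant"
                         else model.q ** 2)
                implied = p_sus + (1 - p_sus) * K / 10
                assert implied == pytest.approx(K, abs=1e-12)

    def test_small_prevalence_limit(self):
        for mode in ("dominant", "recessive"):
            assert fit_disease_allele_freq(1e-8, mode) < 1e-3

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            fit_disease_allele_freq(0.0, "dominant")
        with pytest.raises(ValueError):
            ParametricModel("dominant", 1.5)

    def test_hlod_alpha_identities(self):
        rng = np.random.default_rng(9)
        fam = rng.normal(0, 0.4, size=(6, 8))
        hlod, alpha = hlod_curve(fam)
        plod = fam.sum(axis=0)
        # hLOD >= max(0, parametric LOD); equality when alpha-hat = 1
        assert (hlod >= np.maximum(plod, 0.0) - 1e-9).all()
        at_one = alpha >= 1.0 - 1e-9
        assert np.allclose(hlod[at_one], plod[at_one], atol=1e-9)
        # alpha = 0 contributes log10(1) = 0 for any data
        lr = np.power(10.0, fam)
        assert np.allclose(np.log10(0.0 * lr + 1.0).sum(axis=0), 0.0)

    def test_hlod_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(11)
        fam = rng.normal(0, 0.5, size=(5, 6))
        hlod, _ = hlod_curve(fam)
        alphas = np.linspace(0, 1, 20001)
        lr = np.power(10.0, fam)
        oracle = np.max(
            np.log10(alphas[:, None, None] * lr[None] + 1 - alphas[:, None, None]
                     ).sum(axis=1), axis=0)
        oracle = np.maximum(oracle, 0.0)
        assert np.allclose(hlod, oracle, atol=2e-4)

    def test_affection_weights_favor_sharing_under_recessive(self):
        cls = sibpair_class()
        w = affection_weights(cls, ParametricModel("recessive", 0.01))
        # IBD2 vectors must carry the largest affected-sibs likelihood
        assert w[0b0000] == pytest.approx(w.max(), rel=1e-12)
        assert w[0b1100] == pytest.approx(w.min(), rel=1e-12)
        assert w.max() / w.min() > 10


class TestScanBehavior:
    def test_scan_is_deterministic(self, null_cohort):
        a = linkage_scan(null_cohort, prevalence=0.05)
        b = linkage_scan(null_cohort, prevalence=0.05)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_freq_mode_close_to_panel_mode(self, null_cohort):
        a = linkage_scan(null_cohort)
        b = linkage_scan(null_cohort, sample_freqs=True)
        assert np.abs(a["lod"] - b["lod"]).max() < 1.0

    def test_all_families_uninformative_lod_zero(self, small_panel):
        coh = simulate_cohort(small_panel, 10, seed=3)
        coh = Cohort(coh.subjects,
                     np.full_like(coh.genotypes, -1), small_panel)
        df = linkage_scan(coh)
        assert np.allclose(df["lod"], 0.0)


class TestErrorWiping:
    """Error detection against flanking evidence.

    The evidence for a bad call is the double-recombination penalty of
    keeping it; with a 0.99 posterior flag threshold, strong evidence
    needs a dense map and informative sibships, so the sensitivity
    experiment uses a 0.25-cM map of high-MAF SNPs in quintet sibships.
    """

    def _dense_cohort(self, seed, n_sibships=20, size=5):
        panel = simulate_panel(30, [29 * 0.25], maf_mean=0.5, seed=41)
        return simulate_cohort(panel, n_sibships, size_dist={size: 1.0},
                               seed=seed, half_sib_fraction=0.0)

    @staticmethod
    def _family_marker_events(cohort, call_events):
        sib_of = {}
        for s in cohort.sibships():
            for r in s.rows:
                sib_of[int(r)] = s.sid
        return {(sib_of[int(r)], int(m)) for r, m in call_events}

    def test_clean_data_rarely_wiped(self):
        coh = self._dense_cohort(seed=51)
        cleaned, wiped = detect_and_wipe_errors(coh)
        assert len(wiped) / coh.genotypes.size < 0.001

    def test_planted_errors_detected(self):
        """>50% of planted substitution errors are flagged at the marker
        where they sit (localization within the family may differ)."""
        coh = self._dense_cohort(seed=52)
        noisy, _, err_mask = degrade(coh.genotypes, 0.0, 0.01, seed=53,
                                     return_truth=True)
        noisy_coh = Cohort(coh.subjects, noisy, coh.panel)
        cleaned, wiped = detect_and_wipe_errors(noisy_coh)
        planted = self._family_marker_events(coh, zip(*np.nonzero(err_mask)))
        found = self._family_marker_events(
            coh, zip(wiped["iid_row"], wiped["marker_index"]))
        assert planted, "degrade should have planted errors"
        recall = len(planted & found) / len(planted)
        assert recall > 0.5
        # spurious family-marker wipes stay rare
        assert len(found - planted) <= max(2, len(planted) // 5)

    def test_single_double_recombinant_flagged(self):
        """One planted error forcing two recombinations within ~2 cM is
        flagged and wiped."""
        coh = self._dense_cohort(seed=52)
        noisy = degrade(coh.genotypes, 0.0, 0.01, seed=53)
        single = coh.genotypes.copy()
        single[9, 14] = noisy[9, 14]            # one substituted call
        assert single[9, 14] != coh.genotypes[9, 14]
        cleaned, wiped = detect_and_wipe_errors(
            Cohort(coh.subjects, single, coh.panel))
        assert 14 in set(wiped["marker_index"])
        assert cleaned.genotypes[9, 14] == -1

    def test_wiping_idempotent(self):
        coh = self._dense_cohort(seed=54)
        noisy = degrade(coh.genotypes, 0.0, 0.01, seed=55)
        noisy_coh = Cohort(coh.subjects, noisy, coh.panel)
        cleaned, wiped1 = detect_and_wipe_errors(noisy_coh)
        again, wiped2 = detect_and_wipe_errors(cleaned)
        assert len(wiped2) == 0
        assert np.array_equal(cleaned.genotypes, again.genotypes)
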
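"""Pairwise and community association statistics against independent oracles."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from camtrapnet.association import (
    CHI2_P01,
    CHI2_P05,
    ContingencyTable,
    association_sign,
    classify_chi2,
    contingency,
    gk_lambda,
    pairwise_association_table,
    phi,
    variance_ratio,
    yates_chi2,
)
from camtrapnet.detections import SiteSpeciesMatrix
from camtrapnet.simulate import CommunitySpec, SpeciesSpec, build_latent_corr, simulate_presence


def random_tables(rng, n_tables, low=1, high=40):
    for _ in range(n_tables):
        yield ContingencyTable(*(int(x) for x in rng.integers(low, high, size=4)))


class TestContingency:
    def test_enumeration(self):
        pa = [True, True, False, False]
        pb = [False, True, True, False]
        t = contingency(pa, pb)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_identical_vectors_have_no_mismatch_cells(self):
        v = [True, False, True]
        t = contingency(v, v)
        assert t.b == t.c == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency([True], [True, False])


class TestPhi:
    def test_perfect_positive(self):
        assert phi(ContingencyTable(5, 0, 0, 5)) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert phi(ContingencyTable(0, 5, 5, 0)) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert phi(ContingencyTable(30, 20, 5, 12)) == pytest.approx(0.2665, abs=1e-4)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            phi(ContingencyTable(5, 5, 0, 0))

    def test_phi_squared_times_n_is_uncorrected_chi2(self, rng):
        for t in random_tables(rng, 200):
            expected = chi2_contingency(
                [[t.a, t.b], [t.c, t.d]], correction=False
            ).statistic
            assert phi(t) ** 2 * t.n == pytest.approx(expected, abs=1e-9)


class TestYatesChi2:
    def test_null_table_clamps_to_zero(self):
        assert yates_chi2(ContingencyTable(10, 10, 10, 10)) == 0.0

    def test_hand_computed(self):
        assert yates_chi2(ContingencyTable(20, 5, 5, 20)) == pytest.approx(15.68)

    def test_boundary_cross_product_equal_half_n(self):
        # a=2,b=1,c=1,d=2: |ad-bc| = 3 = n/2 exactly
        assert yates_chi2(ContingencyTable(2, 1, 1, 2)) == 0.0

    def test_matches_scipy_continuity_corrected_test(self, rng):
        for t in random_tables(rng, 200):
            expected = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True).statistic
            assert yates_chi2(t) == pytest.approx(float(expected), abs=1e-9)

    def test_sign_from_cross_product(self):
        assert association_sign(ContingencyTable(20, 5, 5, 20)) == "positive"
        assert association_sign(ContingencyTable(5, 20, 20, 5)) == "negative"
        assert association_sign(ContingencyTable(4, 2, 2, 1)) == "independent"


class TestClassify:
    @pytest.mark.parametrize(
        "chi2,expected",
        [
            (2.0, "none"),
            (5.0, "significant"),
            (25.32, "highly_significant"),
            (CHI2_P05, "none"),  # boundary assigned to the lower class
            (CHI2_P01, "significant"),
        ],
    )
    def test_classes(self, chi2, expected):
        assert classify_chi2(chi2) == expected


def literal_variance_ratio(presence):
    """Two-pass textbook restatement of Schluter's ratio."""
    P = np.asarray(presence, dtype=float)
    N, S = P.shape
    p = [P[:, i].sum() / N for i in range(S)]
    T = [P[j, :].sum() for j in range(N)]
    t_bar = sum(T) / N
    sT2 = sum((tj - t_bar) ** 2 for tj in T) / N
    denom = sum(pi * (1 - pi) for pi in p)
    return sT2 / denom


class TestVarianceRatio:
    def test_perfect_co_occurrence_doubles_the_ratio(self):
        P = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=bool)
        assert variance_ratio(P).vr == pytest.approx(2.0)

    def test_mutual_exclusion_zeroes_the_ratio(self):
        P = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=bool)
        assert variance_ratio(P).vr == pytest.approx(0.0)

    def test_w_is_vr_times_n_and_band_is_chi2(self):
        P = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=bool)
        res = variance_ratio(P)
        assert res.w == pytest.approx(res.vr * 4)
        assert res.df == 4
        assert res.band[0] < res.band[1]

    def test_df_override(self):
        P = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=bool)
        assert variance_ratio(P, df=60).df == 60

    def test_matches_literal_reimplementation(self, rng):
        for _ in range(50):
            P = rng.random((10, 5)) < rng.uniform(0.2, 0.8)
            if P.all(axis=0).all() or (~P).all(axis=0).all():
                continue
            ok_cols = ~(P.all(axis=0) | (~P).all(axis=0))
            if ok_cols.sum() == 0:
                continue
            res = variance_ratio(P)
            assert res.vr == pytest.approx(literal_variance_ratio(P), rel=1e-12)
            assert res.vr >= 0

    def test_degenerate_matrix_rejected(self):
        P = np.ones((4, 3), dtype=bool)
        with pytest.raises(ValueError):
            variance_ratio(P)


def brute_force_lambda(a, b, c, d):
    """PRE by enumerating modal predictions of B's state from A's state."""
    n = a + b + c + d
    errors_without = n - max(a + c, b + d)
    errors_with = (a + b - max(a, b)) + (c + d - max(c, d))
    return (errors_without - errors_with) / errors_without


class TestGkLambda:
    def test_perfect_prediction(self):
        assert gk_lambda(ContingencyTable(5, 0, 0, 5)).lam == pytest.approx(1.0)

    def test_no_error_reduction(self):
        assert gk_lambda(ContingencyTable(5, 5, 5, 5)).lam == pytest.approx(0.0)

    def test_matches_brute_force_pre(self):
        t = ContingencyTable(30, 20, 5, 12)
        assert gk_lambda(t).lam == pytest.approx(brute_force_lambda(30, 20, 5, 12))

    def test_asymmetry(self):
        t = ContingencyTable(30, 20, 2, 15)
        ab = gk_lambda(t, predictor="A", predicted="B")
        ba = gk_lambda(t, predictor="B", predicted="A")
        assert ab.lam != pytest.approx(ba.lam)
        assert 0 <= ab.lam <= 1 and 0 <= ba.lam <= 1

    def test_bootstrap_interval_brackets_the_point_estimate(self, rng):
        for t in random_tables(rng, 20, low=2, high=30):
            try:
                la = gk_lambda(t, n_boot=300, seed=rng)
            except ValueError:
                continue
            assert la.lambda_bo <= la.lam <= la.l_b

    def test_undefined_when_predicted_margin_saturates(self):
        with pytest.raises(ValueError):
            gk_lambda(ContingencyTable(3, 0, 4, 0))  # B present everywhere

    def test_seed_determinism(self):
        t = ContingencyTable(30, 20, 5, 12)
        r1 = gk_lambda(t, seed=7)
        r2 = gk_lambda(t, seed=7)
        assert (r1.l_b, r1.lambda_bo) == (r2.l_b, r2.lambda_bo)


class TestPhiParameterRecovery:
    @pytest.mark.parametrize("phi_target", [-0.4, 0.0, 0.4])
    def test_mean_estimated_phi_tracks_target_at_r200(self, phi_target):
        species = [SpeciesSpec("A", 0.5), SpeciesSpec("B", 0.5)]
        R = build_latent_corr(species, {("A", "B"): {"phi": phi_target}} if phi_target else None)
        spec = CommunitySpec(n_sites=200, species=species, latent_corr=R)
        rng = np.random.default_rng(99)
        phis = []
        for _ in range(150):
            P = simulate_presence(spec, rng)
            phis.append(phi(contingency(P[:, 0], P[:, 1])))
        assert np.mean(phis) == pytest.approx(phi_target, abs=0.05)


class TestPairwiseTable:
    def test_all_pairs_reported_with_undefined_flagged(self):
        counts = np.array([[2, 1, 0], [1, 0, 0], [3, 2, 0]])
        m = SiteSpeciesMatrix(["x", "y", "z"], ["a", "b", "c"], counts)
        tab = pairwise_association_table(m)
        assert len(tab) == 3
        assert (tab["class"] == "undefined").sum() >= 1  # 'a' everywhere, 'c' nowhere
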
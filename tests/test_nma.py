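"""Network meta-analysis: model identities, ranking, intervals, diagnostics."""

import warnings

import numpy as np
import pytest

from exdose.effects import Contrast
from exdose.nma import (
    DisconnectedNetworkError,
    NmaPosterior,
    NmaSpec,
    NotSplittableError,
    adherence_network,
    classify_tau2,
    fit_consistency,
    fit_ume,
    league_table,
    network_meta_regression,
    node_split,
    prediction_interval,
    splittable_comparisons,
    sucra,
)
from exdose.pairwise import pool_pairwise
from exdose.simulate import generate_loop_contrasts

SMALL = NmaSpec(chains=2, draws=1000, warmup=500, seed=1)


def _c(md, se, sid, t="AT", r="UC"):
    return Contrast(study_id=sid, treatment=t, reference=r, md=md, se=se,
                    n_t=50, n_r=50)


def _fixed_posterior(d_draws: np.ndarray, treatments, tau=None) -> NmaPosterior:
    """Posterior stub with externally constructed draws."""
    nd = d_draws.shape[0]
    if tau is None:
        tau = np.zeros(nd)
    return NmaPosterior(
        model="consistency", reference="UC", treatments=list(treatments),
        param_names=[f"d[{t} vs UC]" for t in treatments],
        d=d_draws[None, :, :], tau=np.asarray(tau)[None, :],
        deviance=np.zeros((1, nd)), dic=0.0, pD=0.0, mean_deviance=0.0,
        resdev=np.zeros(1), rhat_max=1.0, ess_min=float(nd),
    )


class TestConsistencyModel:
    def test_disconnected_network_refused(self):
        cs = [_c(-0.2, 0.1, "S1", "AT", "RT"), _c(-0.1, 0.1, "S2", "CT", "UC")]
        with pytest.raises(DisconnectedNetworkError):
            fit_consistency(cs, SMALL)

    def test_all_zero_contrasts_centre_at_zero(self):
        cs = [_c(0.0, 0.1, f"S{i}", t) for i in range(4) for t in ("AT", "RT")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_consistency(cs, SMALL)
        for i in range(len(post.treatments)):
            assert abs(post.d_flat()[:, i].mean()) < 0.05

    def test_single_comparison_matches_pairwise_pool(self):
        cs = [_c(-0.35, 0.08, "S1"), _c(-0.25, 0.09, "S2"),
              _c(-0.30, 0.07, "S3"), _c(-0.28, 0.10, "S4")]
        pooled = pool_pairwise(cs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_consistency(cs, NmaSpec(chains=2, draws=2000, warmup=1000, seed=2))
        d = post.d_flat()[:, 0]
        mc_se = d.std() / np.sqrt(post.ess_min)
        assert abs(d.mean() - pooled.md) <= max(2 * mc_se, 0.02)

    def test_recovery_on_synthetic_network(self, small_network, nma_posterior):
        ledger = small_network["ledger"]
        post = nma_posterior
        dd = post.d_flat()
        for i, t in enumerate(post.treatments):
            lo, hi = np.quantile(dd[:, i], [0.025, 0.975])
            assert lo - 0.05 <= ledger.d_k[t] <= hi + 0.05

    def test_dic_decomposition(self, nma_posterior):
        post = nma_posterior
        assert post.dic == pytest.approx(post.mean_deviance + post.pD)
        assert post.pD > 0


class TestUme:
    def test_single_comparison_equals_consistency(self):
        cs = [_c(-0.35, 0.08, "S1"), _c(-0.25, 0.09, "S2"), _c(-0.3, 0.1, "S3")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_consistency(cs, SMALL)
            b = fit_ume(cs, SMALL)
        assert abs(a.d_flat().mean() - b.d_flat().mean()) < 0.02

    def test_consistent_network_shows_no_ume_preference(self, small_network):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cons = fit_consistency(small_network["contrasts"], SMALL)
            ume = fit_ume(small_network["contrasts"], SMALL)
        assert ume.dic - cons.dic >= -3.0

    def test_inconsistent_loop_prefers_ume(self):
        cs = generate_loop_contrasts(n_per_design=6, tau=0.02, gap=1.0, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cons = fit_consistency(cs, SMALL.__class__(
                reference="UC", chains=2, draws=1000, warmup=500, seed=5))
            ume = fit_ume(cs, NmaSpec(chains=2, draws=1000, warmup=500, seed=5))
        assert ume.dic < cons.dic


class TestNodeSplit:
    def test_star_network_not_splittable(self):
        cs = [_c(-0.2, 0.1, "S1", "AT"), _c(-0.3, 0.1, "S2", "RT")]
        assert splittable_comparisons(cs) == []
        with pytest.raises(NotSplittableError):
            node_split(cs, SMALL, ("AT", "UC"))

    def test_consistent_loop_keeps_large_p(self):
        cs = generate_loop_contrasts(n_per_design=5, n_per_arm=200, tau=0.05, seed=3)
        ns = node_split(cs, NmaSpec(chains=2, draws=1000, warmup=500, seed=3),
                        ("A", "B"))
        assert ns.p_value > 0.05

    def test_injected_gap_detected(self):
        cs = generate_loop_contrasts(n_per_design=5, tau=0.05, gap=0.8, seed=3)
        ns = node_split(cs, NmaSpec(chains=2, draws=1000, warmup=500, seed=3),
                        ("A", "B"))
        assert ns.p_value < 0.05
        assert abs(np.mean(ns.direct) - np.mean(ns.indirect)) > 0.3


class TestSucra:
    def test_dominant_treatment_scores_one(self):
        d = np.full((500, 1), -1.0)  # always better than reference
        scores = sucra(_fixed_posterior(d, ["AT"]))
        assert scores.sucra["AT"] == pytest.approx(1.0)
        assert scores.sucra["UC"] == pytest.approx(0.0)

    def test_exchangeable_treatments_near_half(self):
        rng = np.random.default_rng(0)
        d = rng.normal(-0.5, 0.2, size=(4000, 3))
        scores = sucra(_fixed_posterior(d, ["AT", "CT", "RT"]))
        for t in ("AT", "CT", "RT"):
            assert 0.45 < (scores.sucra[t] - 0) < 0.85  # exchangeable, above UC
        trio = [scores.sucra[t] for t in ("AT", "CT", "RT")]
        assert np.allclose(trio, np.mean(trio), atol=0.03)

    def test_deterministic_ordering_on_constructed_draws(self):
        d = np.tile([-0.5, -0.34, -0.28], (200, 1))  # HIIT < CT < AT every draw
        scores = sucra(_fixed_posterior(d, ["HIIT", "CT", "AT"]))
        assert (
            scores.sucra["HIIT"] > scores.sucra["CT"] > scores.sucra["AT"]
            > scores.sucra["UC"]
        )
        assert scores.sucra["HIIT"] == pytest.approx(1.0)

    def test_mean_sucra_is_exactly_half(self, nma_posterior):
        scores = sucra(nma_posterior)
        assert np.mean(list(scores.sucra.values())) == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(scores.rank_probabilities.sum(axis=1), 1.0)


class TestLeagueTable:
    def test_antisymmetry_and_reference_column(self, nma_posterior):
        lt = league_table(nma_posterior)
        assert np.allclose(lt.mean, -lt.mean.T)
        assert np.allclose(lt.cri_low, -lt.cri_high.T)
        # vs-reference column equals the basic parameters
        dd = nma_posterior.d_flat()
        for i, t in enumerate(nma_posterior.treatments):
            mean, lo, hi = lt.cell(t, "UC")
            assert mean == pytest.approx(dd[:, i].mean())

    def test_diagonal_carries_labels(self, nma_posterior):
        frame = league_table(nma_posterior).to_frame()
        for t in nma_posterior.nodes:
            assert frame.loc[t, t] == t


class TestPredictionInterval:
    def test_zero_tau_collapses_to_cri(self):
        rng = np.random.default_rng(1)
        d = rng.normal(-0.3, 0.05, size=(4000, 1))
        post = _fixed_posterior(d, ["AT"], tau=np.zeros(4000))
        pi = prediction_interval(post)
        row = pi[(pi.treatment == "AT") & (pi.reference == "UC")].iloc[0]
        assert row.pi_low == pytest.approx(row.cri_low, abs=1e-9)
        assert row.pi_high == pytest.approx(row.cri_high, abs=1e-9)

    def test_point_mass_with_fixed_tau_closed_form(self):
        n = 400_000
        d = np.full((n, 1), -0.3)
        post = _fixed_posterior(d, ["AT"], tau=np.full(n, 0.2))
        pi = prediction_interval(post, seed=0)
        row = pi[(pi.treatment == "AT") & (pi.reference == "UC")].iloc[0]
        assert row.pi_low == pytest.approx(-0.3 - 1.959964 * 0.2, abs=0.005)
        assert row.pi_high == pytest.approx(-0.3 + 1.959964 * 0.2, abs=0.005)

    def test_width_grows_with_tau_and_contains_cri(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-0.3, 0.05, size=(20000, 1))
        widths = []
        for tau in (0.05, 0.15, 0.3):
            post = _fixed_posterior(d, ["AT"], tau=np.full(20000, tau))
            row = prediction_interval(post).iloc[0]
            widths.append(row.pi_high - row.pi_low)
            assert row.pi_low <= row.cri_low and row.pi_high >= row.cri_high
        assert widths[0] < widths[1] < widths[2]


class TestTau2Bands:
    @pytest.mark.parametrize(
        "tau2, band",
        [(0.016, "low"), (0.039, "low"), (0.04, "low_moderate"),
         (0.10, "low_moderate"), (0.16, "low_moderate"),
         (0.36, "moderate_high"), (0.50, "high")],
    )
    def test_bands(self, tau2, band):
        assert classify_tau2(tau2) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_tau2(-0.01)


class TestMetaRegression:
    def test_constant_covariate_refused(self, small_network):
        cov = {c.study_id: 1.0 for c in small_network["contrasts"]}
        with pytest.raises(ValueError, match="zero variance"):
            network_meta_regression(small_network["contrasts"], cov, SMALL)

    def test_sparse_covariate_refused(self, small_network):
        cs = small_network["contrasts"]
        sids = sorted({c.study_id for c in cs})
        cov = {s: float(i) for i, s in enumerate(sids[: len(sids) // 2])}
        with pytest.raises(ValueError, match="covariate available"):
            network_meta_regression(cs, cov, SMALL)

    def test_null_covariate_interval_covers_zero(self, small_network):
        cs = small_network["contrasts"]
        rng = np.random.default_rng(11)
        cov = {s: float(rng.normal()) for s in {c.study_id for c in cs}}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = network_meta_regression(cs, cov, SMALL)
        s = post.extra["beta_summary"]
        assert s["cri_low"] <= 0.0 <= s["cri_high"]

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(21)
        beta_true = -0.1
        cs = []
        xs = {}
        for i in range(30):
            sid = f"S{i:02d}"
            x = float(rng.normal(4.0, 1.5))
            xs[sid] = x
            se = 0.06
            md = -0.3 + beta_true * (x - 4.0) + rng.normal(0, 0.05) + rng.normal(0, se)
            cs.append(_c(md, se, sid))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = network_meta_regression(cs, xs, NmaSpec(chains=2, draws=1500,
                                                           warmup=700, seed=21))
        b = post.beta.reshape(-1)
        assert abs(b.mean() - beta_true) <= 2 * b.std()


class TestAdherenceNetwork:
    def test_equal_completion_covers_one(self):
        import pandas as pd

        rows = []
        for i in range(6):
            rows.append({"study_id": f"S{i}", "modality": "AT", "events": 17, "total": 20})
            rows.append({"study_id": f"S{i}", "modality": "UC", "events": 17, "total": 20})
        res = adherence_network(
            pd.DataFrame(rows), NmaSpec(seed=4), n_steps=1200, n_burn=600
        )
        at = res[res.modality == "AT"].iloc[0]
        assert at.cri_low <= 1.0 <= at.cri_high

    def test_large_table_recovers_hand_odds_ratio(self):
        import pandas as pd

        df = pd.DataFrame(
            [
                {"study_id": "T1", "modality": "AT", "events": 360, "total": 400},
                {"study_id": "T1", "modality": "UC", "events": 300, "total": 400},
            ]
        )
        res = adherence_network(df, NmaSpec(seed=1), n_steps=1200, n_burn=600)
        at = res[res.modality == "AT"].iloc[0]
        assert at["or"] == pytest.approx(3.0, rel=0.15)
        uc = res[res.modality == "UC"].iloc[0]
        assert uc["or"] == 1.0
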
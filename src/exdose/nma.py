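"""Bayesian random-effects network meta-analysis on contrast-level data.

The consistency model places a normal likelihood on each observed mean
difference, ``md_i ~ N(delta_i, se_i^2)`` with the shared-arm sampling
covariance of multi-arm trials on the off-diagonals, and exchangeable
trial-specific effects ``delta_i ~ N(d_treat − d_ref, tau^2)`` with the
induced ``tau^2/2`` covariance between contrasts sharing an arm.  Basic
parameters d_k are effects versus the network reference (usual care) with
vague N(0, 10^2) priors on the % HbA1c scale; tau has a Half-Normal(0.5)
prior.  Fitting is by blocked Gibbs sampling (:mod:`exdose._gibbs`).

The same machinery provides the unrelated-mean-effects (inconsistency)
model, DIC/pD model comparison, node-splitting of direct versus indirect
evidence, SUCRA ranking, league tables, 95% prediction intervals, network
meta-regression with a shared interaction, and the binomial log-OR adherence
model (sampled with emcee).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import networkx as nx
import numpy as np
import pandas as pd

from ._gibbs import ContrastGibbs
from .effects import Contrast

__all__ = [
    "NmaSpec",
    "NmaPosterior",
    "NodeSplitResult",
    "SucraScores",
    "LeagueTable",
    "DisconnectedNetworkError",
    "NotSplittableError",
    "fit_consistency",
    "fit_ume",
    "node_split",
    "splittable_comparisons",
    "sucra",
    "league_table",
    "prediction_interval",
    "classify_tau2",
    "network_meta_regression",
    "adherence_network",
]


class DisconnectedNetworkError(ValueError):
    """The treatment network is disconnected; joint estimation is refused."""


class NotSplittableError(ValueError):
    """A comparison lacks direct trials or an independent indirect path."""


@dataclass(frozen=True)
class NmaSpec:
    """Priors, chain settings and reference treatment for the NMA."""

    reference: str = "UC"
    prior_sd: float = 10.0
    tau_prior_sd: float = 0.5
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    seed: int = 0


@dataclass
class NmaPosterior:
    model: str
    reference: str
    treatments: list[str]  # non-reference treatments, ordering of d columns
    param_names: list[str]
    d: np.ndarray  # (chains, draws, n_params)
    tau: np.ndarray  # (chains, draws)
    deviance: np.ndarray
    dic: float
    pD: float
    mean_deviance: float
    resdev: np.ndarray  # per-contrast residual deviance at the posterior mean
    rhat_max: float
    ess_min: float
    beta: np.ndarray | None = None  # meta-regression coefficient draws
    extra: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return [self.reference] + self.treatments

    def d_flat(self) -> np.ndarray:
        """Basic-parameter draws flattened across chains, (ndraws, K-1)."""
        return self.d.reshape(-1, self.d.shape[-1])

    def tau_flat(self) -> np.ndarray:
        return self.tau.reshape(-1)

    def basic_summary(self) -> pd.DataFrame:
        dd = self.d_flat()
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": dd.mean(axis=0),
                "cri_low": np.quantile(dd, 0.025, axis=0),
                "cri_high": np.quantile(dd, 0.975, axis=0),
            }
        )


@dataclass
class NodeSplitResult:
    comparison: tuple[str, str]
    direct: np.ndarray
    indirect: np.ndarray
    difference: np.ndarray
    p_value: float


@dataclass
class SucraScores:
    sucra: dict  # treatment -> score in [0, 1]
    rank_probabilities: pd.DataFrame  # rows treatments, cols rank 1..K

    def to_frame(self) -> pd.DataFrame:
        out = self.rank_probabilities.copy()
        out.insert(0, "sucra", [self.sucra[t] for t in out.index])
        return out


@dataclass
class LeagueTable:
    nodes: list[str]
    mean: np.ndarray
    cri_low: np.ndarray
    cri_high: np.ndarray

    def cell(self, row: str, col: str) -> tuple[float, float, float]:
        i, j = self.nodes.index(row), self.nodes.index(col)
        return self.mean[i, j], self.cri_low[i, j], self.cri_high[i, j]

    def to_frame(self) -> pd.DataFrame:
        k = len(self.nodes)
        cells = []
        for i in range(k):
            row = []
            for j in range(k):
                if i == j:
                    row.append(self.nodes[i])
                else:
                    row.append(
                        f"{self.mean[i, j]:.2f} "
                        f"({self.cri_low[i, j]:.2f}, {self.cri_high[i, j]:.2f})"
                    )
            cells.append(row)
        return pd.DataFrame(cells, index=self.nodes, columns=self.nodes)


# ---------------------------------------------------------------------------


def _check_connected(contrasts: list[Contrast]) -> None:
    g = nx.Graph()
    for c in contrasts:
        g.add_edge(c.treatment, c.reference)
    if g.number_of_nodes() and not nx.is_connected(g):
        raise DisconnectedNetworkError(
            "treatment network is disconnected; NMA refused"
        )


def _arrays(contrasts: list[Contrast]):
    y = np.array([c.md for c in contrasts])
    var = np.array([c.se**2 for c in contrasts])
    shared = np.array([c.ref_var for c in contrasts])
    trial = np.array([c.study_id for c in contrasts])
    return y, var, shared, trial


def _treatment_order(contrasts: list[Contrast], reference: str) -> list[str]:
    nodes = sorted({c.treatment for c in contrasts} | {c.reference for c in contrasts})
    if reference not in nodes:
        raise ValueError(f"reference {reference!r} absent from network")
    return [t for t in nodes if t != reference]


def _basic_design(contrasts, treatments, reference) -> np.ndarray:
    col = {t: i for i, t in enumerate(treatments)}
    X = np.zeros((len(contrasts), len(treatments)))
    for i, c in enumerate(contrasts):
        if c.treatment != reference:
            X[i, col[c.treatment]] += 1.0
        if c.reference != reference:
            X[i, col[c.reference]] -= 1.0
    return X


def _diagnostics(theta: np.ndarray, tau: np.ndarray) -> tuple[float, float]:
    data = az.from_dict(posterior={"d": theta, "tau": tau[..., None]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(data)
        ess = az.ess(data)
    rhat_max = float(
        max(rhat["d"].values.max(), rhat["tau"].values.max())
    )
    ess_min = float(min(ess["d"].values.min(), ess["tau"].values.min()))
    return rhat_max, ess_min


def _finalise(model, contrasts, X, names, spec, reference, treatments,
              beta_cols=0) -> NmaPosterior:
    y, var, shared, trial = _arrays(contrasts)
    sampler = ContrastGibbs(
        y, X, trial, var, shared,
        prior_sd=spec.prior_sd, tau_prior_sd=spec.tau_prior_sd,
    )
    res = sampler.run(
        chains=spec.chains, draws=spec.draws, warmup=spec.warmup, seed=spec.seed
    )
    theta = res["theta"]
    rhat_max, ess_min = _diagnostics(theta, res["tau"])
    if rhat_max > 1.01 or ess_min < 400:
        warnings.warn(
            f"MCMC convergence check: max split-Rhat {rhat_max:.3f}, "
            f"min ESS {ess_min:.0f} (thresholds 1.01 / 400); consider more draws",
            stacklevel=2,
        )
    resdev = (y - res["delta_bar"]) ** 2 / var
    beta = theta[:, :, -beta_cols:] if beta_cols else None
    d = theta[:, :, : theta.shape[-1] - beta_cols]
    return NmaPosterior(
        model=model,
        reference=reference,
        treatments=treatments,
        param_names=names[: len(names) - beta_cols],
        d=d,
        tau=res["tau"],
        deviance=res["deviance"],
        dic=res["dic"],
        pD=res["pD"],
        mean_deviance=res["dbar"],
        resdev=resdev,
        rhat_max=rhat_max,
        ess_min=ess_min,
        beta=beta,
    )


def fit_consistency(contrasts: list[Contrast], spec: NmaSpec = NmaSpec()) -> NmaPosterior:
    """Fit the consistency (full network) random-effects model."""
    _check_connected(contrasts)
    treatments = _treatment_order(contrasts, spec.reference)
    X = _basic_design(contrasts, treatments, spec.reference)
    names = [f"d[{t} vs {spec.reference}]" for t in treatments]
    return _finalise("consistency", contrasts, X, names, spec,
                     spec.reference, treatments)


def fit_ume(contrasts: list[Contrast], spec: NmaSpec = NmaSpec()) -> NmaPosterior:
    """Fit the unrelated-mean-effects model (independent design means).

    Each observed comparison pair gets its own mean with the same
    heterogeneity structure; its DIC is comparable with the consistency
    model's as a global inconsistency check.
    """
    _check_connected(contrasts)
    pairs: list[tuple[str, str]] = []
    for c in contrasts:
        key = (c.treatment, c.reference)
        canon = key if key[0] < key[1] else (key[1], key[0])
        if canon not in pairs:
            pairs.append(canon)
    pairs.sort()
    col = {p: i for i, p in enumerate(pairs)}
    X = np.zeros((len(contrasts), len(pairs)))
    for i, c in enumerate(contrasts):
        key = (c.treatment, c.reference)
        if key in col:
            X[i, col[key]] = 1.0
        else:
            X[i, col[(key[1], key[0])]] = -1.0
    names = [f"d[{a} vs {b}]" for a, b in pairs]
    post = _finalise("ume", contrasts, X, names, spec,
                     spec.reference, _treatment_order(contrasts, spec.reference))
    post.extra["pairs"] = pairs
    return post


def splittable_comparisons(contrasts: list[Contrast]) -> list[tuple[str, str]]:
    """Comparisons with both direct trials and an independent indirect path."""
    out = []
    g_all = nx.Graph()
    for c in contrasts:
        g_all.add_edge(c.treatment, c.reference)
    for a, b in sorted(map(tuple, map(sorted, g_all.edges()))):
        g = nx.Graph()
        g.add_nodes_from([a, b])
        for c in contrasts:
            if {c.treatment, c.reference} != {a, b}:
                g.add_edge(c.treatment, c.reference)
        if nx.has_path(g, a, b):
            out.append((a, b))
    return out


def node_split(
    contrasts: list[Contrast],
    spec: NmaSpec,
    comparison: tuple[str, str],
) -> NodeSplitResult:
    """Split one comparison's direct evidence from the rest of the network.

    Contrasts whose pair equals the split comparison load on a dedicated
    direct-effect parameter; the network estimate for the pair from the
    remaining evidence is the indirect effect.  The two-sided Bayesian
    p-value is ``2·min(P(diff>0), P(diff<0))`` over posterior draws.
    """
    a, b = comparison
    direct_rows = [i for i, c in enumerate(contrasts)
                   if {c.treatment, c.reference} == {a, b}]
    if not direct_rows:
        raise NotSplittableError(f"({a}, {b}): not splittable (no direct trials)")
    g = nx.Graph()
    g.add_nodes_from([a, b])
    for i, c in enumerate(contrasts):
        if i not in direct_rows:
            g.add_edge(c.treatment, c.reference)
    if not nx.has_path(g, a, b):
        raise NotSplittableError(f"({a}, {b}): not splittable (no indirect path)")
    _check_connected(contrasts)
    treatments = _treatment_order(contrasts, spec.reference)
    Xd = _basic_design(contrasts, treatments, spec.reference)
    n = len(contrasts)
    X = np.column_stack([Xd, np.zeros(n)])
    for i in direct_rows:
        X[i, :-1] = 0.0
        X[i, -1] = 1.0 if contrasts[i].treatment == a else -1.0
    names = [f"d[{t} vs {spec.reference}]" for t in treatments] + [
        f"direct[{a} vs {b}]"
    ]
    post = _finalise("nodesplit", contrasts, X, names, spec,
                     spec.reference, treatments, beta_cols=0)
    dd = post.d_flat()
    direct = dd[:, -1]
    col = {t: i for i, t in enumerate(treatments)}
    da = dd[:, col[a]] if a != spec.reference else 0.0
    db = dd[:, col[b]] if b != spec.reference else 0.0
    indirect = da - db
    diff = direct - indirect
    p = 2.0 * min(float(np.mean(diff > 0)), float(np.mean(diff < 0)))
    return NodeSplitResult(
        comparison=(a, b),
        direct=direct,
        indirect=np.broadcast_to(indirect, direct.shape).copy(),
        difference=np.asarray(diff),
        p_value=p,
    )


def sucra(posterior: NmaPosterior, lower_is_better: bool = True) -> SucraScores:
    """SUCRA scores and rank probabilities from the basic-parameter draws.

    The reference enters at effect 0.  Per draw, treatments are ranked (rank
    1 = best) and SUCRA is the mean of ``(K − rank)/(K − 1)``; across
    treatments SUCRA averages to exactly 0.5 per draw set.
    """
    if posterior.model != "consistency":
        raise ValueError("SUCRA is defined on the consistency model posterior")
    dd = posterior.d_flat()
    values = np.column_stack([np.zeros(dd.shape[0]), dd])
    if not lower_is_better:
        values = -values
    k = values.shape[1]
    order = values.argsort(axis=1, kind="stable")
    ranks = order.argsort(axis=1) + 1  # 1 = best (most negative effect)
    nodes = posterior.nodes
    sucra_scores = {
        t: float(np.mean((k - ranks[:, i]) / (k - 1))) for i, t in enumerate(nodes)
    }
    probs = np.stack(
        [(ranks == r).mean(axis=0) for r in range(1, k + 1)], axis=1
    )
    frame = pd.DataFrame(
        probs, index=nodes, columns=[f"rank_{r}" for r in range(1, k + 1)]
    )
    return SucraScores(sucra=sucra_scores, rank_probabilities=frame)


def league_table(posterior: NmaPosterior) -> LeagueTable:
    """All pairwise contrasts d_i − d_j with 95% credible intervals."""
    dd = posterior.d_flat()
    values = np.column_stack([np.zeros(dd.shape[0]), dd])
    diff = values[:, :, None] - values[:, None, :]
    return LeagueTable(
        nodes=posterior.nodes,
        mean=diff.mean(axis=0),
        cri_low=np.quantile(diff, 0.025, axis=0),
        cri_high=np.quantile(diff, 0.975, axis=0),
    )


def prediction_interval(posterior: NmaPosterior, seed: int = 0) -> pd.DataFrame:
    """95% prediction intervals for the effect in a new study, per contrast.

    Each posterior draw of a contrast is widened by N(0, tau) for that draw;
    percentiles of the widened draws give the interval.
    """
    rng = np.random.default_rng([int(seed) % 2**31, 101])
    dd = posterior.d_flat()
    tau = posterior.tau_flat()
    values = np.column_stack([np.zeros(dd.shape[0]), dd])
    nodes = posterior.nodes
    rows = []
    for i, t in enumerate(nodes):
        for j, r in enumerate(nodes):
            if i == j:
                continue
            diff = values[:, i] - values[:, j]
            pred = diff + tau * rng.standard_normal(diff.shape)
            rows.append(
                {
                    "treatment": t,
                    "reference": r,
                    "mean": float(diff.mean()),
                    "cri_low": float(np.quantile(diff, 0.025)),
                    "cri_high": float(np.quantile(diff, 0.975)),
                    "pi_low": float(np.quantile(pred, 0.025)),
                    "pi_high": float(np.quantile(pred, 0.975)),
                }
            )
    return pd.DataFrame(rows)


def classify_tau2(tau2: float) -> str:
    """Heterogeneity band for a between-study variance."""
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if tau2 < 0.04:
        return "low"
    if tau2 <= 0.16:
        return "low_moderate"
    if tau2 <= 0.36:
        return "moderate_high"
    return "high"


def network_meta_regression(
    contrasts: list[Contrast],
    covariate: dict,
    spec: NmaSpec = NmaSpec(),
    min_coverage: float = 0.8,
) -> NmaPosterior:
    """Shared-interaction network meta-regression on one study covariate.

    The mean of each vs-reference contrast is shifted by beta·(x_s − x̄);
    under the shared-interaction assumption the shift cancels in
    active-versus-active contrasts.
    """
    trials = {c.study_id for c in contrasts}
    have = {s for s in trials if covariate.get(s) is not None}
    if len(have) < min_coverage * len(trials):
        raise ValueError(
            f"covariate available for {len(have)}/{len(trials)} trials "
            f"(needs >= {min_coverage:.0%})"
        )
    kept = [c for c in contrasts if c.study_id in have]
    _check_connected(kept)
    xs = np.array([float(covariate[c.study_id]) for c in kept])
    if np.std(xs) == 0:
        raise ValueError("covariate has zero variance across trials")
    xc = xs - xs.mean()
    treatments = _treatment_order(kept, spec.reference)
    Xd = _basic_design(kept, treatments, spec.reference)
    sign = np.array(
        [
            (1.0 if c.reference == spec.reference else 0.0)
            - (1.0 if c.treatment == spec.reference else 0.0)
            for c in kept
        ]
    )
    X = np.column_stack([Xd, xc * sign])
    names = [f"d[{t} vs {spec.reference}]" for t in treatments] + ["beta"]
    post = _finalise("metareg", kept, X, names, spec,
                     spec.reference, treatments, beta_cols=1)
    b = post.beta.reshape(-1)
    post.extra["beta_summary"] = {
        "mean": float(b.mean()),
        "cri_low": float(np.quantile(b, 0.025)),
        "cri_high": float(np.quantile(b, 0.975)),
    }
    return post


# -- adherence (binomial logit) network ------------------------------------


def adherence_network(
    adherence: pd.DataFrame,
    spec: NmaSpec = NmaSpec(),
    n_steps: int = 2000,
    n_burn: int = 1000,
) -> pd.DataFrame:
    """Completion odds ratios versus the reference from a logit network model.

    Binomial likelihood per arm with a trial intercept and a treatment
    log-odds-ratio versus the reference; weakly informative normal priors
    (trial intercepts N(0, 3²), log-ORs N(0, 2²)) on the logit scale.
    Sampled with the emcee ensemble sampler.
    """
    df = adherence.copy()
    mods = sorted(df["modality"].unique())
    if spec.reference not in mods:
        raise ValueError(f"reference {spec.reference!r} absent from adherence data")
    active = [m for m in mods if m != spec.reference]
    studies = sorted(df["study_id"].unique())
    s_idx = df["study_id"].map({s: i for i, s in enumerate(studies)}).to_numpy()
    m_map = {m: i for i, m in enumerate(active)}
    m_idx = df["modality"].map(lambda m: m_map.get(m, -1)).to_numpy()
    events = df["events"].to_numpy(float)
    totals = df["total"].to_numpy(float)
    S, K = len(studies), len(active)
    ndim = S + K

    def log_prob(params: np.ndarray) -> np.ndarray:
        mu = params[:, :S]
        theta = np.concatenate(
            [params[:, S:], np.zeros((params.shape[0], 1))], axis=1
        )
        eta = mu[:, s_idx] + theta[:, m_idx]
        ll = np.sum(events * eta - totals * np.logaddexp(0.0, eta), axis=1)
        lp = -0.5 * np.sum((mu / 3.0) ** 2, axis=1)
        lp -= 0.5 * np.sum((params[:, S:] / 2.0) ** 2, axis=1)
        return ll + lp

    nwalkers = max(2 * ndim + 2, 64)
    rng = np.random.default_rng([int(spec.seed) % 2**31, 77])
    rate = np.clip(events.sum() / totals.sum(), 0.02, 0.98)
    centre = np.concatenate(
        [np.full(S, np.log(rate / (1 - rate))), np.zeros(K)]
    )
    p0 = centre + 0.2 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
    state = sampler.run_mcmc(p0, n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(flat=True)
    rows = [
        {
            "modality": spec.reference,
            "or": 1.0,
            "cri_low": 1.0,
            "cri_high": 1.0,
        }
    ]
    for m, j in m_map.items():
        th = chain[:, S + j]
        rows.append(
            {
                "modality": m,
                "or": float(np.exp(np.mean(th))),
                "cri_low": float(np.exp(np.quantile(th, 0.025))),
                "cri_high": float(np.exp(np.quantile(th, 0.975))),
            }
        )
    return pd.DataFrame(rows)
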
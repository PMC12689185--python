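"""Blocked Gibbs samplers for the package's normal hierarchical models.

Two model families are covered, both fully conjugate apart from the scale
parameters (updated by univariate slice sampling):

* :class:`ContrastGibbs` — the contrast-level random-effects model used by
  the network meta-analysis:

      y_s ~ N(delta_s, V_s)            (within-trial sampling covariance,
                                        shared-arm covariance on off-diagals)
      delta_s ~ N(X_s theta, tau^2 M_s)  (M_s: unit diagonal, 1/2 off-diagonal)
      theta ~ N(0, diag(prior_sd^2)),  tau ~ HalfNormal(tau_prior_sd)

  The design matrix X encodes the model flavour (consistency, unrelated mean
  effects, node split, meta-regression) so one sampler serves them all.

* :class:`HierRegressionGibbs` — the arm-level weighted regression with
  study random intercepts used by the dose-response models:

      y_i ~ N(alpha_{s(i)} + Z_i beta, se_i^2 + sigma^2)
      alpha_s ~ N(0, sigma_alpha^2),  beta ~ N(0, diag(prior_sd^2))
      sigma ~ HalfNormal(sigma_prior),  sigma_alpha ~ HalfNormal(alpha_prior)

Trials with one and two contrasts are updated in vectorised closed form;
larger blocks fall back to small dense solves.  All randomness flows through
``numpy.random.Generator`` seeded per chain, so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["slice_sample_positive", "ContrastGibbs", "HierRegressionGibbs"]

_M2INV = np.array([[4.0 / 3.0, -2.0 / 3.0], [-2.0 / 3.0, 4.0 / 3.0]])


def slice_sample_positive(logp, x0, rng, w=0.25, max_steps=50, floor=1e-10):
    """One slice-sampling update of a positive scalar (stepping out)."""
    logy = logp(x0) + np.log(rng.uniform())
    left = x0 - w * rng.uniform()
    right = left + w
    steps = max_steps
    while left > floor and logp(left) > logy and steps > 0:
        left -= w
        steps -= 1
    left = max(left, floor)
    steps = max_steps
    while logp(right) > logy and steps > 0:
        right += w
        steps -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logp(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _cs_inverse(m: int) -> np.ndarray:
    """Inverse of the m×m compound-symmetry matrix with 1 diag, 1/2 off."""
    j = np.ones((m, m))
    return 2.0 * (np.eye(m) - j / (m + 1))


class ContrastGibbs:
    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        trial_index: np.ndarray,
        var: np.ndarray,
        shared_cov: np.ndarray | None = None,
        prior_sd: float | np.ndarray = 10.0,
        tau_prior_sd: float = 0.5,
    ) -> None:
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.tau_sd = float(tau_prior_sd)
        trial_index = np.asarray(trial_index)
        var = np.asarray(var, float)
        if np.any(var <= 0):
            raise ValueError("contrast variances must be positive")
        if shared_cov is None:
            shared_cov = np.zeros(self.n)
        shared_cov = np.asarray(shared_cov, float)

        # group contrasts by trial, split by block size
        trials: dict = {}
        for i, t in enumerate(trial_index):
            trials.setdefault(t, []).append(i)
        self.idx1 = np.array(
            [ix[0] for ix in trials.values() if len(ix) == 1], dtype=int
        )
        self.v1 = var[self.idx1] if self.idx1.size else np.empty(0)
        pairs = [ix for ix in trials.values() if len(ix) == 2]
        self.idx2 = np.array(pairs, dtype=int) if pairs else np.empty((0, 2), int)
        self.M2inv = _M2INV
        if self.idx2.shape[0]:
            i, j = self.idx2[:, 0], self.idx2[:, 1]
            c = shared_cov[i]  # both contrasts share the trial's reference arm
            det = var[i] * var[j] - c**2
            self.V2inv = np.empty((self.idx2.shape[0], 2, 2))
            self.V2inv[:, 0, 0] = var[j] / det
            self.V2inv[:, 1, 1] = var[i] / det
            self.V2inv[:, 0, 1] = self.V2inv[:, 1, 0] = -c / det
        else:
            self.V2inv = np.empty((0, 2, 2))
        self.rest = []
        for ix in trials.values():
            if len(ix) > 2:
                m = len(ix)
                ix = np.array(ix, int)
                V = np.diag(var[ix]) + shared_cov[ix[0]] * (
                    np.ones((m, m)) - np.eye(m)
                )
                self.rest.append((ix, np.linalg.inv(V), _cs_inverse(m)))

        # blockdiag(M^-1) applied to X, and the constant quadratic form
        self.Xw = self._apply_minv_mat(self.X)
        self.A = self.Xw.T @ self.X
        prior_sd = np.broadcast_to(np.asarray(prior_sd, float), (self.p,))
        self.prior_prec = np.diag(1.0 / prior_sd**2)

    # -- block-structure helpers -------------------------------------------
    def _apply_minv_mat(self, mat: np.ndarray) -> np.ndarray:
        out = mat.copy()
        if self.idx2.shape[0]:
            block = mat[self.idx2]  # (T, 2, p?)
            out[self.idx2] = np.einsum("ij,tj...->ti...", self.M2inv, block)
        for ix, _, minv in self.rest:
            out[ix] = minv @ mat[ix]
        return out

    def _deviance(self, delta: np.ndarray) -> float:
        r = self.y - delta
        dev = float(np.sum(r[self.idx1] ** 2 / self.v1)) if self.idx1.size else 0.0
        if self.idx2.shape[0]:
            r2 = r[self.idx2]
            dev += float(np.einsum("ti,tij,tj->", r2, self.V2inv, r2))
        for ix, vinv, _ in self.rest:
            dev += float(r[ix] @ vinv @ r[ix])
        return dev

    # -- sampling ----------------------------------------------------------
    def _run_chain(self, rng, draws: int, warmup: int):
        p, n = self.p, self.n
        theta = np.zeros(p)
        tau = 0.2
        delta = self.y.copy()
        th_out = np.empty((draws, p))
        tau_out = np.empty(draws)
        dev_out = np.empty(draws)
        delta_sum = np.zeros(n)
        for it in range(warmup + draws):
            t2 = max(tau * tau, 1e-12)
            mu = self.X @ theta
            # delta | theta, tau
            if self.idx1.size:
                prec = 1.0 / self.v1 + 1.0 / t2
                var = 1.0 / prec
                mean = var * (self.y[self.idx1] / self.v1 + mu[self.idx1] / t2)
                delta[self.idx1] = mean + np.sqrt(var) * rng.standard_normal(
                    self.idx1.size
                )
            if self.idx2.shape[0]:
                I = self.idx2
                P = self.V2inv + self.M2inv[None, :, :] / t2
                rhs = (
                    np.einsum("tij,tj->ti", self.V2inv, self.y[I])
                    + np.einsum("ij,tj->ti", self.M2inv, mu[I]) / t2
                )
                det = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] ** 2
                c00 = P[:, 1, 1] / det
                c11 = P[:, 0, 0] / det
                c01 = -P[:, 0, 1] / det
                mean0 = c00 * rhs[:, 0] + c01 * rhs[:, 1]
                mean1 = c01 * rhs[:, 0] + c11 * rhs[:, 1]
                l00 = np.sqrt(c00)
                l10 = c01 / l00
                l11 = np.sqrt(np.maximum(c11 - l10**2, 1e-300))
                z = rng.standard_normal((I.shape[0], 2))
                delta[I[:, 0]] = mean0 + l00 * z[:, 0]
                delta[I[:, 1]] = mean1 + l10 * z[:, 0] + l11 * z[:, 1]
            for ix, vinv, minv in self.rest:
                P = vinv + minv / t2
                rhs = vinv @ self.y[ix] + minv @ mu[ix] / t2
                cov = np.linalg.inv(P)
                delta[ix] = rng.multivariate_normal(cov @ rhs, cov)
            # theta | delta, tau
            b = (self.Xw.T @ delta) / t2
            pmat = self.A / t2 + self.prior_prec
            cf = np.linalg.cholesky(pmat)
            mean_t = np.linalg.solve(pmat, b)
            theta = mean_t + np.linalg.solve(cf.T, rng.standard_normal(p))
            # tau | delta, theta (slice)
            resid = delta - self.X @ theta
            q0 = float(resid @ self._apply_minv_mat(resid))

            def logp(t, q0=q0):
                return -n * np.log(t) - q0 / (2.0 * t * t) - t * t / (
                    2.0 * self.tau_sd**2
                )

            tau = slice_sample_positive(logp, tau, rng)
            if it >= warmup:
                j = it - warmup
                th_out[j] = theta
                tau_out[j] = tau
                dev_out[j] = self._deviance(delta)
                delta_sum += delta
        return th_out, tau_out, dev_out, delta_sum / draws

    def run(self, chains=4, draws=2000, warmup=1000, seed=0):
        th = np.empty((chains, draws, self.p))
        tau = np.empty((chains, draws))
        dev = np.empty((chains, draws))
        delta_bar = np.zeros(self.n)
        for c in range(chains):
            rng = np.random.default_rng([int(seed) % 2**31, c])
            th[c], tau[c], dev[c], dmean = self._run_chain(rng, draws, warmup)
            delta_bar += dmean / chains
        dbar = float(dev.mean())
        d_at_mean = self._deviance(delta_bar)
        p_d = dbar - d_at_mean
        return {
            "theta": th,
            "tau": tau,
            "deviance": dev,
            "delta_bar": delta_bar,
            "dbar": dbar,
            "pD": p_d,
            "dic": dbar + p_d,
        }


class HierRegressionGibbs:
    def __init__(
        self,
        y: np.ndarray,
        se2: np.ndarray,
        Z: np.ndarray,
        study_idx: np.ndarray,
        prior_sd: float | np.ndarray = 10.0,
        sigma_prior: float = 0.3,
        alpha_prior: float = 0.5,
    ) -> None:
        self.y = np.asarray(y, float)
        self.se2 = np.asarray(se2, float)
        if np.any(self.se2 <= 0):
            raise ValueError("observation variances must be positive")
        Z = np.asarray(Z, float)
        study_idx = np.asarray(study_idx, int)
        self.S = int(study_idx.max()) + 1
        n = len(self.y)
        D = np.zeros((n, self.S + Z.shape[1]))
        D[np.arange(n), study_idx] = 1.0
        D[:, self.S:] = Z
        self.D = D
        self.q = Z.shape[1]
        self.sigma_prior = float(sigma_prior)
        self.alpha_prior = float(alpha_prior)
        prior_sd = np.broadcast_to(np.asarray(prior_sd, float), (self.q,))
        self.beta_prec = 1.0 / prior_sd**2

    def _run_chain(self, rng, draws, warmup):
        n, S, q = len(self.y), self.S, self.q
        p = S + q
        sigma, sig_a = 0.1, 0.2
        theta = np.zeros(p)
        th_out = np.empty((draws, p))
        sig_out = np.empty((draws, 2))
        for it in range(warmup + draws):
            w = 1.0 / (self.se2 + sigma**2)
            dw = self.D * w[:, None]
            pmat = dw.T @ self.D
            prior = np.concatenate(
                [np.full(S, 1.0 / max(sig_a**2, 1e-12)), self.beta_prec]
            )
            pmat[np.arange(p), np.arange(p)] += prior
            b = dw.T @ self.y
            cf = np.linalg.cholesky(pmat)
            mean_t = np.linalg.solve(pmat, b)
            theta = mean_t + np.linalg.solve(cf.T, rng.standard_normal(p))
            resid = self.y - self.D @ theta
            r2 = resid**2

            def logp_sigma(s):
                v = self.se2 + s * s
                return (
                    -0.5 * float(np.sum(np.log(v)))
                    - 0.5 * float(np.sum(r2 / v))
                    - s * s / (2.0 * self.sigma_prior**2)
                )

            sigma = slice_sample_positive(logp_sigma, sigma, rng, w=0.05)
            alpha = theta[:S]
            ssq = float(alpha @ alpha)

            def logp_siga(s):
                return -S * np.log(s) - ssq / (2.0 * s * s) - s * s / (
                    2.0 * self.alpha_prior**2
                )

            sig_a = slice_sample_positive(logp_siga, sig_a, rng, w=0.05)
            if it >= warmup:
                j = it - warmup
                th_out[j] = theta
                sig_out[j] = (sigma, sig_a)
        return th_out, sig_out

    def run(self, chains=4, draws=2000, warmup=1000, seed=0):
        p = self.S + self.q
        th = np.empty((chains, draws, p))
        sig = np.empty((chains, draws, 2))
        for c in range(chains):
            rng = np.random.default_rng([int(seed) % 2**31, c])
            th[c], sig[c] = self._run_chain(rng, draws, warmup)
        return {
            "alpha": th[:, :, : self.S],
            "beta": th[:, :, self.S:],
            "sigma": sig[:, :, 0],
            "sigma_alpha": sig[:, :, 1],
        }
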
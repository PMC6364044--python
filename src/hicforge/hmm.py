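"""Three-state Gaussian hidden Markov model for directionality-index tracks.

A compact, self-contained Baum-Welch / Viterbi implementation for
univariate Gaussian emissions. Three hidden states model downstream bias,
no bias and upstream bias of the DI signal; after fitting, states are
relabeled by descending emission mean so state 0 is always the
downstream-biased one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_VAR_FLOOR = 1e-8


@dataclass
class GaussianHMM:
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihoods: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.means)

    def _log_emission(self, x: np.ndarray) -> np.ndarray:
        """log N(x | mean_k, var_k) for every state k; shape (T, K)."""
        x = np.asarray(x, dtype=float)[:, None]
        var = self.variances[None, :]
        return -0.5 * (
            np.log(2 * np.pi * var) + (x - self.means[None, :]) ** 2 / var
        )

    # -- inference ---------------------------------------------------------

    def _forward_backward(self, x: np.ndarray):
        T, K = len(x), self.n_states
        logB = self._log_emission(x)
        B = np.exp(logB - logB.max(axis=1, keepdims=True))
        alpha = np.zeros((T, K))
        beta = np.zeros((T, K))
        c = np.zeros(T)  # scaling factors
        alpha[0] = self.startprob * B[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ self.transmat) * B[t]
            c[t] = alpha[t].sum()
            alpha[t] /= c[t]
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (self.transmat @ (B[t + 1] * beta[t + 1])) / c[t + 1]
        # the per-step row-max normalization of B cancels in gamma/xi but
        # must be added back to the likelihood
        loglik = float(np.sum(np.log(c)) + np.sum(logB.max(axis=1)))
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi = np.zeros((K, K))
        for t in range(T - 1):
            m = (
                alpha[t][:, None]
                * self.transmat
                * (B[t + 1] * beta[t + 1])[None, :]
            ) / c[t + 1]
            xi += m
        return gamma, xi, loglik

    def log_likelihood(self, x: np.ndarray) -> float:
        _, _, ll = self._forward_backward(np.asarray(x, dtype=float))
        return ll

    def fit(self, x: np.ndarray, max_iter: int = 500, tol: float = 1e-4) -> "GaussianHMM":
        """Baum-Welch; records the (non-decreasing) log-likelihood path."""
        x = np.asarray(x, dtype=float)
        self.log_likelihoods = []
        prev = -np.inf
        for _ in range(max_iter):
            gamma, xi, ll = self._forward_backward(x)
            self.log_likelihoods.append(ll)
            self.startprob = gamma[0] / gamma[0].sum()
            denom = xi.sum(axis=1, keepdims=True)
            self.transmat = np.divide(
                xi, denom, out=np.full_like(xi, 1.0 / self.n_states),
                where=denom > 0,
            )
            w = gamma.sum(axis=0)
            self.means = (gamma * x[:, None]).sum(axis=0) / w
            self.variances = np.maximum(
                (gamma * (x[:, None] - self.means[None, :]) ** 2).sum(axis=0) / w,
                _VAR_FLOOR,
            )
            if abs(ll - prev) < tol:
                break
            prev = ll
        return self

    def viterbi(self, x: np.ndarray) -> np.ndarray:
        """Most probable state path (global decoding)."""
        x = np.asarray(x, dtype=float)
        T, K = len(x), self.n_states
        logB = self._log_emission(x)
        with np.errstate(divide="ignore"):
            logA = np.log(self.transmat)
            logpi = np.log(self.startprob)
        delta = np.zeros((T, K))
        psi = np.zeros((T, K), dtype=int)
        delta[0] = logpi + logB[0]
        for t in range(1, T):
            scores = delta[t - 1][:, None] + logA
            psi[t] = scores.argmax(axis=0)
            delta[t] = scores.max(axis=0) + logB[t]
        path = np.zeros(T, dtype=int)
        path[-1] = int(delta[-1].argmax())
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1, path[t + 1]]
        return path

    # -- canonical labeling ------------------------------------------------

    def relabel_by_mean(self) -> "GaussianHMM":
        """Reorder states by descending emission mean (downstream, none,
        upstream)."""
        order = np.argsort(-self.means)
        self.means = self.means[order]
        self.variances = self.variances[order]
        self.startprob = self.startprob[order]
        self.transmat = self.transmat[np.ix_(order, order)]
        return self


def fit_gaussian_hmm(
    x: np.ndarray,
    n_states: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> GaussianHMM:
    """Best-of-restarts Baum-Welch fit, deterministic given ``seed``.

    Restarts draw emission means from random data quantiles around a
    spread of the empirical distribution; transitions start sticky.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    best: GaussianHMM | None = None
    for r in range(n_restarts):
        if r == 0:
            qs = np.linspace(0.9, 0.1, n_states)
        else:
            qs = np.sort(rng.uniform(0.05, 0.95, n_states))[::-1]
        means = np.quantile(x, qs)
        var = max(float(np.var(x)) / n_states, _VAR_FLOOR)
        trans = np.full((n_states, n_states), 0.1 / (n_states - 1))
        np.fill_diagonal(trans, 0.9)
        model = GaussianHMM(
            startprob=np.full(n_states, 1.0 / n_states),
            transmat=trans,
            means=means.astype(float),
            variances=np.full(n_states, var),
        )
        model.fit(x, max_iter=max_iter, tol=tol)
        if best is None or model.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = model
    assert best is not None
    return best.relabel_by_mean()
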
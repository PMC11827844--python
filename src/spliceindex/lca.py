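"""Latent class analysis: EM for a finite mixture of independent Bernoulli
indicators, with AIC/BIC model selection and the class-size stopping rule.

Samples are described by binary indicators (here: per-event normalized Psi
dichotomized at the cohort mean).  Each latent class k has a weight w_k and
per-indicator Bernoulli probabilities p_kd; the log-likelihood is

    l = sum_i log sum_k w_k prod_d p_kd^x_id (1 - p_kd)^(1 - x_id).

EM is restarted from random initializations (default 300 restarts, 5000
iterations each, tolerance 1e-10 on the log-likelihood) and the best
restart is kept.  Model search over increasing class counts stops once any
class's modal size drops below 10% of the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["LcaModel", "BernoulliMixtureLCA", "fit_lca", "lca_model_selection"]

_EPS = 1e-12


@dataclass
class LcaModel:
    n_classes: int
    class_weights: np.ndarray
    item_probs: np.ndarray  # (n_classes, n_indicators)
    log_likelihood: float
    aic: float
    bic: float
    posteriors: np.ndarray  # (n_samples, n_classes)
    n_parameters: int
    loglik_trace: np.ndarray  # best restart's per-iteration log-likelihood

    @property
    def modal_sizes(self) -> np.ndarray:
        """Class sizes under modal (argmax-posterior) assignment."""
        return np.bincount(np.argmax(self.posteriors, axis=1), minlength=self.n_classes)


def _log_bernoulli(X: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """(n, K) matrix of per-class log p(x_i | class k)."""
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    logp, log1p = np.log(p), np.log1p(-p)
    # x*log p + (1-x)*log(1-p) == x*(log p - log(1-p)) + sum log(1-p)
    return X @ (logp - log1p).T + log1p.sum(axis=1)


class BernoulliMixtureLCA(BaseEstimator):
    """Latent-class model over binary indicators, fitted by restarted EM.

    Parameters follow the published procedure: ``n_restarts=300`` random
    starts, ``max_iter=5000`` EM cycles per start, convergence at an
    absolute log-likelihood change below ``tol``.  Initialization draws
    class weights from a flat Dirichlet and item probabilities uniformly
    on (0.05, 0.95).
    """

    def __init__(
        self,
        n_classes: int = 2,
        n_restarts: int = 300,
        max_iter: int = 5000,
        tol: float = 1e-10,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _em_once(self, X: np.ndarray, rng: np.random.Generator) -> tuple[float, np.ndarray, np.ndarray, list[float]]:
        n, d = X.shape
        K = self.n_classes
        if K == 1:
            # closed form: independent Bernoullis at the column means
            probs = X.mean(axis=0, keepdims=True)
            ll = float(_log_bernoulli(X, probs).sum())
            return ll, np.ones(1), probs, [ll]
        weights = rng.dirichlet(np.ones(K))
        probs = rng.uniform(0.05, 0.95, size=(K, d))
        prev = -np.inf
        trace: list[float] = []
        for _ in range(self.max_iter):
            logpost = _log_bernoulli(X, probs) + np.log(np.clip(weights, _EPS, None))
            norm = logsumexp(logpost, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logpost - norm[:, None])
            nk = resp.sum(axis=0)
            weights = nk / n
            probs = (resp.T @ X) / np.clip(nk[:, None], _EPS, None)
            if abs(ll - prev) < self.tol:
                break
            prev = ll
        return trace[-1], weights, probs, trace

    def fit(self, X, y=None) -> "BernoulliMixtureLCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a non-empty 2-D binary matrix")
        if not np.isin(X, (0.0, 1.0)).all():
            raise ValueError("X must be binary")
        rng = np.random.default_rng(self.random_state)
        n_restarts = 1 if self.n_classes == 1 else self.n_restarts
        best = None
        for _ in range(n_restarts):
            ll, w, p, trace = self._em_once(X, rng)
            if best is None or ll > best[0]:
                best = (ll, w, p, trace)
        ll, w, p, trace = best
        # canonical class order: descending weight (metrics are invariant
        # to relabeling; this just makes output deterministic to read)
        order = np.argsort(-w)
        self.class_weights_ = w[order]
        self.item_probs_ = p[order]
        self.log_likelihood_ = ll
        n, d = X.shape
        self.n_parameters_ = self.n_classes * d + (self.n_classes - 1)
        self.aic_ = -2.0 * ll + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * ll + self.n_parameters_ * np.log(n)
        self.loglik_trace_ = np.asarray(trace)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "item_probs_")
        X = np.asarray(X, dtype=float)
        logpost = _log_bernoulli(X, self.item_probs_) + np.log(
            np.clip(self.class_weights_, _EPS, None)
        )
        return np.exp(logpost - logsumexp(logpost, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def to_model(self, X) -> LcaModel:
        check_is_fitted(self, "item_probs_")
        return LcaModel(
            n_classes=self.n_classes,
            class_weights=self.class_weights_,
            item_probs=self.item_probs_,
            log_likelihood=self.log_likelihood_,
            aic=self.aic_,
            bic=self.bic_,
            posteriors=self.predict_proba(X),
            n_parameters=self.n_parameters_,
            loglik_trace=self.loglik_trace_,
        )


def fit_lca(
    binary_matrix,
    n_classes: int,
    n_restarts: int = 300,
    max_iter: int = 5000,
    tol: float = 1e-10,
    seed: int | None = None,
) -> LcaModel:
    """Fit one latent-class model; best log-likelihood across restarts."""
    est = BernoulliMixtureLCA(
        n_classes=n_classes, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(binary_matrix)
    return est.to_model(binary_matrix)


def lca_model_selection(
    models: list[LcaModel], n_samples: int, min_class_frac: float = 0.10
) -> tuple[LcaModel, bool]:
    """Pick the best-BIC model among interpretable class counts.

    Models are considered in ascending n_classes; once a model produces any
    modal class smaller than ``min_class_frac`` of the sample, that model
    and all larger ones are not interpreted (the predetermined stopping
    rule).  Returns (chosen model, stop flag).
    """
    if not models:
        raise ValueError("no models supplied")
    ordered = sorted(models, key=lambda m: m.n_classes)
    interpreted: list[LcaModel] = []
    stopped = False
    for m in ordered:
        if m.n_classes > 1 and m.modal_sizes.min() < min_class_frac * n_samples:
            stopped = True
            break
        interpreted.append(m)
    if not interpreted:
        # even the smallest model trips the rule; report it but flag the stop
        return ordered[0], True
    chosen = min(interpreted, key=lambda m: m.bic)
    return chosen, stopped
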
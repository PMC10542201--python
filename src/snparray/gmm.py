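"""Batched one-dimensional constrained Gaussian mixtures.

The genotype caller fits, per SNP, small mixtures on the contrast axis
whose components sit at known prior cluster positions (one component
per candidate genotype). Model selection runs over subsets of those
positions, so a monomorphic SNP is a one-component model and a SNP
lacking a minor-homozygote cluster is a two-component model. EM here is
batched across SNPs sharing an initialization, fully deterministic (no
random restarts), with ordered means (components are re-sorted to the
descending contrast order after every M step so component identity is
positional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class BatchGmmFit:
    """EM result for S SNPs fitted with the same k-component init."""

    means: np.ndarray     # (S, k), descending along k
    sds: np.ndarray       # (S, k)
    weights: np.ndarray   # (S, k), rows sum to 1
    loglik: np.ndarray    # (S,)
    bic: np.ndarray       # (S,)
    converged: np.ndarray  # (S,) bool

    @property
    def k(self) -> int:
        return self.means.shape[1]

    def responsibilities(self, x: np.ndarray,
                         rows: np.ndarray | None = None) -> np.ndarray:
        """Posterior component memberships for data x of shape (S', N).

        ``rows`` selects which fitted SNPs' parameters the rows of ``x``
        belong to (default: all S, in order; x must then have S rows).
        """
        means, sds, weights = self.means, self.sds, self.weights
        if rows is not None:
            means, sds, weights = means[rows], sds[rows], weights[rows]
        if x.shape[0] != means.shape[0]:
            raise ValueError("x rows must match the selected fitted SNPs")
        log_r = _log_component_density(x, means, sds, weights)
        log_r -= log_r.max(axis=2, keepdims=True)
        r = np.exp(log_r)
        r /= r.sum(axis=2, keepdims=True)
        return r


def _log_component_density(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                           weights: np.ndarray) -> np.ndarray:
    # x: (S, N); params: (S, k) -> (S, N, k)
    z = (x[:, :, None] - means[:, None, :]) / sds[:, None, :]
    return (-0.5 * z * z - np.log(sds[:, None, :]) - 0.5 * LOG_2PI
            + np.log(np.maximum(weights[:, None, :], 1e-300)))


def fit_gmm_batch(x: np.ndarray, init_means: np.ndarray,
                  init_sd: float = 0.2, max_iter: int = 100,
                  tol: float = 1e-6, min_sd: float = 0.05,
                  min_weight: float = 1e-4,
                  max_shift: float | None = None) -> BatchGmmFit:
    """Fit the same k-component 1-D mixture to every row of ``x``.

    ``x`` has shape (S, N): S SNPs by N samples. ``init_means`` (k,)
    are prior cluster positions in descending order. Component order is
    enforced after each M step. When ``max_shift`` is given, each
    component mean is anchored within ``init +/- max_shift`` so a
    component cannot wander onto a neighbouring genotype's cluster and
    component identity stays positional. BIC uses 3k-1 free parameters.
    """
    x = np.asarray(x, dtype=float)
    S, N = x.shape
    k = len(init_means)
    init_arr = np.asarray(init_means, dtype=float)
    means = np.tile(init_arr, (S, 1))
    sds = np.full((S, k), init_sd)
    weights = np.full((S, k), 1.0 / k)
    prev_ll = np.full(S, -np.inf)
    converged = np.zeros(S, dtype=bool)

    for _ in range(max_iter):
        log_d = _log_component_density(x, means, sds, weights)
        m = log_d.max(axis=2, keepdims=True)
        log_norm = m[:, :, 0] + np.log(np.exp(log_d - m).sum(axis=2))
        ll = log_norm.sum(axis=1)
        resp = np.exp(log_d - log_norm[:, :, None])

        newly = np.abs(ll - prev_ll) < tol
        converged |= newly
        prev_ll = ll
        if converged.all():
            break

        nk = resp.sum(axis=1)                       # (S, k)
        safe_nk = np.maximum(nk, 1e-10)
        new_means = (resp * x[:, :, None]).sum(axis=1) / safe_nk
        dev = x[:, :, None] - new_means[:, None, :]
        new_var = (resp * dev * dev).sum(axis=1) / safe_nk
        new_sds = np.sqrt(np.maximum(new_var, min_sd ** 2))
        new_w = np.maximum(nk / N, min_weight)
        new_w /= new_w.sum(axis=1, keepdims=True)

        # empty components keep their previous position
        empty = nk < 1e-8
        new_means = np.where(empty, means, new_means)
        new_sds = np.where(empty, min_sd, new_sds)

        if max_shift is not None:
            new_means = np.clip(new_means, init_arr - max_shift,
                                init_arr + max_shift)

        # enforce descending mean order, carrying sds/weights along
        order = np.argsort(-new_means, axis=1, kind="stable")
        rows = np.arange(S)[:, None]
        means = new_means[rows, order]
        sds = new_sds[rows, order]
        weights = new_w[rows, order]

    n_params = 3 * k - 1
    bic = -2.0 * prev_ll + n_params * np.log(max(N, 1))
    return BatchGmmFit(means, sds, weights, prev_ll, bic, converged)


def gaussian_loglik(x: np.ndarray, mean: float, sd: float) -> float:
    sd = max(sd, 1e-6)
    z = (np.asarray(x, dtype=float) - mean) / sd
    return float((-0.5 * z * z - np.log(sd) - 0.5 * LOG_2PI).sum())
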
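"""Univariate two-component Gaussian mixture, fitted by EM.

Used to split cells into marker-high and marker-low sets from the averaged
(meta-marker) expression of a cell type's marker panel. The fit is
deliberately minimal and deterministic: means/variances are initialised by
splitting the sorted data at the median, the E and M steps are the closed
forms for a 1-D mixture, and a variance floor prevents collapse onto a
point mass. The log-likelihood is asserted nondecreasing at every
iteration, which is a property of exact EM and therefore a cheap internal
consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GMMFit", "fit_gmm_1d", "binarize_high"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMFit:
    """Fitted 2-component univariate Gaussian mixture."""

    means: np.ndarray  # shape (2,)
    variances: np.ndarray  # shape (2,), > 0
    weights: np.ndarray  # shape (2,), sum to 1
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    @property
    def high_component(self) -> int:
        """Index of the larger-mean ('marker-high') component."""
        return int(np.argmax(self.means))


def _log_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _log_resp(x, means, variances, weights):
    """Log joint (n, 2) and per-point log-likelihood (n,)."""
    lj = np.stack(
        [np.log(weights[k]) + _log_pdf(x, means[k], variances[k]) for k in (0, 1)],
        axis=1,
    )
    m = lj.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(lj - m).sum(axis=1))
    return lj, lse


def fit_gmm_1d(
    values,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_restarts: int = 0,
) -> GMMFit:
    """Fit a 2-component 1-D Gaussian mixture by EM.

    Parameters
    ----------
    values
        1-D array of observations; at least 4 distinct values required.
    tol
        Convergence threshold on the change in total log-likelihood.
    max_iter
        Iteration cap; the fit is returned with ``converged=False`` if hit.
    seed, n_restarts
        Optional random restarts (perturbed means) on top of the
        deterministic median-split initialisation; the best log-likelihood
        wins. With ``n_restarts=0`` (default) the fit is fully
        deterministic and ``seed`` is unused.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4 or np.unique(x).size < 4:
        raise ValueError(
            f"need >= 4 distinct values to fit a 2-component mixture, got "
            f"{np.unique(x).size} distinct of {x.size}"
        )
    var_floor = max(1e-6 * float(np.var(x)), 1e-300)

    xs = np.sort(x)
    half = xs.size // 2
    inits = [
        (
            np.array([xs[:half].mean(), xs[half:].mean()]),
            np.array([max(xs[:half].var(), var_floor), max(xs[half:].var(), var_floor)]),
        )
    ]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        spread = xs[-1] - xs[0]
        for _ in range(n_restarts):
            mu = np.sort(rng.uniform(xs[0], xs[-1], size=2))
            inits.append((mu, np.full(2, max((spread / 4.0) ** 2, var_floor))))

    best: GMMFit | None = None
    for mu0, var0 in inits:
        fit = _em(x, mu0.copy(), var0.copy(), tol, max_iter, var_floor)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em(x, means, variances, tol, max_iter, var_floor) -> GMMFit:
    n = x.size
    weights = np.array([0.5, 0.5])
    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lj, lse = _log_resp(x, means, variances, weights)
        ll = float(lse.sum())
        # exact EM never decreases the likelihood; tolerate fp round-off only
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased: {trace[-1]} -> {ll}"
            )
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        resp = np.exp(lj - lse[:, None])  # (n, 2) posteriors
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
    return GMMFit(
        means=means,
        variances=variances,
        weights=weights,
        loglik=trace[-1],
        converged=converged,
        n_iter=it,
        loglik_trace=np.asarray(trace),
    )


def binarize_high(fit: GMMFit, values) -> np.ndarray:
    """Flag observations assigned to the larger-mean component.

    A point is 'high' iff its posterior probability under the larger-mean
    component strictly exceeds 0.5; an exact 0.5 posterior (the crossing
    point) is assigned low. Flags are invariant to component relabeling
    because the high component is identified by its mean.
    """
    x = np.asarray(values, dtype=float).ravel()
    lj, lse = _log_resp(x, fit.means, fit.variances, fit.weights)
    post_high = np.exp(lj[:, fit.high_component] - lse)
    return post_high > 0.5
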
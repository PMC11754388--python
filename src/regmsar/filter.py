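"""Hamilton forward filter for the two-state switching autoregression.

The discrete state chain is marginalized out of the likelihood by the
classic forward recursion over filtered state probabilities, which makes
the marginal log-likelihood a smooth function of the continuous
parameters.  A brute-force path-enumeration oracle is included for
testing at small T.

Conventions
-----------
* The chain starts in state 1 at the first occasion with probability 1,
  so the filtered probabilities at t=1 are (1, 0).
* The first observation is conditioned on: the likelihood accumulates the
  one-step predictive densities from the second occasion onward.  (No
  marginal density is assigned to the first observation.)
* The transition into occasion t uses the predictor evaluated with
  covariates at t and the lagged series at t-1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .model import (
    BetweenParams,
    PanelDataset,
    TransitionInputs,
    WithinParams,
    compute_mu0,
    compute_mu1,
    compute_mu2,
)

__all__ = [
    "FilterResult",
    "forward_loglik",
    "brute_force_loglik",
    "filtered_probabilities",
    "filter_core",
    "filter_total_fast",
]

_BRUTE_FORCE_T_MAX = 15


@dataclass
class FilterResult:
    """Output of the forward recursion.

    ``xi[i, t]`` are the filtered state probabilities P(S_it = s | data up
    to t); ``per_time_loglik[i, t]`` is the log one-step predictive
    density of the series at occasion t (zero at t=1, which is
    conditioned on); ``loglik`` is their total.
    """

    xi: np.ndarray
    loglik: float
    per_time_loglik: np.ndarray

    def to_frame(self):
        """Long-format table of filtered probabilities, for inspection."""
        import pandas as pd

        n, t, _ = self.xi.shape
        idx, tt = np.meshgrid(np.arange(1, n + 1), np.arange(1, t + 1), indexing="ij")
        return pd.DataFrame(
            {
                "id": idx.ravel(),
                "t": tt.ravel(),
                "xi_state1": self.xi[:, :, 0].ravel(),
                "xi_state2": self.xi[:, :, 1].ravel(),
                "log_predictive": self.per_time_loglik.ravel(),
            }
        )


def filter_core(log_dens, p11, p21, return_xi: bool = False):
    """Vectorized forward recursion over arbitrary leading batch axes.

    Parameters
    ----------
    log_dens : array (..., T, 2)
        State-conditional log-densities of the series at each occasion.
        Entries at t=1 (index 0) are ignored.
    p11 : array broadcastable to (..., T)
        Probability of staying in state 1 on the transition *into* each
        occasion; index 0 unused.
    p21 : float
        Fixed probability of returning from state 2 to state 1.
    return_xi : bool
        Also return filtered probabilities and per-time log-densities
        (requires materializing (..., T) arrays).

    Returns
    -------
    total : array (...,) summed log predictive density over t = 2..T,
        and optionally ``(xi, per_time)``.
    """
    log_dens = np.asarray(log_dens, dtype=float)
    p11 = np.asarray(p11, dtype=float)
    T = log_dens.shape[-2]
    bshape = np.broadcast_shapes(log_dens.shape[:-2], p11.shape[:-1])
    xi1 = np.ones(bshape)
    total = np.zeros(bshape)
    if return_xi:
        xi = np.zeros(bshape + (T, 2))
        xi[..., 0, 0] = 1.0
        per_time = np.zeros(bshape + (T,))
    with np.errstate(divide="ignore"):
        for t in range(1, T):
            p = np.broadcast_to(p11[..., t], bshape)
            # pred2 = 1 - pred1 since each row of the transition matrix sums to 1
            pred1 = p21 + (p - p21) * xi1
            j1 = np.log(pred1) + log_dens[..., t, 0]
            j2 = np.log1p(-pred1) + log_dens[..., t, 1]
            lt = np.logaddexp(j1, j2)
            total += lt
            xi1 = np.exp(j1 - lt)
            if return_xi:
                xi[..., t, 0] = xi1
                xi[..., t, 1] = 1.0 - xi1
                per_time[..., t] = lt
    if return_xi:
        return total, xi, per_time
    return total


def filter_total_fast(log_dens, p11, p21, renorm_every: int = 8):
    """Summed log predictive density only, via the scaled linear-space recursion.

    Equivalent to :func:`filter_core` without ``return_xi`` but cheaper:
    the state-conditional densities are exponentiated once (normalized by
    their per-occasion maximum so the scaled values stay in (0, 1]), the
    recursion then runs in probability space and the running product of
    scale factors is folded back into log space every ``renorm_every``
    steps.  A zero product (an observation impossible under both states)
    yields -inf/NaN, which callers treat as log-density -inf.
    """
    log_dens = np.asarray(log_dens, dtype=float)
    p11 = np.asarray(p11, dtype=float)
    T = log_dens.shape[-2]
    m = np.max(log_dens, axis=-1)  # (..., T)
    F = np.exp(log_dens - m[..., None])
    bshape = np.broadcast_shapes(log_dens.shape[:-2], p11.shape[:-1])
    xi1 = np.ones(bshape)
    prod = np.ones(bshape)
    total = np.zeros(bshape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(1, T):
            p = p11[..., t]
            pred1 = p21 + (p - p21) * xi1
            num1 = pred1 * F[..., t, 0]
            c = num1 + (1.0 - pred1) * F[..., t, 1]
            xi1 = num1 / c
            prod = prod * c
            if t % renorm_every == 0:
                total += np.log(prod)
                prod = np.ones(bshape)
        total += np.log(prod)
    return total + np.sum(m[..., 1:], axis=-1)


try:  # optional compiled kernel for the sampler's hot path
    from numba import njit as _njit

    # One scaled recursion per (walker, node, individual) series.  The
    # scale product is floored at 1e-300 so an impossible observation
    # drives the total far negative without tripping fastmath on infs.

    @_njit(fastmath=True, cache=False)
    def _recursion_kernel(F1, F2, msum, eta, p21, time_varying):  # pragma: no cover
        W, N, T = F1.shape
        G = eta.shape[1]
        out = np.empty((W, G, N))
        for w in range(W):
            for g in range(G):
                for n in range(N):
                    e = eta[w, g, n, 0]
                    if e >= 0.0:
                        p = 1.0 / (1.0 + np.exp(-e))
                    else:
                        ex = np.exp(e)
                        p = ex / (1.0 + ex)
                    xi1 = 1.0
                    prod = 1.0
                    tot = 0.0
                    for t in range(1, T):
                        if time_varying:
                            e = eta[w, g, n, t]
                            if e >= 0.0:
                                p = 1.0 / (1.0 + np.exp(-e))
                            else:
                                ex = np.exp(e)
                                p = ex / (1.0 + ex)
                        pred1 = p21 + (p - p21) * xi1
                        num1 = pred1 * F1[w, n, t]
                        c = num1 + (1.0 - pred1) * F2[w, n, t] + 1e-300
                        xi1 = num1 / c
                        prod *= c
                        if t % 8 == 0:
                            tot += np.log(prod)
                            prod = 1.0
                    out[w, g, n] = tot + np.log(prod) + msum[w, n]
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def marginal_filter_totals(log_dens, eta, p21) -> np.ndarray:
    """Summed log predictive densities over a quadrature-node batch.

    Parameters
    ----------
    log_dens : (W, N, T, 2)
        State-conditional log-densities per walker (shared across nodes).
    eta : (W, G, N) or (W, G, N, T)
        Transition-predictor values per walker, node and individual;
        a trailing time axis makes the stay probability time-varying.
    p21 : float

    Returns
    -------
    (W, G, N) array of summed log predictive densities (t = 2..T).

    Dispatches to a compiled kernel when numba is importable; the numpy
    path (:func:`filter_total_fast`) is the reference implementation.
    """
    log_dens = np.asarray(log_dens, dtype=float)
    eta = np.asarray(eta, dtype=float)
    time_varying = eta.ndim == 4
    if _HAVE_NUMBA:
        m = np.max(log_dens, axis=-1)  # (W, N, T)
        F = np.exp(log_dens - m[..., None])
        msum = np.sum(m[..., 1:], axis=-1)  # (W, N)
        eta_k = eta if time_varying else eta[..., None]
        return _recursion_kernel(
            np.ascontiguousarray(F[..., 0]),
            np.ascontiguousarray(F[..., 1]),
            msum,
            np.ascontiguousarray(eta_k),
            float(p21),
            time_varying,
        )
    w, g = eta.shape[0], eta.shape[1]
    n, T = log_dens.shape[1], log_dens.shape[2]
    p11 = expit(eta[..., None]) if not time_varying else expit(eta)
    p11 = np.broadcast_to(p11, (w, g, n, T))
    return filter_total_fast(log_dens[:, None], p11, p21)


def _state_logdens_k1(data: PanelDataset, w: WithinParams) -> np.ndarray:
    """State-conditional log-densities, vectorized for the univariate model.

    Returns (N, T, 2); the t=1 slice is computed with a zero lag and is
    never used by the filter.
    """
    y = data.eta_y[:, :, 0]
    prev = np.concatenate([np.zeros((data.N, 1)), y[:, :-1]], axis=1)
    zterm = w.gamma * data.eta_z if data.eta_z is not None else 0.0
    mean1 = np.zeros_like(y) + zterm
    mean2 = w.a2[0] + w.b2[0, 0] * prev + zterm
    sd = w.sigma_eps
    const = -np.log(sd) - 0.5 * np.log(2.0 * np.pi)
    ld = np.empty((data.N, data.T, 2))
    ld[:, :, 0] = -0.5 * ((y - mean1) / sd) ** 2 + const
    ld[:, :, 1] = -0.5 * ((y - mean2) / sd) ** 2 + const
    return ld


def _state_logdens(data: PanelDataset, w: WithinParams) -> np.ndarray:
    if data.K == 1:
        return _state_logdens_k1(data, w)
    # General K: loop over occasions with the Cholesky of the residual
    # covariance; the shipped designs are univariate so speed is secondary.
    cov = w.sigma_eps_matrix
    L = np.linalg.cholesky(cov)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    const = -0.5 * (logdet + data.K * np.log(2.0 * np.pi))
    ld = np.empty((data.N, data.T, 2))
    prev = np.concatenate([np.zeros((data.N, 1, data.K)), data.eta_y[:, :-1]], axis=1)
    z = data.eta_z if data.eta_z is not None else np.zeros((data.N, data.T))
    for s_idx, s in enumerate((1, 2)):
        mean = (
            w.intercept(s)
            + prev @ w.ar_matrix(s).T
            + z[:, :, None] * w.Gamma
        )
        resid = np.linalg.solve(L, (data.eta_y - mean)[..., None])[..., 0]
        ld[:, :, s_idx] = -0.5 * np.sum(resid**2, axis=-1) + const
    return ld


def _transition_predictor(
    data: PanelDataset,
    between: BetweenParams,
    eps0: np.ndarray,
    include_mu1: bool,
    include_mu2: bool,
) -> TransitionInputs:
    mu0 = compute_mu0(between.beta0, between.beta_x, data.eta_x, eps0)
    mu1 = None
    mu2 = None
    if include_mu1:
        mu1 = compute_mu1(between.beta_z, between.beta_xz, data.eta_z, data.eta_x)
    if include_mu2:
        mu2 = compute_mu2(between.beta_y, between.beta_xy, data.eta_y, data.eta_x)
    return TransitionInputs(mu0=mu0, mu1=mu1, mu2=mu2, include_mu1=include_mu1, include_mu2=include_mu2)


def forward_loglik(
    data: PanelDataset,
    within: WithinParams,
    between: BetweenParams,
    eps0: np.ndarray,
    transition_inputs: TransitionInputs | None = None,
    include_mu1: bool = False,
    include_mu2: bool = False,
) -> FilterResult:
    """Marginal log-likelihood of the series with the states filtered out.

    ``eps0`` is the vector of individual random-intercept deviations,
    treated here as known inputs (the posterior either samples them or
    marginalizes them by quadrature; see :mod:`regmsar.inference`).
    """
    if transition_inputs is None:
        transition_inputs = _transition_predictor(
            data, between, np.asarray(eps0, dtype=float), include_mu1, include_mu2
        )
    eta_tilde = transition_inputs.eta_tilde(data.T)
    p11 = expit(eta_tilde)
    ld = _state_logdens(data, within)
    total, xi, per_time = filter_core(ld, p11, between.p21, return_xi=True)
    if not np.all(np.isfinite(per_time[:, 1:])):
        bad = np.argwhere(~np.isfinite(per_time))
        i, t = bad[0]
        raise FloatingPointError(
            f"non-finite predictive density at individual {i + 1}, occasion {t + 1}"
        )
    return FilterResult(xi=xi, loglik=float(np.sum(total)), per_time_loglik=per_time)


def filtered_probabilities(result: FilterResult) -> np.ndarray:
    """Filtered state probabilities, shape (N, T, 2)."""
    return result.xi


def brute_force_loglik(
    data: PanelDataset,
    within: WithinParams,
    between: BetweenParams,
    eps0: np.ndarray,
    transition_inputs: TransitionInputs | None = None,
    include_mu1: bool = False,
    include_mu2: bool = False,
) -> float:
    """Exact marginal log-likelihood by enumerating all state paths.

    Testing oracle only: the cost is 2^(T-1) paths per individual (the
    first state is fixed at 1), so T is capped at 15.
    """
    if data.T > _BRUTE_FORCE_T_MAX:
        raise ValueError(
            f"brute-force enumeration limited to T <= {_BRUTE_FORCE_T_MAX}, got T={data.T}"
        )
    if transition_inputs is None:
        transition_inputs = _transition_predictor(
            data, between, np.asarray(eps0, dtype=float), include_mu1, include_mu2
        )
    eta_tilde = transition_inputs.eta_tilde(data.T)
    p11 = expit(eta_tilde)
    p21 = between.p21
    ld = _state_logdens(data, within)
    total = 0.0
    with np.errstate(divide="ignore"):
        log_trans = {
            # (origin, destination) -> log prob as function of t, per individual
            (0, 0): np.log(p11),
            (0, 1): np.log1p(-p11),
            (1, 0): np.full_like(p11, np.log(p21) if p21 > 0 else -np.inf),
            (1, 1): np.full_like(p11, np.log1p(-p21) if p21 < 1 else -np.inf),
        }
    for i in range(data.N):
        path_logps = []
        for path in itertools.product((0, 1), repeat=data.T - 1):
            lp = 0.0
            prev = 0  # state 1 at t=1
            for t, s in enumerate(path, start=1):
                lp += log_trans[(prev, s)][i, t] + ld[i, t, s]
                prev = s
            path_logps.append(lp)
        path_logps = np.asarray(path_logps)
        m = np.max(path_logps)
        total += m + np.log(np.sum(np.exp(path_logps - m)))
    return float(total)
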
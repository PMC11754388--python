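"""Core model equations for the two-level Markov-switching AR(1) model.

The model couples three pieces:

* a within-level (vector) autoregression whose intercept and AR matrix
  switch with a two-state discrete latent chain ``S_it`` (state 1 is the
  reference state with intercept and AR coefficients fixed at zero),
* a between-level regression that feeds individual covariates into the
  chain's transition probabilities through a logistic link, and
* an optional linear-normal measurement layer mapping latent variables to
  observed items.

Everything here is deterministic: densities, linear predictors and the
transition machinery.  Simulation lives in :mod:`regmsar.simulate`, the
likelihood recursion in :mod:`regmsar.filter`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "DimensionError",
    "ConfigurationError",
    "WithinParams",
    "BetweenParams",
    "MeasurementParams",
    "PanelDataset",
    "TransitionInputs",
    "compute_mu0",
    "compute_mu1",
    "compute_mu2",
    "stay_probability",
    "transition_matrix",
    "state_conditional_logdensity",
    "measurement_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DimensionError(ValueError):
    """Raised when an array argument has an incompatible shape.

    The message names the offending axis so callers can locate the
    mismatch without inspecting tracebacks.
    """


class ConfigurationError(ValueError):
    """Raised when a model component is requested but its inputs are absent."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class WithinParams:
    """State-dependent parameters of the within-level autoregression.

    State 1 is the anchored reference state: its intercept and AR matrix
    are identically zero and are not stored.  ``a2``/``b2`` hold the
    state-2 intercept (length ``K``) and AR matrix (``K x K``).  ``gamma``
    is the effect of the time-varying covariate on the *first* component
    of the series only.  For ``K == 1`` the residual scale is the scalar
    ``sigma_eps``; for ``K > 1`` supply the SD vector ``tau_eps`` and the
    Cholesky factor ``omega_eps`` of the residual correlation matrix.
    """

    a2: np.ndarray
    b2: np.ndarray
    gamma: float = 0.0
    sigma_eps: float | None = None
    tau_eps: np.ndarray | None = None
    omega_eps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a2 = _as_1d(self.a2, "a2")
        self.b2 = np.atleast_2d(np.asarray(self.b2, dtype=float))
        k = self.a2.shape[0]
        if self.b2.shape != (k, k):
            raise DimensionError(
                f"b2 must be ({k}, {k}) to match a2, got {self.b2.shape}"
            )
        if k == 1:
            if self.sigma_eps is None:
                raise ConfigurationError("sigma_eps required when K == 1")
            if self.sigma_eps <= 0:
                raise ValueError("sigma_eps must be positive")
        else:
            if self.tau_eps is None or self.omega_eps is None:
                raise ConfigurationError("tau_eps and omega_eps required when K > 1")
            self.tau_eps = _as_1d(self.tau_eps, "tau_eps")
            if self.tau_eps.shape[0] != k:
                raise DimensionError(f"tau_eps must have length K={k}")
            if np.any(self.tau_eps <= 0):
                raise ValueError("tau_eps must be positive")
            self.omega_eps = np.asarray(self.omega_eps, dtype=float)
            if self.omega_eps.shape != (k, k):
                raise DimensionError(f"omega_eps must be ({k}, {k})")
            # PD check of the reconstructed covariance, at construction time.
            np.linalg.cholesky(self.sigma_eps_matrix)

    @property
    def K(self) -> int:
        return self.a2.shape[0]

    def intercept(self, s: int) -> np.ndarray:
        """State-specific intercept; state 1 is the zero vector."""
        if s not in (1, 2):
            raise ValueError(f"state must be 1 or 2, got {s}")
        return np.zeros(self.K) if s == 1 else self.a2

    def ar_matrix(self, s: int) -> np.ndarray:
        if s not in (1, 2):
            raise ValueError(f"state must be 1 or 2, got {s}")
        return np.zeros((self.K, self.K)) if s == 1 else self.b2

    @property
    def Gamma(self) -> np.ndarray:
        """Covariate-effect vector (gamma, 0, ..., 0)."""
        g = np.zeros(self.K)
        g[0] = self.gamma
        return g

    @property
    def sigma_eps_matrix(self) -> np.ndarray:
        """Residual covariance, reconstructed from its Cholesky pieces."""
        if self.K == 1:
            return np.array([[self.sigma_eps**2]])
        L = np.diag(self.tau_eps) @ self.omega_eps
        return L @ L.T


@dataclass
class BetweenParams:
    """Between-level regression parameters driving the transition machinery.

    ``p21`` is the fixed probability of returning from state 2 to state 1
    between consecutive occasions (0.05 in the shipped study designs).
    """

    beta0: float
    beta_x: np.ndarray
    sigma_eps0: float
    beta_z: float = 0.0
    beta_xz: np.ndarray | None = None
    beta_y: np.ndarray | None = None
    beta_xy: np.ndarray | None = None
    phi_x: np.ndarray | None = None
    p21: float = 0.05

    def __post_init__(self) -> None:
        self.beta_x = _as_1d(self.beta_x, "beta_x")
        if self.beta_xz is not None:
            self.beta_xz = _as_1d(self.beta_xz, "beta_xz")
            if self.beta_xz.shape != self.beta_x.shape:
                raise DimensionError("beta_xz must have length Q like beta_x")
        if self.beta_y is not None:
            self.beta_y = _as_1d(self.beta_y, "beta_y")
        if self.beta_xy is not None:
            self.beta_xy = _as_1d(self.beta_xy, "beta_xy")
        if self.sigma_eps0 < 0:
            raise ValueError("sigma_eps0 must be non-negative")
        if not 0.0 <= self.p21 <= 1.0:
            raise ValueError("p21 must lie in [0, 1]")
        if self.phi_x is not None:
            self.phi_x = np.asarray(self.phi_x, dtype=float)
            q = self.beta_x.shape[0]
            if self.phi_x.shape != (q, q):
                raise DimensionError(f"phi_x must be ({q}, {q})")
            if not np.allclose(self.phi_x, self.phi_x.T):
                raise ValueError("phi_x must be symmetric")
            np.linalg.cholesky(self.phi_x)

    @property
    def Q(self) -> int:
        return self.beta_x.shape[0]

    def beta_star(self, include_mu1: bool = False, include_mu2: bool = False) -> np.ndarray:
        """Concatenated transition-slope vector (beta_x, beta_z, beta_xz, beta_y, beta_xy).

        Only the components of the included predictor blocks appear, so the
        result has exactly the model's ``P`` entries.
        """
        parts = [self.beta_x]
        if include_mu1:
            if self.beta_xz is None:
                raise ConfigurationError("beta_xz required when mu1 is included")
            parts.append(np.array([self.beta_z]))
            parts.append(self.beta_xz)
        if include_mu2:
            if self.beta_y is None or self.beta_xy is None:
                raise ConfigurationError("beta_y and beta_xy required when mu2 is included")
            parts.append(self.beta_y)
            parts.append(self.beta_xy)
        return np.concatenate(parts)


@dataclass
class MeasurementParams:
    """Optional linear-normal measurement layer.

    Leading loadings are fixed at 1 for identification; error covariances
    are diagonal.  ``None`` blocks are treated as identity mappings (the
    simulation-study setting: loadings 1, measurement error 0), whose
    likelihood contribution is conventionally zero.
    """

    lambda_y: np.ndarray | None = None
    sigma_y: np.ndarray | None = None
    lambda_z: np.ndarray | None = None
    sigma_z: np.ndarray | None = None
    lambda_x: np.ndarray | None = None
    sigma_x: np.ndarray | None = None
    sigma_eta_z: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_y", "sigma_z", "sigma_x"):
            v = getattr(self, name)
            if v is not None:
                v = _as_1d(v, name)
                if np.any(v < 0):
                    raise ValueError(f"{name} entries must be non-negative")
                setattr(self, name, v)
        for name in ("lambda_y", "lambda_z", "lambda_x"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def is_identity(self) -> bool:
        return self.lambda_y is None and self.lambda_z is None and self.lambda_x is None


@dataclass
class PanelDataset:
    """Complete (no missing values) long panel of N individuals over T occasions.

    ``eta_y`` is stored as (N, T, K); a (N, T) array is promoted to K=1.
    Time is 1-based in the model equations; axis 1 index 0 is occasion
    t=1, where the state is known to be 1 for every individual.
    """

    eta_y: np.ndarray
    eta_x: np.ndarray
    eta_z: np.ndarray | None = None
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eta_y = np.asarray(self.eta_y, dtype=float)
        if self.eta_y.ndim == 2:
            self.eta_y = self.eta_y[:, :, None]
        if self.eta_y.ndim != 3:
            raise DimensionError("eta_y must be (N, T) or (N, T, K)")
        n, t = self.eta_y.shape[:2]
        self.eta_x = np.asarray(self.eta_x, dtype=float)
        if self.eta_x.ndim != 2 or self.eta_x.shape[0] != n:
            raise DimensionError(f"eta_x must be (N={n}, Q), got {self.eta_x.shape}")
        if self.eta_z is not None:
            self.eta_z = np.asarray(self.eta_z, dtype=float)
            if self.eta_z.shape != (n, t):
                raise DimensionError(f"eta_z must be (N={n}, T={t}), got {self.eta_z.shape}")
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=int)
            if self.states.shape != (n, t):
                raise DimensionError(f"states must be (N={n}, T={t})")
            if not np.all(np.isin(self.states, (1, 2))):
                raise ValueError("states must take values in {1, 2}")
            if not np.all(self.states[:, 0] == 1):
                raise ValueError("states at t=1 must all equal 1")
        if not np.all(np.isfinite(self.eta_y)):
            raise ValueError("eta_y contains non-finite values (missing data unsupported)")

    @property
    def N(self) -> int:
        return self.eta_y.shape[0]

    @property
    def T(self) -> int:
        return self.eta_y.shape[1]

    @property
    def K(self) -> int:
        return self.eta_y.shape[2]

    @property
    def Q(self) -> int:
        return self.eta_x.shape[1]


@dataclass
class TransitionInputs:
    """Decomposition of the transition-probability predictor.

    ``eta_tilde`` is the sum of the random-intercept component ``mu0``
    (per individual), the time-varying covariate component ``mu1`` and the
    lagged-series component ``mu2``; omitted components contribute zero.
    """

    mu0: np.ndarray
    mu1: np.ndarray | None = None
    mu2: np.ndarray | None = None
    include_mu1: bool = False
    include_mu2: bool = False

    def eta_tilde(self, T: int | None = None) -> np.ndarray:
        """Return the (N, T) predictor; time-invariant mu0 is broadcast."""
        mu0 = np.asarray(self.mu0, dtype=float)
        parts = []
        if self.include_mu1:
            if self.mu1 is None:
                raise ConfigurationError("mu1 requested but not provided")
            parts.append(np.asarray(self.mu1, dtype=float))
        if self.include_mu2:
            if self.mu2 is None:
                raise ConfigurationError("mu2 requested but not provided")
            parts.append(np.asarray(self.mu2, dtype=float))
        if parts:
            out = mu0[:, None] + sum(parts)
        else:
            if T is None:
                raise ValueError("T required when eta_tilde is time-invariant")
            out = np.repeat(mu0[:, None], T, axis=1)
        return out


def compute_mu0(beta0, beta_x, eta_x, eps0) -> np.ndarray:
    """Random-intercept component: beta0 + eta_x @ beta_x + eps0, per individual."""
    beta_x = _as_1d(beta_x, "beta_x")
    eta_x = np.atleast_2d(np.asarray(eta_x, dtype=float))
    eps0 = _as_1d(eps0, "eps0")
    if eta_x.shape[1] != beta_x.shape[0]:
        raise DimensionError(
            f"eta_x axis 1 has length {eta_x.shape[1]}, expected Q={beta_x.shape[0]}"
        )
    if eps0.shape[0] != eta_x.shape[0]:
        raise DimensionError(
            f"eps0 axis 0 has length {eps0.shape[0]}, expected N={eta_x.shape[0]}"
        )
    return float(beta0) + eta_x @ beta_x + eps0


def compute_mu1(beta_z, beta_xz, eta_z, eta_x) -> np.ndarray:
    """Time-varying component: beta_z * eta_z + (beta_xz' eta_x) * eta_z."""
    if eta_z is None:
        raise ConfigurationError("mu1 requires the time-varying covariate eta_z")
    beta_xz = _as_1d(beta_xz, "beta_xz")
    eta_z = np.atleast_2d(np.asarray(eta_z, dtype=float))
    eta_x = np.atleast_2d(np.asarray(eta_x, dtype=float))
    if eta_x.shape[1] != beta_xz.shape[0]:
        raise DimensionError(
            f"eta_x axis 1 has length {eta_x.shape[1]}, expected Q={beta_xz.shape[0]}"
        )
    if eta_x.shape[0] != eta_z.shape[0]:
        raise DimensionError("eta_x and eta_z disagree on N (axis 0)")
    slope = float(beta_z) + eta_x @ beta_xz
    return slope[:, None] * eta_z


def compute_mu2(beta_y, beta_xy, eta_y, eta_x) -> np.ndarray:
    """Lagged-series component aligned to arrival time.

    Entry ``[:, t]`` (0-based) is the contribution of the series at
    occasion t-1 to the transition *into* occasion t:
    ``beta_y' eta_y[t-1] + beta_xy' (eta_x kron eta_y[t-1])``.
    At the first occasion there is no lag and the contribution is zero.

    The Kronecker product is Q-major: block q of ``beta_xy`` multiplies
    ``eta_x[q] * eta_y`` (a K-vector), so ``beta_xy`` has length K*Q.
    """
    beta_y = _as_1d(beta_y, "beta_y")
    beta_xy = _as_1d(beta_xy, "beta_xy")
    eta_y = np.asarray(eta_y, dtype=float)
    if eta_y.ndim == 2:
        eta_y = eta_y[:, :, None]
    eta_x = np.atleast_2d(np.asarray(eta_x, dtype=float))
    k = beta_y.shape[0]
    q = eta_x.shape[1]
    if eta_y.shape[2] != k:
        raise DimensionError(f"eta_y axis 2 has length {eta_y.shape[2]}, expected K={k}")
    if beta_xy.shape[0] != k * q:
        raise DimensionError(
            f"beta_xy has length {beta_xy.shape[0]}, expected K*Q={k * q}"
        )
    n, t = eta_y.shape[:2]
    lag = np.concatenate([np.zeros((n, 1, k)), eta_y[:, :-1]], axis=1)
    bxy = beta_xy.reshape(q, k)
    # beta_xy' (eta_x kron y) = sum_q eta_x[:, q] * (bxy[q] . y)
    main = lag @ beta_y
    inter = np.einsum("nq,ntk,qk->nt", eta_x, lag, bxy)
    out = main + inter
    out[:, 0] = 0.0
    return out


def stay_probability(eta_tilde) -> np.ndarray | float:
    """Probability of remaining in state 1: logistic(eta_tilde), overflow-safe."""
    out = expit(np.asarray(eta_tilde, dtype=float))
    if np.ndim(eta_tilde) == 0:
        return float(out)
    return out


def transition_matrix(p11: float, p21: float) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix, rows indexed by origin state."""
    for name, p in (("p11", p11), ("p21", p21)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return np.array([[p11, 1.0 - p11], [p21, 1.0 - p21]])


def state_conditional_logdensity(eta_y_t, eta_y_prev, eta_z_t, s: int, w: WithinParams) -> float:
    """Log-density of the series at one occasion given the state and the lag.

    The mean is ``A_s + B_s eta_y_prev + Gamma eta_z_t`` with
    ``Gamma = (gamma, 0, ..., 0)``; the covariance is the state-invariant
    residual covariance of ``w``.
    """
    y = _as_1d(eta_y_t, "eta_y_t")
    prev = _as_1d(eta_y_prev, "eta_y_prev")
    mean = w.intercept(s) + w.ar_matrix(s) @ prev + w.Gamma * float(eta_z_t)
    if w.K == 1:
        sd = w.sigma_eps
        z = (y[0] - mean[0]) / sd
        return float(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI)
    cov = w.sigma_eps_matrix
    L = np.linalg.cholesky(cov)
    resid = np.linalg.solve(L, y - mean)
    return float(
        -0.5 * resid @ resid - np.sum(np.log(np.diag(L))) - 0.5 * w.K * _LOG_2PI
    )


def _items_loglik(obs, loading, latent, sigma) -> float:
    mean = np.asarray(latent) * np.asarray(loading)
    z = (np.asarray(obs) - mean) / sigma
    return float(np.sum(-0.5 * z**2 - np.log(sigma) - 0.5 * _LOG_2PI))


def measurement_loglik(Y, Z, X, latents: dict, m: MeasurementParams | None) -> float:
    """Sum of independent normal item log-densities of the measurement layer.

    With no free loadings configured (the identity mapping of the shipped
    simulation designs) the contribution is conventionally zero.
    """
    if m is None or m.is_identity:
        return 0.0
    total = 0.0
    if m.lambda_y is not None:
        if Y is None or "eta_y" not in latents:
            raise ConfigurationError("measurement layer for Y enabled without Y/eta_y")
        Y = np.asarray(Y, dtype=float)
        eta_y = np.asarray(latents["eta_y"], dtype=float)
        if eta_y.ndim == 2:
            eta_y = eta_y[:, :, None]
        lam = np.atleast_2d(m.lambda_y)
        if lam.shape[1] != eta_y.shape[2] or Y.shape[2] != lam.shape[0]:
            raise DimensionError(
                f"lambda_y shape {lam.shape} incompatible with Y {Y.shape} / eta_y {eta_y.shape}"
            )
        mean = eta_y @ lam.T
        z = (Y - mean) / m.sigma_y
        total += float(np.sum(-0.5 * z**2 - np.log(m.sigma_y) - 0.5 * _LOG_2PI))
    if m.lambda_z is not None:
        if Z is None or "eta_z" not in latents:
            raise ConfigurationError("measurement layer for Z enabled without Z/eta_z")
        lam = np.ravel(m.lambda_z)
        Z = np.asarray(Z, dtype=float)
        eta_z = np.asarray(latents["eta_z"], dtype=float)
        mean = eta_z[..., None] * lam
        z = (Z - mean) / m.sigma_z
        total += float(np.sum(-0.5 * z**2 - np.log(m.sigma_z) - 0.5 * _LOG_2PI))
    if m.lambda_x is not None:
        if X is None or "eta_x" not in latents:
            raise ConfigurationError("measurement layer for X enabled without X/eta_x")
        lam = np.atleast_2d(m.lambda_x)
        X = np.asarray(X, dtype=float)
        eta_x = np.asarray(latents["eta_x"], dtype=float)
        if lam.shape[1] != eta_x.shape[1] or X.shape[1] != lam.shape[0]:
            raise DimensionError(
                f"lambda_x shape {lam.shape} incompatible with X {X.shape} / eta_x {eta_x.shape}"
            )
        mean = eta_x @ lam.T
        z = (X - mean) / m.sigma_x
        total += float(np.sum(-0.5 * z**2 - np.log(m.sigma_x) - 0.5 * _LOG_2PI))
    return total
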
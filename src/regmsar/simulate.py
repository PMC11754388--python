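"""Synthetic-data generators for the two shipped study designs.

Study 1 (time-invariant transitions)
    Between-level covariates eta_x ~ N(0, Phi) with unit variances and
    0.3 pairwise correlations drive a time-invariant stay probability
    logistic(beta0 + beta_x' eta_x + eps0_i); the return probability from
    state 2 is fixed at 0.05.  The nonzero slopes alternate +0.5/-0.5 and
    the zero-rate is 50% or 75% of P in {5, 15, 25}, N in {50, 75, 100},
    T in {10, 25, 50}.

Study 2 (time-varying transitions)
    N = 100, P = 15 decomposed as 7 time-invariant slopes
    (0.5, -0.5, 0.5, 0, 0, 0, 0), one time-varying covariate with slope
    0.5 and 7 cross-level interactions with nonzeros (0.5, -0.5, 0.5) in
    the trailing slots; T ranges over 30..70.

Both designs share the within-level truths: state-2 intercept 3, AR
coefficient 0.8, covariate effect gamma = 0.5, residual SD 0.25, and a
unit random-intercept SD.  The observed items equal the latent variables
(loadings 1, zero measurement error).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import expit

from .model import BetweenParams, PanelDataset, WithinParams

__all__ = [
    "Sim1Design",
    "Sim2Design",
    "SimulatedDataset",
    "make_beta_star",
    "generate_sim1",
    "generate_sim2",
    "compute_snr",
    "sim1_phi",
    "sim1_snr",
    "sim2_phi_full",
    "sim2_snr",
    "LOGISTIC_VARIANCE",
    "WITHIN_TRUTH",
]

LOGISTIC_VARIANCE = math.pi**2 / 3.0

# Within-level truths shared by both study designs.
WITHIN_TRUTH = dict(a2=3.0, b2=0.8, gamma=0.5, sigma_eps=0.25)

_BETA0 = 3.0
_P21 = 0.05
_PHI_OFFDIAG = 0.3
# The random-intercept SD is not varied across design cells; 1 is the
# value consistent with the printed design SNR of ~0.08 at P=5 given the
# logistic residual variance pi^2/3 in the denominator.
_SIGMA_EPS0 = 1.0


@dataclass(frozen=True)
class Sim1Design:
    """Design cell of the time-invariant study (defaults: smallest cell)."""

    N: int = 50
    T: int = 10
    P: int = 5
    zero_rate: float = 0.5
    seed: int = 0
    beta0: float = _BETA0
    sigma_eps0: float = _SIGMA_EPS0

    def __post_init__(self):
        if self.N <= 0 or self.T <= 0 or self.P <= 0:
            raise ValueError("N, T and P must be positive")
        if not 0.0 <= self.zero_rate < 1.0:
            raise ValueError("zero_rate must lie in [0, 1)")


@dataclass(frozen=True)
class Sim2Design:
    """Design cell of the time-varying study: P = 7 + 1 + 7 predictors."""

    N: int = 100
    T: int = 30
    seed: int = 0
    beta0: float = _BETA0
    sigma_eps0: float = _SIGMA_EPS0
    Q: int = 7

    beta_x: tuple = (0.5, -0.5, 0.5, 0.0, 0.0, 0.0, 0.0)
    beta_z: float = 0.5
    # three nonzero interactions, placed in the trailing slots
    beta_xz: tuple = (0.0, 0.0, 0.0, 0.0, 0.5, -0.5, 0.5)

    def __post_init__(self):
        if len(self.beta_x) != self.Q or len(self.beta_xz) != self.Q:
            raise ValueError("beta_x and beta_xz must have length Q")

    @property
    def P(self) -> int:
        return 2 * self.Q + 1


@dataclass
class SimulatedDataset:
    """A generated panel together with the generating truths."""

    data: PanelDataset
    true_states: np.ndarray
    true_beta_star: np.ndarray
    true_eps0: np.ndarray
    true_within: WithinParams
    true_between: BetweenParams
    design: Sim1Design | Sim2Design

    def design_dict(self) -> dict:
        return asdict(self.design)


def make_beta_star(P: int, zero_rate: float) -> np.ndarray:
    """Alternating +0.5/-0.5 slopes followed by zeros.

    The nonzero count is floor(P * (1 - zero_rate)); at P=25 with a 50%
    zero rate this yields 12 nonzero entries.
    """
    if P <= 0:
        raise ValueError("P must be positive")
    if not 0.0 <= zero_rate < 1.0:
        raise ValueError("zero_rate must lie in [0, 1)")
    n_nonzero = int(math.floor(P * (1.0 - zero_rate)))
    beta = np.zeros(P)
    signs = np.where(np.arange(n_nonzero) % 2 == 0, 0.5, -0.5)
    beta[:n_nonzero] = signs
    return beta


def sim1_phi(P: int, offdiag: float = _PHI_OFFDIAG) -> np.ndarray:
    """Covariate covariance: unit variances, constant pairwise correlation."""
    phi = np.full((P, P), offdiag)
    np.fill_diagonal(phi, 1.0)
    return phi


def _simulate_chain(rng: np.random.Generator, p11: np.ndarray, p21: float, T: int) -> np.ndarray:
    """Simulate the two-state chain from S_1 = 1.

    ``p11`` is (N,) for time-invariant predictors or (N, T) otherwise
    (column t is the stay probability on the transition into occasion t).
    """
    n = p11.shape[0]
    p11_t = p11 if p11.ndim == 2 else np.repeat(p11[:, None], T, axis=1)
    states = np.ones((n, T), dtype=int)
    u = rng.random((n, T))
    for t in range(1, T):
        prev = states[:, t - 1]
        stay1 = u[:, t] < p11_t[:, t]
        back1 = u[:, t] < p21
        states[:, t] = np.where(prev == 1, np.where(stay1, 1, 2), np.where(back1, 1, 2))
    return states


def _simulate_series(
    rng: np.random.Generator,
    states: np.ndarray,
    eta_z: np.ndarray,
    w: WithinParams,
) -> np.ndarray:
    """Simulate the univariate series given the state path (lag at t=1 is 0)."""
    n, T = states.shape
    eps = rng.normal(0.0, w.sigma_eps, size=(n, T))
    y = np.zeros((n, T))
    prev = np.zeros(n)
    for t in range(T):
        in2 = states[:, t] == 2
        mean = np.where(in2, w.a2[0] + w.b2[0, 0] * prev, 0.0) + w.gamma * eta_z[:, t]
        y[:, t] = mean + eps[:, t]
        prev = y[:, t]
    return y


def _within_truth() -> WithinParams:
    return WithinParams(
        a2=[WITHIN_TRUTH["a2"]],
        b2=[[WITHIN_TRUTH["b2"]]],
        gamma=WITHIN_TRUTH["gamma"],
        sigma_eps=WITHIN_TRUTH["sigma_eps"],
    )


def generate_sim1(design: Sim1Design) -> SimulatedDataset:
    """Generate one dataset of the time-invariant study design."""
    rng = np.random.default_rng(design.seed)
    phi = sim1_phi(design.P)
    beta_star = make_beta_star(design.P, design.zero_rate)
    eta_x = rng.multivariate_normal(np.zeros(design.P), phi, size=design.N, method="cholesky")
    eps0 = rng.normal(0.0, design.sigma_eps0, size=design.N)
    eta_z = rng.normal(0.0, 1.0, size=(design.N, design.T))
    eta_tilde = design.beta0 + eta_x @ beta_star + eps0
    p11 = expit(eta_tilde)
    states = _simulate_chain(rng, p11, _P21, design.T)
    within = _within_truth()
    eta_y = _simulate_series(rng, states, eta_z, within)
    between = BetweenParams(
        beta0=design.beta0,
        beta_x=beta_star,
        sigma_eps0=design.sigma_eps0,
        phi_x=phi,
        p21=_P21,
    )
    data = PanelDataset(eta_y=eta_y, eta_x=eta_x, eta_z=eta_z, states=states)
    return SimulatedDataset(
        data=data,
        true_states=states,
        true_beta_star=beta_star,
        true_eps0=eps0,
        true_within=within,
        true_between=between,
        design=design,
    )


def generate_sim2(design: Sim2Design) -> SimulatedDataset:
    """Generate one dataset of the time-varying study design.

    With the time-varying slopes zeroed the generating law reduces to the
    time-invariant design at Q predictors.
    """
    rng = np.random.default_rng(design.seed)
    phi = sim1_phi(design.Q)
    beta_x = np.asarray(design.beta_x, dtype=float)
    beta_xz = np.asarray(design.beta_xz, dtype=float)
    eta_x = rng.multivariate_normal(np.zeros(design.Q), phi, size=design.N, method="cholesky")
    eps0 = rng.normal(0.0, design.sigma_eps0, size=design.N)
    eta_z = rng.normal(0.0, 1.0, size=(design.N, design.T))
    mu0 = design.beta0 + eta_x @ beta_x + eps0
    mu1 = (design.beta_z + eta_x @ beta_xz)[:, None] * eta_z
    p11 = expit(mu0[:, None] + mu1)
    states = _simulate_chain(rng, p11, _P21, design.T)
    within = _within_truth()
    eta_y = _simulate_series(rng, states, eta_z, within)
    between = BetweenParams(
        beta0=design.beta0,
        beta_x=beta_x,
        beta_z=design.beta_z,
        beta_xz=beta_xz,
        sigma_eps0=design.sigma_eps0,
        phi_x=phi,
        p21=_P21,
    )
    beta_star = between.beta_star(include_mu1=True)
    data = PanelDataset(eta_y=eta_y, eta_x=eta_x, eta_z=eta_z, states=states)
    return SimulatedDataset(
        data=data,
        true_states=states,
        true_beta_star=beta_star,
        true_eps0=eps0,
        true_within=within,
        true_between=between,
        design=design,
    )


def compute_snr(beta_star, phi_full, sigma0_sq: float, sigma_s_sq: float) -> float:
    """Design signal-to-noise ratio of the transition predictor.

    The signal is the variance the slopes contribute through the full
    predictor covariance; the noise is the random-intercept variance plus
    the logistic residual variance.
    """
    beta_star = np.asarray(beta_star, dtype=float)
    phi_full = np.asarray(phi_full, dtype=float)
    if phi_full.shape != (beta_star.size, beta_star.size):
        raise ValueError(
            f"phi_full must be ({beta_star.size}, {beta_star.size}), got {phi_full.shape}"
        )
    return float(beta_star @ phi_full @ beta_star / (sigma0_sq + sigma_s_sq))


def sim2_phi_full(design: Sim2Design | None = None, sigma_z_sq: float = 1.0) -> np.ndarray:
    """Blockwise predictor covariance of the time-varying design.

    Blocks: Phi for eta_x, sigma_z^2 for eta_z, Phi * sigma_z^2 for the
    interactions; cross-block covariances vanish by symmetry.
    """
    design = design or Sim2Design()
    phi = sim1_phi(design.Q)
    q = design.Q
    full = np.zeros((design.P, design.P))
    full[:q, :q] = phi
    full[q, q] = sigma_z_sq
    full[q + 1 :, q + 1 :] = phi * sigma_z_sq
    return full


def sim1_snr(P: int, zero_rate: float = 0.5, sigma_eps0: float = _SIGMA_EPS0) -> float:
    """SNR of a time-invariant design cell."""
    beta = make_beta_star(P, zero_rate)
    return compute_snr(beta, sim1_phi(P), sigma_eps0**2, LOGISTIC_VARIANCE)


def sim2_snr(design: Sim2Design | None = None) -> float:
    design = design or Sim2Design()
    beta = np.concatenate(
        [np.asarray(design.beta_x), [design.beta_z], np.asarray(design.beta_xz)]
    )
    return compute_snr(beta, sim2_phi_full(design), design.sigma_eps0**2, LOGISTIC_VARIANCE)
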
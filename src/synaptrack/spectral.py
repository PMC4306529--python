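"""Frequency-domain forward model: transfer functions and predicted cross-spectra.

The delayed neural mass system is linearised about its fixed point.  Because
the sigmoid is centred, the unforced fixed point is the origin and the
linearisation depends only on the parameters.  Conduction delays enter the
frequency-domain system matrix as exact phase factors ``exp(-i*omega*tau)`` on
the delayed coupling blocks (no Taylor approximation), so the transfer
function from the endogenous drive of each source to each channel is

    T(f) = C (i 2 pi f I - A0 - Ai e^{-i 2 pi f tau_i} - Ae e^{-i 2 pi f tau_e})^{-1} B

The predicted cross-spectral density over channels is then

    G_y(f) = T(f) G_u(f) T(f)^H + G_n(f)

with ``G_u`` the power-law spectrum of the endogenous neuronal fluctuations
(independent across sources by default) and ``G_n`` a measurement-noise
spectrum with a common and a channel-specific power-law component.  ``G_y`` is
Hermitian with real non-negative neuronal diagonal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .neural_mass import (
    coupling_matrices,
    equations_of_motion,
    extrinsic_connections,
    sigmoid_gain,
)
from .priors import SP, SS, EffectiveParams

__all__ = [
    "FrequencyGrid",
    "SpectralConfig",
    "StateSpace",
    "UnstableModelError",
    "FixedPointError",
    "fixed_point",
    "jacobian",
    "transfer_function",
    "powerlaw_spectrum",
    "predict_csd",
    "csd_is_hermitian",
]


class UnstableModelError(RuntimeError):
    """Linearised system is not stable at the given parameters."""


class FixedPointError(RuntimeError):
    """Root finding for the fixed point did not converge."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing analysis frequencies in Hz."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be a strictly increasing 1-d grid")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """1-Hz bins over the 8-48 Hz band (41 bins)."""
        return cls(np.arange(8.0, 49.0))

    @property
    def n(self) -> int:
        return self.freqs.size


@dataclass
class SpectralConfig:
    """Fixed scales of the spectral observation model.

    ``input_scale`` multiplies the endogenous input spectrum,
    ``noise_common_scale`` the common measurement-noise component, and the
    channel-specific noise is ``noise_specific_ratio`` times the common one.
    ``shared_input_frac`` mixes a component of the endogenous drive that is
    common to all sources (0 = fully independent drives).
    """

    input_scale: float = 1.0
    noise_common_scale: float = 1.0 / 16
    noise_specific_ratio: float = 0.5
    shared_input_frac: float = 0.0


DEFAULT_SPECTRAL = SpectralConfig()


@dataclass
class StateSpace:
    """Linearised delay system ``dz/dt = A0 z + Ai z(t-tau_i) + Ae z(t-tau_e) + B u``."""

    A0: np.ndarray
    Ai: np.ndarray
    Ae: np.ndarray
    B: np.ndarray
    C: np.ndarray
    tau_i: float  # s
    tau_e: float  # s

    @property
    def n(self) -> int:
        return self.A0.shape[0]

    def zero_frequency_matrix(self) -> np.ndarray:
        """System matrix with the delay terms evaluated at zero frequency."""
        return self.A0 + self.Ai + self.Ae

    def max_real_eigenvalue(self) -> float:
        return float(np.max(np.linalg.eigvals(self.zero_frequency_matrix()).real))


def fixed_point(
    eff: EffectiveParams,
    conn=None,
    drive: float | np.ndarray = 0.0,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Solve the unforced (constant-input) motion equations for a root.

    With the centred sigmoid and zero drive the origin is a fixed point; the
    solver is still run so that non-zero constant inputs are supported.  At a
    fixed point the delayed states equal the current ones, so delays drop out.
    """
    n_s = eff.n_sources
    if conn is None:
        conn = extrinsic_connections("forward", n_s)
    dr = np.broadcast_to(np.asarray(drive, dtype=float), (n_s,))

    def fun(state):
        n = 4 * n_s
        v = state[:n]
        return equations_of_motion(state, lambda tau: v, eff, dr, conn)

    start = np.zeros(8 * n_s) if x0 is None else np.asarray(x0, dtype=float)
    sol = scipy.optimize.root(fun, start, method="hybr", tol=tol)
    resid = np.linalg.norm(fun(sol.x))
    if not sol.success or resid > 1e-9:
        raise FixedPointError(
            f"fixed-point search failed (residual {resid:.2e}); the parameter "
            "set may be unstable or invalid"
        )
    x = sol.x.copy()
    x[np.abs(x) < 1e-14] = 0.0
    return x


def jacobian(eff: EffectiveParams, x_star: np.ndarray | None = None, conn=None) -> StateSpace:
    """Linearise the delay system about a fixed point.

    Returns the state-space matrices with the delayed couplings kept in
    separate blocks (``Ai`` intrinsic, ``Ae`` extrinsic) so that delays can be
    applied exactly in the frequency domain.  The output map ``C`` selects the
    superficial-pyramidal depolarisation of each source scaled by electrode
    gain; ``B`` injects the endogenous drive into the input-cell equations.
    """
    n_s = eff.n_sources
    n = 4 * n_s
    if conn is None:
        conn = extrinsic_connections("forward", n_s)
    if x_star is None:
        x_star = np.zeros(2 * n)
    v_star = np.asarray(x_star, dtype=float)[:n]

    Wi, We = coupling_matrices(eff, conn)
    gain_v = sigmoid_gain(v_star, eff.gamma)  # dS/dv at the expansion point
    kap = np.broadcast_to(eff.kappa, (n_s, 4)).ravel()

    A0 = np.zeros((2 * n, 2 * n))
    A0[:n, n:] = np.eye(n)
    A0[n:, :n] = -np.diag(kap**2)
    A0[n:, n:] = -2.0 * np.diag(kap)

    Ai = np.zeros((2 * n, 2 * n))
    Ai[n:, :n] = kap[:, None] * Wi * gain_v[None, :]
    Ae = np.zeros((2 * n, 2 * n))
    Ae[n:, :n] = kap[:, None] * We * gain_v[None, :]

    B = np.zeros((2 * n, n_s))
    for s in range(n_s):
        B[n + s * 4 + SS, s] = kap[s * 4 + SS]

    n_ch = eff.n_channels
    C = np.zeros((n_ch, 2 * n))
    for c in range(n_ch):
        C[c, c * 4 + SP] = eff.gain[c]

    return StateSpace(
        A0=A0,
        Ai=Ai,
        Ae=Ae,
        B=B,
        C=C,
        tau_i=eff.delay_intrinsic * 1e-3,
        tau_e=eff.delay_extrinsic * 1e-3,
    )


def transfer_function(ss: StateSpace, grid: FrequencyGrid, check_stability: bool = True) -> np.ndarray:
    """Modulation transfer functions ``T(f)``, shape ``(n_f, n_ch, n_src)``.

    Delays enter as exact phase factors on the delayed coupling blocks.  A
    positive real eigenvalue of the zero-frequency system matrix raises
    :class:`UnstableModelError`; a numerically singular resolvent at some
    frequency signals marginal instability and is reported likewise.
    """
    if check_stability and ss.max_real_eigenvalue() > 0:
        raise UnstableModelError(
            f"max real eigenvalue {ss.max_real_eigenvalue():.3g} > 0"
        )
    f = grid.freqs
    s = 2j * np.pi * f
    ph_i = np.exp(-s * ss.tau_i)
    ph_e = np.exp(-s * ss.tau_e)
    n = ss.n
    A = (
        ss.A0[None, :, :]
        + ph_i[:, None, None] * ss.Ai[None, :, :]
        + ph_e[:, None, None] * ss.Ae[None, :, :]
    )
    M = s[:, None, None] * np.eye(n)[None, :, :] - A
    try:
        X = np.linalg.solve(M, np.broadcast_to(ss.B, (f.size, *ss.B.shape)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - marginal cases
        raise UnstableModelError(f"singular resolvent: {exc}") from exc
    return ss.C[None, :, :] @ X


def powerlaw_spectrum(amp: float, exponent: float, grid: FrequencyGrid) -> np.ndarray:
    """Power-law spectrum ``amp * f**(-exponent)`` on the grid."""
    if amp < 0:
        raise ValueError("amplitude must be non-negative")
    return amp * grid.freqs ** (-exponent)


def predict_csd(
    eff: EffectiveParams,
    grid: FrequencyGrid | None = None,
    architecture: str = "forward",
    config: SpectralConfig = DEFAULT_SPECTRAL,
    conn=None,
    transfer: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted channel cross-spectral density, shape ``(n_f, n_ch, n_ch)``.

    ``transfer`` may be supplied (with unit gains already folded into ``C`` or
    not -- here it must be the gain-scaled transfer function) to reuse a cached
    linearisation; otherwise the model is linearised about the origin.
    """
    if grid is None:
        grid = FrequencyGrid.default()
    if transfer is None:
        if conn is None:
            conn = extrinsic_connections(architecture, eff.n_sources)
        ssp = jacobian(eff, conn=conn)
        transfer = transfer_function(ssp, grid)
    T = transfer  # (n_f, n_ch, n_src)
    f = grid.freqs
    gu = config.input_scale * powerlaw_spectrum(eff.input_amp, eff.input_exp, grid)
    n_src = T.shape[2]
    rho = config.shared_input_frac
    Gu = gu[:, None, None] * ((1.0 - rho) * np.eye(n_src) + rho)[None, :, :]
    S = T @ Gu @ T.conj().transpose(0, 2, 1)

    gn = config.noise_common_scale * powerlaw_spectrum(eff.noise_amp, eff.noise_exp, grid)
    n_ch = T.shape[1]
    S = S + gn[:, None, None] * np.ones((n_ch, n_ch))[None, :, :]
    S = S + (config.noise_specific_ratio * gn)[:, None, None] * np.eye(n_ch)[None, :, :]
    return 0.5 * (S + S.conj().transpose(0, 2, 1))


def csd_is_hermitian(csd: np.ndarray, atol: float = 1e-10) -> bool:
    """Check the structural invariants of a CSD stack.

    Hermitian at every frequency with real, non-negative diagonal.
    """
    herm = np.allclose(csd, csd.conj().swapaxes(-1, -2), atol=atol)
    diags = np.diagonal(csd, axis1=-2, axis2=-1)
    return bool(herm and np.all(np.abs(diags.imag) < atol) and np.all(diags.real >= -atol))
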
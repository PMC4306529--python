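"""Canonical-microcircuit neural mass dynamics and a delay-aware integrator.

Each of the four populations of a source obeys a second-order (convolution)
synaptic model

    dv/dt = x
    dx/dt = kappa * u - 2 * kappa * x - kappa**2 * v

where ``v`` is mean depolarisation, ``kappa`` the population's synaptic rate
constant, and ``u`` the total presynaptic drive: signed connection strengths
times a sigmoid transform of the *delayed* presynaptic depolarisation, plus
endogenous input to the input cells.  Intrinsic couplings are delayed by the
intrinsic conduction delay (~1 ms), extrinsic couplings by the extrinsic one
(~8 ms), so the full system is a delay differential equation.

The sigmoid is the centred logistic ``1/(1+exp(-slope*v)) - 1/2``; it vanishes
at ``v = 0``, which makes the origin a fixed point of the unforced system and
lets the spectral module linearise around a known expansion point.

The integrator (`integrate`) uses a fixed-step Heun (RK2) scheme with a ring
buffer of past depolarisations and linear interpolation for the delayed
states.  It is deliberately simple and bit-reproducible for a fixed seed: it
serves as the simulation oracle against which the frequency-domain predictions
are validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .priors import (
    BACKWARD_SOURCE,
    BACKWARD_TARGETS,
    FORWARD_SOURCE,
    FORWARD_TARGETS,
    INTRINSIC_EDGES,
    SS,
    SP,
    EffectiveParams,
)

__all__ = [
    "sigmoid_response",
    "sigmoid_gain",
    "extrinsic_connections",
    "coupling_matrices",
    "equations_of_motion",
    "integrate",
    "powerlaw_drive",
    "SimResult",
    "IntegrationDivergence",
]


class IntegrationDivergence(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


def sigmoid_response(v, slope):
    """Centred logistic firing-rate response, in (-1/2, 1/2).

    Odd in ``v`` and zero at ``v = 0``; ``slope`` is the intrinsic gain.
    """
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-slope * np.asarray(v, dtype=float))) - 0.5


def sigmoid_gain(v, slope):
    """Derivative of :func:`sigmoid_response` with respect to ``v``."""
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-slope * np.asarray(v, dtype=float)))
    return slope * s * (1.0 - s)


def extrinsic_connections(architecture: str, n_sources: int = 2):
    """Between-source connection list ``[(origin, target, kind), ...]``.

    ``architecture == "forward"``: the forward-type connection originates in
    the primary source (index 0) and targets the secondary source, with a
    reciprocal backward connection from secondary to primary.
    ``"backward"`` is the mirror image.
    """
    if n_sources == 1:
        return []
    if n_sources != 2:
        raise ValueError("only 1- or 2-source architectures are wired")
    if architecture == "forward":
        return [(0, 1, "forward"), (1, 0, "backward")]
    if architecture == "backward":
        return [(0, 1, "backward"), (1, 0, "forward")]
    raise ValueError(f"unknown architecture {architecture!r}")


def coupling_matrices(eff: EffectiveParams, conn) -> tuple[np.ndarray, np.ndarray]:
    """Signed coupling-rate matrices (intrinsic, extrinsic).

    Each is ``(4*n_sources, 4*n_sources)``, mapping presynaptic sigmoid output
    (indexed by source*4+population) to the synaptic input ``u`` of each
    population.  Entries carry the signed connection strengths in Hz.
    """
    n_s = eff.n_sources
    n = 4 * n_s
    Wi = np.zeros((n, n))
    We = np.zeros((n, n))
    for s in range(n_s):
        for e, (tgt, src, sign, _rate) in enumerate(INTRINSIC_EDGES):
            Wi[s * 4 + tgt, s * 4 + src] += sign * eff.intrinsic[s, e]
    kind_idx = {"forward": 0, "backward": 1}
    kind_src = {"forward": FORWARD_SOURCE, "backward": BACKWARD_SOURCE}
    kind_tgt = {"forward": FORWARD_TARGETS, "backward": BACKWARD_TARGETS}
    for origin, target, kind in conn:
        a = eff.extrinsic[kind_idx[kind]]
        src_pop = kind_src[kind]
        for tpop, w in kind_tgt[kind]:
            We[target * 4 + tpop, origin * 4 + src_pop] += w * a
    return Wi, We


def equations_of_motion(state, delayed_v, eff: EffectiveParams, drive, conn=None):
    """Time derivatives of the full state vector.

    Parameters
    ----------
    state : array, shape (8 * n_sources,)
        ``[v (4*n_s), x (4*n_s)]`` with ``v`` in mV and ``x = dv/dt``.
    delayed_v : callable
        ``delayed_v(tau_s) -> array (4*n_s,)`` giving the depolarisations at
        ``t - tau`` (``tau`` in seconds).
    eff : EffectiveParams
        Natural-scale parameters.
    drive : array, shape (n_sources,)
        Exogenous input to the input cells of each source.
    conn : list, optional
        Extrinsic connection list; defaults to the forward-from-primary wiring.
    """
    n_s = eff.n_sources
    n = 4 * n_s
    state = np.asarray(state, dtype=float)
    if state.shape != (2 * n,):
        raise ValueError(f"state must have length {2 * n}, got {state.shape}")
    if conn is None:
        conn = extrinsic_connections("forward", n_s)
    Wi, We = coupling_matrices(eff, conn)
    v = state[:n]
    x = state[n:]
    tau_i = eff.delay_intrinsic * 1e-3
    tau_e = eff.delay_extrinsic * 1e-3
    u = Wi @ sigmoid_response(delayed_v(tau_i), eff.gamma)
    if np.any(We):
        u = u + We @ sigmoid_response(delayed_v(tau_e), eff.gamma)
    u = u.reshape(n_s, 4)
    u[:, SS] += np.asarray(drive, dtype=float)
    kap = np.broadcast_to(eff.kappa, (n_s, 4)).ravel()
    dv = x
    dx = kap * u.ravel() - 2.0 * kap * x - kap**2 * v
    return np.concatenate([dv, dx])


def powerlaw_drive(
    n_steps: int,
    dt: float,
    amp: float,
    exponent: float,
    rng: np.random.Generator,
    f_min: float = 0.5,
) -> np.ndarray:
    """Gaussian series with one-sided power spectral density ``amp * f**-exponent``.

    Synthesised in the frequency domain (band-limited below ``f_min`` to avoid
    the power-law divergence at DC) and therefore exactly reproducible for a
    given generator state.
    """
    freqs = np.fft.rfftfreq(n_steps, dt)
    psd = np.zeros_like(freqs)
    band = freqs >= f_min
    psd[band] = amp * freqs[band] ** (-exponent)
    # one-sided PSD -> rfft coefficient scale
    scale = np.sqrt(psd * n_steps / (2.0 * dt))
    coef = scale * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    coef[0] = 0.0
    if n_steps % 2 == 0:
        coef[-1] = coef[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coef, n=n_steps)


@dataclass
class SimResult:
    """Output of :func:`integrate`."""

    t: np.ndarray  # (n_steps,) seconds
    channels: np.ndarray  # (n_channels, n_steps) observed depolarisations
    states: np.ndarray | None = None  # (n_steps, 8*n_sources) if requested
    dt: float = 0.0


def integrate(
    eff: EffectiveParams,
    duration: float,
    dt: float = 5e-4,
    drive: np.ndarray | None = None,
    seed: int | None = None,
    conn=None,
    x0: np.ndarray | None = None,
    return_states: bool = False,
) -> SimResult:
    """Integrate the delayed neural mass model with a fixed-step Heun scheme.

    Observed channels are the superficial-pyramidal depolarisations of each
    source scaled by the electrode gains.  ``drive`` may be supplied as an
    ``(n_steps, n_sources)`` array; otherwise a seeded power-law drive with the
    model's endogenous input spectrum is generated.  ``dt`` (seconds) must be
    smaller than the smallest conduction delay.
    """
    n_s = eff.n_sources
    n = 4 * n_s
    tau_i = eff.delay_intrinsic * 1e-3
    tau_e = eff.delay_extrinsic * 1e-3
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt >= min(tau_i, tau_e):
        raise ValueError("dt must be smaller than the smallest delay")
    if conn is None:
        conn = extrinsic_connections("forward", n_s)
    n_steps = int(round(duration / dt))
    if drive is None:
        rng = np.random.default_rng(seed)
        drive = np.column_stack(
            [
                powerlaw_drive(n_steps, dt, eff.input_amp, eff.input_exp, rng)
                for _ in range(n_s)
            ]
        )
    drive = np.asarray(drive, dtype=float)
    if drive.shape != (n_steps, n_s):
        raise ValueError(f"drive must have shape {(n_steps, n_s)}")

    Wi, We = coupling_matrices(eff, conn)
    kap = np.broadcast_to(eff.kappa, (n_s, 4)).ravel()
    kap2 = kap**2
    gamma = eff.gamma
    has_ext = bool(np.any(We))

    max_tau = max(tau_i, tau_e)
    buf_len = int(np.ceil(max_tau / dt)) + 3
    hist = np.zeros((buf_len, n))  # past v values on the step grid

    if x0 is None:
        state = np.zeros(2 * n)
    else:
        state = np.asarray(x0, dtype=float).copy()
        if state.shape != (2 * n,):
            raise ValueError("x0 has wrong length")
    hist[:] = state[:n]

    # fractional-step offsets for delayed lookups (delays need not be integer
    # multiples of dt; linear interpolation in the ring buffer)
    off_i, frac_i = divmod(tau_i / dt, 1.0)
    off_e, frac_e = divmod(tau_e / dt, 1.0)
    off_i, off_e = int(off_i), int(off_e)

    def delayed(i_now: int, off: int, frac: float, extra: float) -> np.ndarray:
        # v at time (i_now + extra)*dt - tau, with extra in {0, 1}
        pos = i_now + extra - off - frac
        i0 = int(np.floor(pos))
        w = pos - i0
        a = hist[i0 % buf_len]
        b = hist[(i0 + 1) % buf_len]
        return a + w * (b - a)

    ss_rows = np.arange(n_s) * 4 + SS
    sp_rows = np.arange(n_s) * 4 + SP
    channels = np.empty((eff.n_channels, n_steps))
    states = np.empty((n_steps, 2 * n)) if return_states else None
    t = np.arange(n_steps) * dt

    def deriv(v, x, vd_i, vd_e, dr):
        u = Wi @ sigmoid_response(vd_i, gamma)
        if has_ext:
            u = u + We @ sigmoid_response(vd_e, gamma)
        u[ss_rows] += dr
        return kap * u - 2.0 * kap * x - kap2 * v

    for i in range(n_steps):
        v = state[:n]
        x = state[n:]
        hist[i % buf_len] = v

        channels[:, i] = eff.gain * v[sp_rows][: eff.n_channels]
        if return_states:
            states[i] = state

        dr0 = drive[i]
        dr1 = drive[i + 1] if i + 1 < n_steps else drive[i]
        k1v = x
        k1x = deriv(v, x, delayed(i, off_i, frac_i, 0.0), delayed(i, off_e, frac_e, 0.0), dr0)
        v1 = v + dt * k1v
        x1 = x + dt * k1x
        k2v = x1
        k2x = deriv(v1, x1, delayed(i, off_i, frac_i, 1.0), delayed(i, off_e, frac_e, 1.0), dr1)
        state = np.concatenate([v + 0.5 * dt * (k1v + k2v), x + 0.5 * dt * (k1x + k2x)])

        if i % 200 == 0 and not np.all(np.isfinite(state)):
            raise IntegrationDivergence(
                f"state diverged at t={i * dt:.3f}s; parameters: kappa={eff.kappa}, "
                f"intrinsic={eff.intrinsic.tolist()}, extrinsic={eff.extrinsic.tolist()}"
            )

    if not np.all(np.isfinite(state)):
        raise IntegrationDivergence("state diverged at end of integration")
    return SimResult(t=t, channels=channels, states=states, dt=dt)
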
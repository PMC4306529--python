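"""Candidate change-models, temporal bases, model comparison and trajectories.

A candidate model fixes (i) the extrinsic architecture -- whether the
connection originating in the primary source is of forward or backward laminar
type -- and (ii) which of four couplings may drift across time windows: the
superficial-pyramidal self-inhibition gain in each source, the forward
strength, and the backward strength.  All 2^4 = 16 flag combinations define
the change-model space.

Window-to-window drift is parameterised by low-order polynomials of time,
independently per segment (pre-onset and post-onset), so trajectories may jump
at onset.  Bases are orthonormalised per segment for identifiability.

Model comparison is fixed-effects: log evidences (variational free energies)
add over sessions, and posterior model probabilities are softmax of the pooled
values.  Bayesian updating carries one session's posterior over the static
parameters into the next session's prior, resetting session-specific
parameters (electrode gain) and the drift coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .priors import SP_SELF, CMCParameters, PriorSpec

__all__ = [
    "FLAG_NAMES",
    "FLAG_TARGETS",
    "ModelSpec",
    "ComparisonResult",
    "Trajectory",
    "temporal_basis",
    "enumerate_models",
    "expand_parameters",
    "compare_models",
    "bayesian_update",
    "extract_trajectories",
]

#: Couplings that may change over windows, in model-id bit order (MSB first).
FLAG_NAMES = ("intrinsic_primary", "intrinsic_secondary", "forward", "backward")

#: Parameter-block entry targeted by each flag.
FLAG_TARGETS = {
    "intrinsic_primary": ("intrinsic", (0, SP_SELF)),
    "intrinsic_secondary": ("intrinsic", (1, SP_SELF)),
    "forward": ("extrinsic", (0,)),
    "backward": ("extrinsic", (1,)),
}

Z90 = float(scipy.stats.norm.ppf(0.95))  # two-sided 90% interval half-width in sd


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: architecture, change flags, temporal-basis order."""

    architecture: str = "forward"  # forward- or backward-from-primary
    flags: tuple[bool, bool, bool, bool] = (True, True, True, True)
    order: int = 3
    n_pre: int = 9
    n_post: int = 9

    def __post_init__(self) -> None:
        if self.architecture not in ("forward", "backward"):
            raise ValueError("architecture must be 'forward' or 'backward'")
        if len(self.flags) != len(FLAG_NAMES):
            raise ValueError(f"need {len(FLAG_NAMES)} change flags")

    @property
    def model_id(self) -> str:
        bits = "".join("1" if f else "0" for f in self.flags)
        return f"{self.architecture[:3]}-{bits}"

    @property
    def flagged(self) -> list[str]:
        return [n for n, f in zip(FLAG_NAMES, self.flags) if f]

    @property
    def n_windows(self) -> int:
        return self.n_pre + self.n_post

    def basis(self) -> np.ndarray:
        return temporal_basis(self.n_pre, self.n_post, self.order)


def temporal_basis(n_windows_pre: int, n_windows_post: int, order: int) -> np.ndarray:
    """Block design matrix mapping basis coefficients to per-window deviations.

    Independent orthonormalised polynomial bases (constant .. ``order``) per
    segment, assembled block-diagonally: shape
    ``(n_pre + n_post, 2 * (order + 1))``, full column rank.  The per-segment
    blocks allow a discontinuity at the segment boundary (onset).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    blocks = []
    for n in (n_windows_pre, n_windows_post):
        if n < order + 1:
            raise ValueError(f"segment of {n} windows cannot support order {order}")
        t = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
        V = np.vander(t, order + 1, increasing=True)
        Q, R = np.linalg.qr(V)
        Q = Q * np.sign(np.diag(R))[None, :]  # leading coefficient positive
        blocks.append(Q)
    X = scipy.linalg.block_diag(*blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient temporal basis")
    return X


def enumerate_models(
    order: int = 3,
    architecture: str = "forward",
    n_pre: int = 9,
    n_post: int = 9,
) -> list[ModelSpec]:
    """All 16 flag combinations, in deterministic binary-counting order.

    Model ``m`` has flag bits ``(m >> 3, m >> 2, m >> 1, m) & 1`` for
    (intrinsic primary, intrinsic secondary, forward, backward); ``m = 0`` is
    the null (no-change) model and ``m = 15`` the saturated one.
    """
    out = []
    for m in range(2 ** len(FLAG_NAMES)):
        flags = tuple(bool((m >> (len(FLAG_NAMES) - 1 - k)) & 1) for k in range(len(FLAG_NAMES)))
        out.append(
            ModelSpec(architecture=architecture, flags=flags, order=order, n_pre=n_pre, n_post=n_post)
        )
    return out


def expand_parameters(
    base: CMCParameters,
    coefficients: dict[str, np.ndarray],
    basis: np.ndarray,
    flags: dict[str, bool] | None = None,
) -> list[CMCParameters]:
    """Per-window parameter sets: flagged log-scalings get ``basis @ coefs`` added.

    Unflagged parameters are identical (bit-for-bit) across windows.
    """
    n_w = basis.shape[0]
    for name, coef in coefficients.items():
        if name not in FLAG_TARGETS:
            raise ValueError(f"unknown changing parameter {name!r}")
        if flags is not None and not flags.get(name, False):
            raise ValueError(f"coefficients supplied for unflagged parameter {name!r}")
        if np.shape(coef) != (basis.shape[1],):
            raise ValueError(f"coefficients for {name!r} do not conform to the basis")
    out = []
    for w in range(n_w):
        p = base.copy()
        for name, coef in coefficients.items():
            block, idx = FLAG_TARGETS[name]
            p.add(block, idx, float(basis[w] @ np.asarray(coef)))
        out.append(p)
    return out


@dataclass
class ComparisonResult:
    """Fixed-effects pooled evidence and posterior model probabilities."""

    pooled: dict[str, float]  # model id -> summed log evidence (nats)
    probabilities: dict[str, float]  # over included models, sums to 1
    excluded: dict[str, str] = field(default_factory=dict)  # model id -> reason

    @property
    def winner(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "pooled_log_evidence": self.pooled[m],
                "posterior_probability": self.probabilities[m],
            }
            for m in sorted(self.pooled, key=self.pooled.get, reverse=True)
        ]
        for m, why in self.excluded.items():
            rows.append(
                {"model": m, "pooled_log_evidence": np.nan, "posterior_probability": 0.0, "excluded": why}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.table().to_csv(path, index=False)


def compare_models(evidences: dict[str, list[float] | None]) -> ComparisonResult:
    """Pool per-session log evidences (fixed effects) and normalise.

    A model with a missing/non-finite session evidence (e.g. a non-convergent
    inversion) is excluded rather than imputed; probabilities are computed over
    the included models only and are invariant to adding a constant to every
    pooled evidence.
    """
    pooled: dict[str, float] = {}
    excluded: dict[str, str] = {}
    n_sessions = None
    for m, Fs in evidences.items():
        if Fs is None:
            excluded[m] = "no evidence supplied"
            continue
        Fs = list(Fs)
        if n_sessions is None:
            n_sessions = len(Fs)
        if len(Fs) != n_sessions:
            excluded[m] = f"evidence for {len(Fs)}/{n_sessions} sessions"
            continue
        if not all(np.isfinite(Fs)):
            excluded[m] = "non-finite evidence (non-convergent inversion)"
            continue
        pooled[m] = float(np.sum(Fs))
    if not pooled:
        raise ValueError("no model has a complete set of finite evidences")
    vals = np.array(list(pooled.values()))
    p = np.exp(vals - vals.max())
    p /= p.sum()
    probabilities = {m: float(pi) for m, pi in zip(pooled, p)}
    return ComparisonResult(pooled=pooled, probabilities=probabilities, excluded=excluded)


def bayesian_update(
    posterior,
    priors: PriorSpec,
    reset_blocks: tuple[str, ...] = ("gain",),
    carry_joint: bool = True,
) -> PriorSpec:
    """Build the next session's priors from this session's posterior.

    Static (base) parameters are carried: their log-scaling prior means and
    variances are set from the posterior, with the joint covariance sub-block
    retained so that sequential updating reproduces a joint inversion for
    linear models.  Blocks in ``reset_blocks`` (by default the electrode gain,
    which may change between sessions) and the per-window drift coefficients
    revert to the original priors.
    """
    if not getattr(posterior, "converged", True):
        raise ValueError("refusing to update from a non-converged posterior")
    new = priors.copy()
    carried: list[tuple[str, tuple]] = []
    carried_pos: list[int] = []
    for i, (block, idx) in enumerate(posterior.base_entries):
        if block in reset_blocks:
            continue
        new.log_means[block][idx] = posterior.mean[i]
        new.variances[block][idx] = posterior.cov[i, i]
        carried.append((block, idx))
        carried_pos.append(i)
    if carry_joint and carried:
        sub = posterior.cov[np.ix_(carried_pos, carried_pos)]
        new.joint = (carried, 0.5 * (sub + sub.T))
    return new


@dataclass
class Trajectory:
    """Posterior trajectories of the changing log-scalings, with 90% intervals."""

    params: dict[str, dict[str, np.ndarray]]  # name -> {mean, lo90, hi90}
    times: np.ndarray  # window centre times (s), onset at 0
    label: str = ""

    def __post_init__(self) -> None:
        for name, tr in self.params.items():
            if not (np.all(tr["lo90"] <= tr["mean"] + 1e-12) and np.all(tr["mean"] <= tr["hi90"] + 1e-12)):
                raise ValueError(f"interval bounds do not bracket the mean for {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, tr in self.params.items():
            for w in range(self.times.size):
                rows.append(
                    {
                        "session": self.label,
                        "window": w,
                        "time_s": self.times[w],
                        "parameter": name,
                        "mean": tr["mean"][w],
                        "lo90": tr["lo90"][w],
                        "hi90": tr["hi90"][w],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_trajectories(posterior, model: ModelSpec, basis: np.ndarray | None = None, label: str = "") -> Trajectory:
    """Per-window posterior mean and 90% credible band of each changing coupling.

    The trajectory of a flagged coupling is its static log-scaling plus the
    basis-projected drift coefficients; the variance is propagated through
    this linear map using the full posterior covariance (so static/drift
    correlations are honoured).  Intervals are Gaussian: mean +- 1.645 sd.
    """
    if basis is None:
        basis = model.basis()
    n_w = basis.shape[0]
    n = posterior.mean.size
    params: dict[str, dict[str, np.ndarray]] = {}
    for name in model.flagged:
        L = np.zeros((n_w, n))
        block, idx = FLAG_TARGETS[name]
        base_pos = posterior.index_of(block, idx)
        if base_pos is not None:
            L[:, base_pos] = 1.0
        sl = posterior.coef_slice(name)
        if sl is not None:
            L[:, sl] = basis
        mean = L @ posterior.mean
        sd = np.sqrt(np.maximum(np.einsum("wi,ij,wj->w", L, posterior.cov, L), 0.0))
        params[name] = {"mean": mean, "lo90": mean - Z90 * sd, "hi90": mean + Z90 * sd}
    times = _window_times(model)
    return Trajectory(params=params, times=times, label=label)


def _window_times(model: ModelSpec) -> np.ndarray:
    """Window centre times with onset at 0 and 1-s spacing by convention."""
    pre = np.arange(model.n_pre) - float(model.n_pre)
    post = np.arange(model.n_post)
    return np.concatenate([pre, post])
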
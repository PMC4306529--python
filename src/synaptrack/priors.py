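"""Priors and log-scaling parameterisation of the two-source canonical microcircuit.

Every biophysical parameter is expressed as a positive prior-mean value on its
natural scale (rates in Hz, delays in ms) together with a dimensionless
log-scaling deviation ``theta``, so that the effective value is
``mean * exp(theta)``.  Gaussian priors are placed on ``theta`` (usually with
mean 0); a prior variance of zero fixes a parameter at its prior mean.  This
keeps every rate and delay strictly positive for any real ``theta`` and makes
deviations directly comparable across parameters of very different magnitude.

The intrinsic circuit of a single source has four populations:

* input cells (spiny-stellate-like, ``ss``) -- receive endogenous fluctuations
  and forward extrinsic afferents,
* superficial pyramidal cells (``sp``) -- originate forward connections and the
  measured depolarisation,
* inhibitory interneurons (``ii``),
* deep pyramidal cells (``dp``) -- originate backward connections.

The signed intrinsic wiring (10 edges per source) and the laminar targets of
extrinsic forward/backward connections live in the module-level tables below;
they are data, not code, so alternative circuits can be configured without
touching the dynamics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "POPULATIONS",
    "SS",
    "SP",
    "II",
    "DP",
    "INTRINSIC_EDGES",
    "SP_SELF",
    "FORWARD_SOURCE",
    "FORWARD_TARGETS",
    "BACKWARD_SOURCE",
    "BACKWARD_TARGETS",
    "PriorSpec",
    "CMCParameters",
    "EffectiveParams",
    "default_priors",
    "effective_value",
    "block_shapes",
]

POPULATIONS = ("ss", "sp", "ii", "dp")
SS, SP, II, DP = range(4)

#: Intrinsic wiring of one source: (target population, presynaptic population,
#: sign, prior-mean rate in Hz).  Negative signs are effective inhibitory
#: connections (some of which absorb unmodelled interneuron relays).
INTRINSIC_EDGES: tuple[tuple[int, int, float, float], ...] = (
    (SS, SS, -1.0, 800.0),
    (SS, SP, -1.0, 800.0),
    (SS, II, -1.0, 1600.0),
    (II, II, -1.0, 800.0),
    (II, SS, +1.0, 800.0),
    (II, DP, +1.0, 400.0),
    (SP, SP, -1.0, 800.0),  # recurrent self-inhibition of superficial pyramids
    (SP, SS, +1.0, 800.0),
    (DP, II, -1.0, 400.0),
    (DP, DP, -1.0, 200.0),
)

#: Index (into ``INTRINSIC_EDGES``) of the tracked intrinsic gain: the
#: inhibitory recurrent (self) connection of superficial pyramidal cells.
SP_SELF = 6

N_INTRINSIC = len(INTRINSIC_EDGES)

#: Laminar pattern of extrinsic connections: forward connections originate in
#: superficial pyramidal cells and target input cells and deep pyramids;
#: backward connections originate in deep pyramidal cells and target
#: superficial pyramids (net inhibitory, via absorbed interneurons) and
#: inhibitory interneurons.  Weights multiply the (shared) connection strength.
FORWARD_SOURCE = SP
FORWARD_TARGETS: tuple[tuple[int, float], ...] = ((SS, +1.0), (DP, +1.0))
BACKWARD_SOURCE = DP
BACKWARD_TARGETS: tuple[tuple[int, float], ...] = ((SP, -1.0), (II, +1.0))

#: Synaptic rate constants kappa per population (Hz): 1000/2, 1000/2, 1000/16,
#: 1000/28 for ss, sp, ii, dp.
KAPPA_MEANS = np.array([1000.0 / 2, 1000.0 / 2, 1000.0 / 16, 1000.0 / 28])


def block_shapes(n_sources: int = 2, n_channels: int = 2) -> dict[str, tuple]:
    """Array shape of each named parameter block."""
    return {
        "intrinsic": (n_sources, N_INTRINSIC),
        "extrinsic": (2,),  # [forward, backward] strengths
        "kappa": (4,),
        "gamma": (),
        "delay_intrinsic": (),
        "delay_extrinsic": (),
        "input_amp": (),
        "input_exp": (),
        "noise_amp": (),
        "noise_exp": (),
        "gain": (n_channels,),
    }


BLOCK_NAMES = tuple(block_shapes())


def effective_value(prior_mean: float, log_scaling: float) -> float:
    """Natural-scale value ``prior_mean * exp(log_scaling)``.

    ``prior_mean`` must be strictly positive; the log-scaling parameterisation
    is undefined otherwise.
    """
    if np.any(np.asarray(prior_mean) <= 0):
        raise ValueError("prior mean must be strictly positive")
    return prior_mean * np.exp(log_scaling)


def _zeros_like_shapes(shapes: dict[str, tuple]) -> dict[str, np.ndarray]:
    return {k: np.zeros(s) for k, s in shapes.items()}


@dataclass
class PriorSpec:
    """Gaussian priors over log-scalings plus natural-scale prior means.

    ``means`` are on the natural scale (Hz, ms, dimensionless amplitudes);
    ``log_means`` and ``variances`` parameterise the Gaussian prior over the
    log-scaling of each entry.  ``variances == 0`` fixes a parameter.
    ``joint`` optionally carries a full covariance over a named subset of
    entries (used by Bayesian updating across sessions).
    """

    means: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]
    log_means: dict[str, np.ndarray] = field(default_factory=dict)
    joint: tuple[list[tuple[str, tuple]], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.means = {k: np.asarray(v, dtype=float) for k, v in self.means.items()}
        self.variances = {
            k: np.asarray(v, dtype=float) for k, v in self.variances.items()
        }
        if not self.log_means:
            self.log_means = {k: np.zeros_like(v) for k, v in self.means.items()}
        else:
            self.log_means = {
                k: np.asarray(v, dtype=float) for k, v in self.log_means.items()
            }
        self.validate()

    # -- shape helpers -----------------------------------------------------
    @property
    def n_sources(self) -> int:
        return self.means["intrinsic"].shape[0]

    @property
    def n_channels(self) -> int:
        return self.means["gain"].shape[0]

    def validate(self) -> None:
        for name in BLOCK_NAMES:
            if name not in self.means:
                raise ValueError(f"missing prior block {name!r}")
            if np.any(self.means[name] <= 0):
                raise ValueError(f"prior means of {name!r} must be positive")
            if np.any(self.variances[name] < 0):
                raise ValueError(f"prior variances of {name!r} must be >= 0")
            if self.means[name].shape != self.variances[name].shape:
                raise ValueError(f"shape mismatch in prior block {name!r}")

    def copy(self) -> "PriorSpec":
        return copy.deepcopy(self)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {}
        for name in BLOCK_NAMES:
            out[name] = {
                "mean": self.means[name].tolist(),
                "log_mean": self.log_means[name].tolist(),
                "variance": self.variances[name].tolist(),
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(
            means={k: np.asarray(v["mean"]) for k, v in d.items()},
            variances={k: np.asarray(v["variance"]) for k, v in d.items()},
            log_means={k: np.asarray(v["log_mean"]) for k, v in d.items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriorSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_priors(n_sources: int = 2, n_channels: int = 2) -> PriorSpec:
    """Default priors for the two-source canonical microcircuit.

    Rates and delays: intrinsic edge rates from ``INTRINSIC_EDGES`` (var 1/8 on
    the tracked superficial-pyramidal self-inhibition, other edges fixed);
    extrinsic strengths 200 Hz (var 1/8); synaptic rate constants
    1000/[2, 2, 16, 28] Hz (var 1/16); sigmoid slope 2/3 (var 1/32); intrinsic
    delay 1 ms and extrinsic delay 8 ms (var 1/32); input and measurement-noise
    amplitudes and power-law exponents all 1 (var 1/128); electrode gains 4000
    sensor-units/mV (var 1/8).
    """
    shapes = block_shapes(n_sources, n_channels)
    means = _zeros_like_shapes(shapes)
    variances = _zeros_like_shapes(shapes)

    edge_rates = np.array([e[3] for e in INTRINSIC_EDGES])
    means["intrinsic"] = np.tile(edge_rates, (n_sources, 1))
    variances["intrinsic"] = np.zeros((n_sources, N_INTRINSIC))
    variances["intrinsic"][:, SP_SELF] = 1.0 / 8

    means["extrinsic"] = np.array([200.0, 200.0])
    variances["extrinsic"] = np.full(2, 1.0 / 8)

    means["kappa"] = KAPPA_MEANS.copy()
    variances["kappa"] = np.full(4, 1.0 / 16)

    means["gamma"] = np.asarray(2.0 / 3)
    variances["gamma"] = np.asarray(1.0 / 32)

    means["delay_intrinsic"] = np.asarray(1.0)  # ms
    variances["delay_intrinsic"] = np.asarray(1.0 / 32)
    means["delay_extrinsic"] = np.asarray(8.0)  # ms
    variances["delay_extrinsic"] = np.asarray(1.0 / 32)

    for name in ("input_amp", "input_exp", "noise_amp", "noise_exp"):
        means[name] = np.asarray(1.0)
        variances[name] = np.asarray(1.0 / 128)

    # Electrode gain converts population depolarisation (mV) to recorded
    # sensor units; its magnitude sets the neuronal signal well above the
    # measurement-noise floor in band, as in intracranial recordings.
    means["gain"] = np.full(n_channels, 4000.0)
    variances["gain"] = np.full(n_channels, 1.0 / 8)

    return PriorSpec(means=means, variances=variances)


@dataclass
class CMCParameters:
    """Log-scaling deviations for every model parameter.

    All blocks hold dimensionless log-scalings; natural-scale values are
    obtained against a :class:`PriorSpec` via :meth:`effective`.
    """

    blocks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.blocks = {k: np.asarray(v, dtype=float) for k, v in self.blocks.items()}

    @classmethod
    def zeros(cls, n_sources: int = 2, n_channels: int = 2) -> "CMCParameters":
        return cls(blocks=_zeros_like_shapes(block_shapes(n_sources, n_channels)))

    @classmethod
    def from_priors(cls, priors: PriorSpec) -> "CMCParameters":
        """Parameters at the prior expectation of the log-scalings."""
        return cls(blocks={k: np.array(v, dtype=float) for k, v in priors.log_means.items()})

    def copy(self) -> "CMCParameters":
        return CMCParameters(blocks={k: v.copy() for k, v in self.blocks.items()})

    def get(self, block: str, index: tuple = ()) -> float:
        return float(self.blocks[block][index])

    def set(self, block: str, index: tuple, value: float) -> None:
        self.blocks[block][index] = value

    def add(self, block: str, index: tuple, value: float) -> None:
        self.blocks[block][index] += value

    @property
    def n_sources(self) -> int:
        return self.blocks["intrinsic"].shape[0]

    @property
    def n_channels(self) -> int:
        return self.blocks["gain"].shape[0]

    def effective(self, priors: PriorSpec) -> "EffectiveParams":
        b = {k: effective_value(priors.means[k], v) for k, v in self.blocks.items()}
        return EffectiveParams(
            intrinsic=b["intrinsic"],
            extrinsic=b["extrinsic"],
            kappa=b["kappa"],
            gamma=float(b["gamma"]),
            delay_intrinsic=float(b["delay_intrinsic"]),
            delay_extrinsic=float(b["delay_extrinsic"]),
            input_amp=float(b["input_amp"]),
            input_exp=float(b["input_exp"]),
            noise_amp=float(b["noise_amp"]),
            noise_exp=float(b["noise_exp"]),
            gain=b["gain"],
        )


@dataclass
class EffectiveParams:
    """Natural-scale parameter values (rates Hz, delays ms)."""

    intrinsic: np.ndarray  # (n_sources, N_INTRINSIC) Hz, unsigned magnitudes
    extrinsic: np.ndarray  # (2,) Hz: [forward, backward]
    kappa: np.ndarray  # (4,) Hz per population
    gamma: float  # sigmoid slope, dimensionless
    delay_intrinsic: float  # ms
    delay_extrinsic: float  # ms
    input_amp: float
    input_exp: float
    noise_amp: float
    noise_exp: float
    gain: np.ndarray  # (n_channels,)

    @property
    def n_sources(self) -> int:
        return self.intrinsic.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]
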
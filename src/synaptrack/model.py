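"""Model/results interface: build a model from data, ``fit()``, inspect results.

`CSDModel` bundles windowed cross-spectral data with a candidate change-model
(architecture + which couplings may drift), priors and numerical settings;
``fit()`` runs the variational-Laplace inversion and returns a `DCMResults`
carrying the Gaussian posterior, the free energy (log-evidence bound used for
model comparison), coupling trajectories with credible bands, and plotting /
summary helpers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    Recording,
    WindowedCSD,
    bandpass,
    bipolar_montage,
    estimate_csd,
    segment_windows,
)
from .inversion import CSDPredictor, InversionSettings, Posterior, build_parameter_map, invert
from .model_space import ModelSpec, Trajectory, extract_trajectories
from .priors import PriorSpec, default_priors
from .spectral import DEFAULT_SPECTRAL, FrequencyGrid, SpectralConfig

__all__ = ["CSDModel", "DCMResults"]


class CSDModel:
    """Two-source canonical-microcircuit DCM for windowed cross-spectra.

    Parameters
    ----------
    data : WindowedCSD
        Complex cross-spectral matrices per window on a frequency grid.
    model_spec : ModelSpec, optional
        Architecture and change flags; defaults to the saturated model (all
        four couplings may drift) with a third-order per-segment basis.
    priors : PriorSpec, optional
        Defaults to :func:`synaptrack.priors.default_priors`.
    settings : InversionSettings, optional
    config : SpectralConfig, optional
        Fixed scales of the spectral observation model.
    """

    def __init__(
        self,
        data: WindowedCSD,
        model_spec: ModelSpec | None = None,
        priors: PriorSpec | None = None,
        settings: InversionSettings | None = None,
        config: SpectralConfig = DEFAULT_SPECTRAL,
    ):
        self.data = data
        n_post = data.n_windows // 2
        self.model_spec = model_spec or ModelSpec(
            n_pre=data.n_windows - n_post, n_post=n_post
        )
        if self.model_spec.n_windows != data.n_windows:
            raise ValueError("model window counts do not match the data")
        self.priors = priors or default_priors(n_channels=data.n_channels)
        self.settings = settings or InversionSettings()
        self.config = config

    @classmethod
    def from_recording(
        cls,
        rec: Recording,
        pairs: list[tuple[str, str]],
        onset: float,
        pre: float = 10.0,
        post: float = 10.0,
        window_len: float = 2.0,
        overlap: float = 0.5,
        band: tuple[float, float] = (0.5, 48.0),
        grid: FrequencyGrid | None = None,
        estimator: str = "var",
        **kwargs,
    ) -> "CSDModel":
        """Standard preprocessing path from a raw recording.

        Bipolar montage, zero-phase band-pass, peri-onset epoching into
        overlapping windows for the pre- and post-onset segments, and
        per-window CSD estimation on the grid.
        """
        grid = grid or FrequencyGrid.default()
        rec2 = bandpass(bipolar_montage(rec, pairs), *band)
        pre_wins = [
            (onset - pre + a, onset - pre + b) for a, b in segment_windows(pre, window_len, overlap)
        ]
        post_wins = [(onset + a, onset + b) for a, b in segment_windows(post, window_len, overlap)]
        segments = ["pre"] * len(pre_wins) + ["ictal"] * len(post_wins)
        data = estimate_csd(rec2, pre_wins + post_wins, grid, method=estimator, segments=segments)
        spec = kwargs.pop("model_spec", None) or ModelSpec(
            n_pre=len(pre_wins), n_post=len(post_wins)
        )
        return cls(data, model_spec=spec, **kwargs)

    def fit(self) -> "DCMResults":
        posterior = invert(
            self.data, self.model_spec, self.priors, self.settings, config=self.config
        )
        return DCMResults(self, posterior)


class DCMResults:
    """Results of a fitted cross-spectral DCM."""

    def __init__(self, model: CSDModel, posterior: Posterior):
        self.model = model
        self.posterior = posterior

    # -- scalar diagnostics -------------------------------------------------
    @property
    def free_energy(self) -> float:
        return self.posterior.free_energy

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.posterior.mean, index=self.posterior.labels)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.maximum(np.diag(self.posterior.cov), 0.0)),
            index=self.posterior.labels,
        )

    def trajectories(self, label: str = "") -> Trajectory:
        return extract_trajectories(self.posterior, self.model.model_spec, label=label)

    def predicted(self) -> np.ndarray:
        """Predicted CSD stack at the posterior mean."""
        spec = self.model.model_spec
        pmap = build_parameter_map(
            self.model.priors, spec, spec.basis().shape[1], self.model.settings.coef_prior_var
        )
        predictor = CSDPredictor(
            self.model.priors, spec, self.model.data.grid, pmap, config=self.model.config
        )
        return predictor.predict_stack(self.posterior.mean)

    def summary(self) -> str:
        spec = self.model.model_spec
        head = [
            "Cross-spectral DCM results",
            "=" * 60,
            f"architecture: {spec.architecture}-from-primary   model id: {spec.model_id}",
            f"changing couplings: {', '.join(spec.flagged) or 'none'}",
            f"windows: {spec.n_pre} pre + {spec.n_post} post, basis order {spec.order}",
            f"free energy: {self.free_energy:.2f} nats "
            f"(accuracy {self.posterior.accuracy:.2f}, complexity {self.posterior.complexity:.2f})",
            f"converged: {self.converged}  iterations: {len(self.posterior.trace) - 1}",
            "-" * 60,
        ]
        tab = pd.DataFrame({"mean": self.params, "sd": self.bse})
        return "\n".join(head) + "\n" + tab.to_string(float_format=lambda x: f"{x: .3f}")

    # -- plotting -----------------------------------------------------------
    def plot_trajectories(self, truth=None, ax=None):
        """Posterior coupling trajectories with 90% bands (and optional truth)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        tr = self.trajectories()
        for name, est in tr.params.items():
            (line,) = ax.plot(tr.times, est["mean"], label=name)
            ax.fill_between(tr.times, est["lo90"], est["hi90"], alpha=0.2, color=line.get_color())
            if truth is not None and name in truth.trajectories:
                ax.plot(tr.times, truth.trajectories[name], "--", color=line.get_color())
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time from onset (s)")
        ax.set_ylabel("log scaling")
        ax.legend(fontsize=8)
        return ax

    def plot_fit(self, window: int = 0, ax=None):
        """Observed versus predicted auto-/cross-spectra for one window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        f = self.model.data.grid.freqs
        obs = self.model.data.csd[window]
        pred = self.predicted()[window]
        n_ch = obs.shape[-1]
        for c in range(n_ch):
            ax.semilogy(f, np.abs(obs[:, c, c]), ":", label=f"obs ch{c}")
            ax.semilogy(f, np.abs(pred[:, c, c]), "-", label=f"pred ch{c}")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("|CSD|")
        ax.legend(fontsize=8)
        return ax

    def save(self, path: str | Path) -> None:
        self.posterior.to_hdf5(path)
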
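"""Shared fixtures: priors, grids, synthetic datasets and heavy session-scoped
face-validation runs reused by the acceptance and module suites."""

from pathlib import Path

import numpy as np
import pytest

from synaptrack.inversion import InversionSettings, invert
from synaptrack.model_space import ModelSpec, extract_trajectories
from synaptrack.priors import CMCParameters, default_priors
from synaptrack.spectral import FrequencyGrid
from synaptrack.synthetic import assess_recovery, generate_dataset, true_trajectories


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def eff(priors):
    return CMCParameters.zeros().effective(priors)


def write_minimal_edf(path: Path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a minimal valid EDF file (synthetic test fixture)."""
    n_ch, n_samp = data.shape
    spr = int(fs)
    n_rec = n_samp // spr
    data = data[:, : n_rec * spr]
    pmin, pmax, dmin, dmax = -1000.0, 1000.0, -32768, 32767

    def f(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    hdr = f("0", 8) + f("X", 80) + f("X", 80) + f("01.01.20", 8) + f("00.00.00", 8)
    hdr += f(256 * (1 + n_ch), 8) + f("", 44) + f(n_rec, 8) + f(1, 8) + f(n_ch, 4)
    for vals, n in [
        (labels, 16),
        ([""] * n_ch, 80),
        (["uV"] * n_ch, 8),
        ([pmin] * n_ch, 8),
        ([pmax] * n_ch, 8),
        ([dmin] * n_ch, 8),
        ([dmax] * n_ch, 8),
        ([""] * n_ch, 80),
        ([spr] * n_ch, 8),
        ([""] * n_ch, 32),
    ]:
        for v in vals:
            hdr += f(v, n)
    scaled = np.clip((data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin, dmin, dmax)
    body = b"".join(
        scaled.astype("<i2")[c, r * spr : (r + 1) * spr].tobytes()
        for r in range(n_rec)
        for c in range(n_ch)
    )
    Path(path).write_bytes(hdr + body)


@pytest.fixture()
def edf_path(tmp_path):
    rng = np.random.default_rng(0)
    data = 50.0 * rng.standard_normal((2, 256 * 4))
    path = tmp_path / "fixture.edf"
    write_minimal_edf(path, data, 256.0, ["LH4", "LH5"])
    return path, data


# ---------------------------------------------------------------------------
# heavy, shared face-validation runs (canonical design: 18 windows, SNR 4)
# ---------------------------------------------------------------------------

FACE_SEEDS = (1, 2, 3, 4, 5)
FACE_SPEC = ModelSpec(architecture="forward", flags=(True, True, True, False))


def _face_run(seed: int, snr: float):
    truth = true_trajectories()
    ds = generate_dataset(truth, snr=snr, seed=seed)
    post = invert(ds.data, FACE_SPEC)
    traj = extract_trajectories(post, FACE_SPEC)
    report = assess_recovery(truth, traj)
    return {"truth": truth, "dataset": ds, "posterior": post, "trajectory": traj, "report": report}


@pytest.fixture(scope="session")
def face_validation_runs():
    """Five seeded face-validation runs at SNR 4 (the canonical conditions)."""
    return [_face_run(seed, 4.0) for seed in FACE_SEEDS]


@pytest.fixture(scope="session")
def face_validation_runs_snr8():
    """The same five seeds at SNR 8, for noise-monotonicity checks."""
    return [_face_run(seed, 8.0) for seed in FACE_SEEDS]


@pytest.fixture(scope="session")
def quick_inversion():
    """One small, fast inversion for structural checks (not recovery quality)."""
    truth = true_trajectories(n_pre=4, n_post=4, amplitudes={"intrinsic_primary": 1.5})
    ds = generate_dataset(truth, snr=4.0, seed=11)
    spec = ModelSpec(flags=(True, False, False, False), order=1, n_pre=4, n_post=4)
    post = invert(ds.data, spec, settings=InversionSettings(max_iter=12))
    return {"truth": truth, "dataset": ds, "spec": spec, "posterior": post}
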
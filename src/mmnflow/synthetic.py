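"""Synthetic multi-subject EEG cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 64-channel epochs at 256 Hz (-100..500 ms) around binary tones,
with an ERP backbone (an MMN-like frontocentral negativity at 150-200 ms for
deviants, larger in stable than volatile phases, and a P3a-like central
positivity at 250-300 ms), linear single-trial coupling of voltage to
z-standardised learning trajectories, spatially and temporally correlated
Gaussian noise, occasional large-amplitude artifact trials, and
subject-level effect amplitudes linked to a psychosocial-functioning
covariate. Every injected quantity is recorded so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .hgf import HGFTrajectories
from .paradigm import TrialLabels

__all__ = ["SensorLayout", "EpochStack", "ErpComponent", "TrajectoryEffect",
           "NoiseModel", "GroundTruth", "CovariateLink", "generate_subject",
           "generate_cohort", "simulate_covariates", "default_truth"]

FS_DEFAULT = 256.0
TMIN_MS = -100.0
N_SAMPLES_DEFAULT = 154  # -100..~498 ms at 256 Hz


# --------------------------------------------------------------------------
# sensor layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorLayout:
    """Named electrodes with unit-sphere 3-D positions and a 2-D projection.

    The 2-D positions are an azimuthal-equidistant projection from the
    vertex, rescaled so all electrodes lie inside the unit disc.
    """

    names: tuple[str, ...]
    pos3d: np.ndarray  # (n, 3) on the unit sphere
    pos2d: np.ndarray  # (n, 2) within the unit disc

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if np.any(np.linalg.norm(self.pos2d, axis=1) > 1.0 + 1e-9):
            raise ValueError("2-D positions must lie within the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def standard_1020(cls, n_channels: int = 64) -> "SensorLayout":
        """64-channel 10-20 style cap (biosemi64 montage via mne).

        For ``n_channels < 64`` a spatially spread subset is selected
        deterministically (every k-th electrode of the cap ordering).
        """
        import mne
        montage = mne.channels.make_standard_montage("biosemi64")
        pos = montage.get_positions()["ch_pos"]
        names = list(pos.keys())
        xyz = np.array([pos[n] for n in names])
        xyz = xyz - xyz.mean(axis=0) * np.array([1.0, 1.0, 0.0])
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        theta = np.arccos(np.clip(xyz[:, 2], -1, 1))  # polar angle from vertex
        phi = np.arctan2(xyz[:, 1], xyz[:, 0])
        r = theta / theta.max()
        pos2d = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        if n_channels < len(names):
            idx = np.unique(np.round(
                np.linspace(0, len(names) - 1, n_channels)).astype(int))
            names = [names[i] for i in idx]
            xyz, pos2d = xyz[idx], pos2d[idx]
        elif n_channels > len(names):
            raise ValueError("at most 64 channels available")
        return cls(names=tuple(names), pos3d=xyz, pos2d=pos2d)


# --------------------------------------------------------------------------
# epoch container
# --------------------------------------------------------------------------

@dataclass
class EpochStack:
    """Trials x channels x samples voltages in microvolts, plus metadata."""

    voltages: np.ndarray       # (n_trials, n_channels, n_samples), uV
    times: np.ndarray          # (n_samples,), ms relative to tone onset
    layout: SensorLayout
    trials: pd.DataFrame       # columns: tone, trial_type, phase, artifact
    subject: str = "sub-00"
    fs: float = FS_DEFAULT

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.trials) != self.voltages.shape[0]:
            raise ValueError("trial metadata length must equal n_trials")
        if self.voltages.shape[1] != self.layout.n_channels:
            raise ValueError("channel dimension does not match layout")

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    def copy(self) -> "EpochStack":
        return EpochStack(voltages=self.voltages.copy(),
                          times=self.times.copy(), layout=self.layout,
                          trials=self.trials.copy(), subject=self.subject,
                          fs=self.fs)

    def select(self, idx) -> "EpochStack":
        idx = np.asarray(idx)
        return EpochStack(voltages=self.voltages[idx],
                          times=self.times.copy(), layout=self.layout,
                          trials=self.trials.iloc[idx].reset_index(drop=True),
                          subject=self.subject, fs=self.fs)

    def time_window(self, tmin_ms: float, tmax_ms: float) -> np.ndarray:
        return (self.times >= tmin_ms) & (self.times <= tmax_ms)

    # -- HDF5 I/O ----------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("voltages", data=self.voltages)
            f.create_dataset("times", data=self.times)
            f.attrs["units"] = "uV"
            f.attrs["fs"] = self.fs
            f.attrs["subject"] = self.subject
            f.attrs["channel_names"] = json.dumps(list(self.layout.names))
            f.create_dataset("pos3d", data=self.layout.pos3d)
            f.create_dataset("pos2d", data=self.layout.pos2d)
            grp = f.create_group("trials")
            for col in self.trials.columns:
                data = self.trials[col].to_numpy()
                if data.dtype == object or data.dtype.kind == "U":
                    data = data.astype("S16")
                grp.create_dataset(col, data=data)

    @classmethod
    def from_hdf5(cls, path) -> "EpochStack":
        with h5py.File(path, "r") as f:
            names = tuple(json.loads(f.attrs["channel_names"]))
            layout = SensorLayout(names=names, pos3d=f["pos3d"][()],
                                  pos2d=f["pos2d"][()])
            cols = {}
            for col in f["trials"]:
                data = f["trials"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype("U16")
                cols[col] = data
            return cls(voltages=f["voltages"][()], times=f["times"][()],
                       layout=layout, trials=pd.DataFrame(cols),
                       subject=str(f.attrs["subject"]),
                       fs=float(f.attrs["fs"]))


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def _gauss(x, center, fwhm):
    sigma = fwhm / 2.3548200450309493
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


_STANDARD_POS2D: dict[str, np.ndarray] = {}


def _center2d(layout: SensorLayout, name: str) -> np.ndarray:
    """Projected position of a named electrode.

    Falls back to the full standard cap when the layout is a channel subset
    that does not contain the electrode itself, so component geometry is
    independent of the simulated montage density.
    """
    if name in layout.names:
        return layout.pos2d[layout.index(name)]
    if not _STANDARD_POS2D:
        full = SensorLayout.standard_1020(64)
        _STANDARD_POS2D.update(dict(zip(full.names, full.pos2d)))
    return _STANDARD_POS2D[name]


@dataclass(frozen=True)
class ErpComponent:
    """Deterministic ERP component with a unit-peak Gaussian geometry.

    `amplitude` maps (trial_type, phase) -> peak amplitude in uV; pairs not
    listed contribute zero.
    """

    name: str
    channel: str               # topography centre
    spatial_fwhm: float = 0.5  # unit-disc units
    latency_ms: float = 175.0
    temporal_fwhm_ms: float = 50.0
    amplitude: dict = field(default_factory=dict)

    def waveform(self, layout: SensorLayout, times: np.ndarray) -> np.ndarray:
        c = _center2d(layout, self.channel)
        dist = np.linalg.norm(layout.pos2d - c, axis=1)
        g = _gauss(dist, 0.0, self.spatial_fwhm)
        h = _gauss(times, self.latency_ms, self.temporal_fwhm_ms)
        return g[:, None] * h[None, :]


@dataclass(frozen=True)
class TrajectoryEffect:
    """Linear coupling of voltage to one z-standardised trajectory."""

    regressor: str             # trajectory column, e.g. "delta1"
    channel: str
    latency_ms: float
    amplitude: float           # uV per z-unit (group mean)
    spatial_fwhm: float = 0.5
    temporal_fwhm_ms: float = 45.0
    between_subject_sd: float = 0.3

    def waveform(self, layout: SensorLayout, times: np.ndarray) -> np.ndarray:
        c = _center2d(layout, self.channel)
        dist = np.linalg.norm(layout.pos2d - c, axis=1)
        g = _gauss(dist, 0.0, self.spatial_fwhm)
        h = _gauss(times, self.latency_ms, self.temporal_fwhm_ms)
        return g[:, None] * h[None, :]


@dataclass(frozen=True)
class NoiseModel:
    """Spatially correlated (exponential kernel) AR(1) Gaussian noise."""

    sigma: float = 8.0            # marginal SD, uV
    ar1_phi: float = 0.8
    spatial_scale: float = 0.35   # unit-disc units

    def sample(self, rng, layout: SensorLayout, n_trials: int,
               n_samples: int) -> np.ndarray:
        d = np.linalg.norm(layout.pos2d[:, None] - layout.pos2d[None, :],
                           axis=-1)
        cov = np.exp(-d / self.spatial_scale)
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(layout.n_channels))
        white = rng.standard_normal((n_trials, layout.n_channels, n_samples))
        # unit-marginal AR(1) along time
        ar = np.empty_like(white)
        ar[..., 0] = white[..., 0]
        c = np.sqrt(1.0 - self.ar1_phi ** 2)
        for t in range(1, n_samples):
            ar[..., t] = self.ar1_phi * ar[..., t - 1] + c * white[..., t]
        return self.sigma * np.einsum("ij,kjt->kit", L, ar)


@dataclass(frozen=True)
class CovariateLink:
    """Linear link between a covariate and a subject-level effect amplitude.

    The targeted amplitude is the extra deviant-P3a amplitude in the volatile
    phase: amplitude_s = intercept + slope * (covariate_s - 8) + N(0, sd).
    """

    covariate: str = "GF_social"
    slope: float = 0.5       # uV per score unit
    intercept: float = 0.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class GroundTruth:
    """Everything injected into a synthetic subject/cohort."""

    erp_components: tuple = ()
    effects: tuple = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    p_artifact: float = 0.028
    artifact_uV: float = 150.0
    link: CovariateLink | None = None


def default_truth() -> GroundTruth:
    """Default study-like ground truth.

    MMN: deviant-negative frontocentral 150-200 ms, larger (more negative)
    in stable than volatile phases. P3a: deviant-positive central
    250-300 ms. Trajectory effects follow the reported sensor-space
    geometry: low-level PE (delta1) early frontocentral, high-level PE
    (delta2) frontocentral, low-level precision ratio (psi2) early central,
    high-level precision ratio (psi3) later frontal.
    """
    mmn = ErpComponent(
        name="mmn", channel="FCz", latency_ms=175.0, temporal_fwhm_ms=50.0,
        amplitude={("deviant", "stable"): -3.3, ("deviant", "volatile"): -1.0})
    p3a = ErpComponent(
        name="p3a", channel="Cz", latency_ms=275.0, temporal_fwhm_ms=60.0,
        amplitude={("deviant", "stable"): 2.0, ("deviant", "volatile"): 2.0})
    n1 = ErpComponent(
        name="n1", channel="Cz", latency_ms=100.0, temporal_fwhm_ms=40.0,
        amplitude={(tt, ph): -1.0 for tt in ("standard", "deviant", "other")
                   for ph in ("stable", "volatile")})
    effects = (
        TrajectoryEffect("delta1", "FCz", 137.0, 1.2),
        TrajectoryEffect("delta2", "FCz", 141.0, 1.0),
        TrajectoryEffect("psi2", "Cz", 117.0, 0.8),
        TrajectoryEffect("psi3", "Fz", 207.0, 1.2),
    )
    return GroundTruth(erp_components=(n1, mmn, p3a), effects=effects,
                       noise=NoiseModel(), link=CovariateLink())


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _zscore(x):
    return (x - x.mean()) / x.std()


def generate_subject(traj: HGFTrajectories, labels: TrialLabels,
                     truth: GroundTruth, seed: int,
                     layout: SensorLayout | None = None,
                     subject: str = "sub-00",
                     effect_amplitudes: dict | None = None,
                     p3a_volatile_extra: float = 0.0,
                     fs: float = FS_DEFAULT,
                     n_samples: int = N_SAMPLES_DEFAULT,
                     tones: np.ndarray | None = None) -> EpochStack:
    """Generate one subject's epochs.

    voltage(k, c, t) = ERP_base(c, t | trial_type_k, phase_k)
                       + sum_e A_e g_e(c) h_e(t) z_e(k) + noise(k, c, t),
    with artifact trials receiving an additional +-`artifact_uV` square
    pulse on a random channel. `effect_amplitudes` overrides the per-subject
    amplitude of named regressor effects (used by :func:`generate_cohort`);
    `p3a_volatile_extra` adds covariate-linked deviant-P3a amplitude in the
    volatile phase.
    """
    n = len(traj)
    if labels.trial_type.shape[0] != n:
        raise ValueError("trajectories and labels have different lengths")
    layout = layout or SensorLayout.standard_1020()
    rng = np.random.default_rng(seed)
    times = TMIN_MS + np.arange(n_samples) * 1000.0 / fs

    v = truth.noise.sample(rng, layout, n, n_samples) \
        if truth.noise.sigma > 0 else np.zeros(
            (n, layout.n_channels, n_samples))

    # ERP backbone per (trial_type, phase)
    for comp in truth.erp_components:
        wf = comp.waveform(layout, times)
        for (tt, ph), amp in comp.amplitude.items():
            sel = (labels.trial_type == tt) & (labels.phase == ph)
            if sel.any():
                v[sel] += amp * wf

    if p3a_volatile_extra != 0.0:
        extra = ErpComponent(name="p3a_link", channel="Cz", latency_ms=275.0,
                             temporal_fwhm_ms=60.0)
        sel = (labels.trial_type == "deviant") & (labels.phase == "volatile")
        if sel.any():
            v[sel] += p3a_volatile_extra * extra.waveform(layout, times)

    # trial-wise trajectory coupling
    for eff in truth.effects:
        amp = (effect_amplitudes or {}).get(eff.regressor, eff.amplitude)
        z = _zscore(traj.table[eff.regressor].to_numpy(float))
        v += amp * z[:, None, None] * eff.waveform(layout, times)[None]

    # artifact trials: square pulse on one channel
    art = rng.random(n) < truth.p_artifact
    for k in np.flatnonzero(art):
        ch = rng.integers(layout.n_channels)
        sign = 1 if rng.random() < 0.5 else -1
        t0 = rng.integers(n_samples // 2)
        v[k, ch, t0:t0 + n_samples // 4] += sign * truth.artifact_uV

    trials = pd.DataFrame({
        "tone": tones if tones is not None else np.zeros(n, int),
        "trial_type": labels.trial_type,
        "phase": labels.phase,
        "artifact": art,
    })
    return EpochStack(voltages=v, times=times, layout=layout, trials=trials,
                      subject=subject, fs=fs)


def simulate_covariates(n_subjects: int, seed: int) -> pd.DataFrame:
    """Subject covariate table: GF scores (6-10, median-9-like), age,
    working-memory span and cannabis use."""
    rng = np.random.default_rng(seed)
    scores = np.arange(6, 11)
    weights = np.array([0.05, 0.10, 0.20, 0.40, 0.25])
    gf_social = rng.choice(scores, n_subjects, p=weights)
    gf_role = rng.choice(scores, n_subjects, p=weights)
    age = np.clip(rng.normal(22.9, 6.8, n_subjects), 18, 55).round(1)
    wm = np.clip(rng.normal(6.6, 2.1, n_subjects), 2, 12).round(1)
    cannabis = rng.choice(["y", "n"], n_subjects, p=[27 / 43, 16 / 43])
    return pd.DataFrame({
        "subject": [f"sub-{i:02d}" for i in range(n_subjects)],
        "GF_social": gf_social, "GF_role": gf_role,
        "age": age, "working_memory": wm, "cannabis": cannabis,
    })


def generate_cohort(n_subjects: int, traj: HGFTrajectories,
                    labels: TrialLabels, truth: GroundTruth,
                    master_seed: int,
                    layout: SensorLayout | None = None,
                    tones: np.ndarray | None = None,
                    fs: float = FS_DEFAULT,
                    n_samples: int = N_SAMPLES_DEFAULT
                    ) -> tuple[list[EpochStack], pd.DataFrame]:
    """Generate a cohort sharing one design/trajectory set.

    Subject effect amplitudes are drawn around the group means
    (`TrajectoryEffect.amplitude` +- `between_subject_sd`); if
    `truth.link` is set, each subject's extra volatile-phase deviant-P3a
    amplitude is intercept + slope * (covariate - 8) + noise, giving the
    second-level covariate regression a known slope. Per-subject seeds are
    derived from `master_seed`.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    layout = layout or SensorLayout.standard_1020()
    rng = np.random.default_rng(master_seed)
    covariates = simulate_covariates(n_subjects, seed=int(
        rng.integers(2 ** 31)))
    subject_seeds = rng.integers(2 ** 31, size=n_subjects)
    stacks = []
    for i in range(n_subjects):
        amps = {eff.regressor:
                float(rng.normal(eff.amplitude, eff.between_subject_sd))
                for eff in truth.effects}
        extra = 0.0
        if truth.link is not None:
            cov = float(covariates.loc[i, truth.link.covariate])
            extra = (truth.link.intercept
                     + truth.link.slope * (cov - 8.0)
                     + rng.normal(0.0, truth.link.noise_sd))
        stacks.append(generate_subject(
            traj, labels, truth, seed=int(subject_seeds[i]), layout=layout,
            subject=f"sub-{i:02d}", effect_amplitudes=amps,
            p3a_volatile_extra=extra, fs=fs, n_samples=n_samples,
            tones=tones))
    return stacks, covariates
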
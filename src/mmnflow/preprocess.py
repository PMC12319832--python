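"""Epoch-domain preprocessing: baseline correction, amplitude-threshold
artifact rejection, bad-channel interpolation, band-limiting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthetic import EpochStack

__all__ = ["PreprocessReport", "baseline_correct", "reject_artifacts",
           "interpolate_bad_channels", "band_limit", "preprocess_epochs"]


@dataclass
class PreprocessReport:
    """Record of what preprocessing did to an epoch stack."""

    n_total: int
    retained: np.ndarray = field(default_factory=lambda: np.array([], int))
    rejected: np.ndarray = field(default_factory=lambda: np.array([], int))
    reasons: dict = field(default_factory=dict)      # trial -> reason
    interpolated: list = field(default_factory=list)  # channel names
    interpolation_method: str = "inverse_distance_k4"
    filter_settings: dict = field(default_factory=dict)

    def validate(self):
        if len(self.retained) + len(self.rejected) != self.n_total:
            raise ValueError("retained + rejected must equal total trials")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_retained": int(len(self.retained)),
            "n_rejected": int(len(self.rejected)),
            "retained": [int(i) for i in self.retained],
            "rejected": {int(k): v for k, v in self.reasons.items()},
            "interpolated_channels": list(self.interpolated),
            "interpolation_method": self.interpolation_method,
            "filter_settings": self.filter_settings,
        }


def baseline_correct(epochs: EpochStack,
                     window_ms: tuple[float, float] = (-100.0, 0.0)
                     ) -> EpochStack:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    lo, hi = window_ms
    sel = (epochs.times >= lo) & (epochs.times <= hi)
    if not sel.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    out = epochs.copy()
    out.voltages -= out.voltages[:, :, sel].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(epochs: EpochStack, threshold_uV: float = 75.0
                     ) -> tuple[EpochStack, PreprocessReport]:
    """Drop trials where any channel/sample exceeds +-threshold."""
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    absmax = np.abs(epochs.voltages).max(axis=(1, 2))
    bad = absmax > threshold_uV
    retained = np.flatnonzero(~bad)
    rejected = np.flatnonzero(bad)
    report = PreprocessReport(
        n_total=epochs.n_trials, retained=retained, rejected=rejected,
        reasons={int(i): f"amplitude {absmax[i]:.1f} uV > {threshold_uV} uV"
                 for i in rejected})
    report.validate()
    return epochs.select(retained), report


def interpolate_bad_channels(epochs: EpochStack,
                             bad_fraction_threshold: float = 0.20,
                             threshold_uV: float = 75.0, k: int = 4
                             ) -> tuple[EpochStack, PreprocessReport]:
    """Replace channels with too many artifactual trials by an
    inverse-distance-weighted mean of their nearest clean neighbours.

    A channel is bad when its own per-channel artifact fraction (fraction of
    trials where *that channel* exceeds +-threshold) exceeds
    ``bad_fraction_threshold``. Bad channels are reconstructed on all trials
    from the `k` nearest clean channels, weights 1/distance.
    """
    v = epochs.voltages
    per_chan_bad = (np.abs(v) > threshold_uV).any(axis=2).mean(axis=0)
    bad = np.flatnonzero(per_chan_bad > bad_fraction_threshold)
    if bad.size > epochs.layout.n_channels / 2:
        raise RuntimeError(
            f"{bad.size}/{epochs.layout.n_channels} channels bad: data "
            "unusable")
    out = epochs.copy()
    clean = np.setdiff1d(np.arange(epochs.layout.n_channels), bad)
    for ch in bad:
        d = np.linalg.norm(epochs.layout.pos2d[clean]
                           - epochs.layout.pos2d[ch], axis=1)
        nearest = clean[np.argsort(d)[:k]]
        w = 1.0 / np.maximum(np.sort(d)[:k], 1e-12)
        w /= w.sum()
        out.voltages[:, ch, :] = np.einsum(
            "j,kjt->kt", w, v[:, nearest, :])
    report = PreprocessReport(
        n_total=epochs.n_trials, retained=np.arange(epochs.n_trials),
        interpolated=[epochs.layout.names[i] for i in bad])
    report.validate()
    return out, report


def band_limit(data: np.ndarray, fs_in: float, hp_hz: float = 0.1,
               lp_hz: float = 30.0, fs_out: float | None = 256.0,
               axis: int = -1) -> tuple[np.ndarray, float]:
    """Zero-phase band-limit (and optionally resample) along `axis`.

    High-pass then low-pass 4th-order Butterworth applied with filtfilt;
    resampling uses polyphase filtering. Returns (data, fs).
    """
    if not (0 <= hp_hz < lp_hz):
        raise ValueError("need 0 <= hp_hz < lp_hz")
    if fs_in < 2 * lp_hz:
        raise ValueError("sampling rate below Nyquist for the low-pass")
    x = np.asarray(data, float)
    if hp_hz > 0:
        sos = signal.butter(4, hp_hz, btype="highpass", fs=fs_in,
                            output="sos")
        # pad on the scale of the high-pass time constant, else the edge
        # transient of a 0.1 Hz corner spans the whole signal
        padlen = min(x.shape[axis] - 1, int(3 * fs_in / hp_hz))
        x = signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)
    sos = signal.butter(4, lp_hz, btype="lowpass", fs=fs_in, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=axis)
    fs = fs_in
    if fs_out is not None and fs_out != fs_in:
        from fractions import Fraction
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator,
                                 axis=axis)
        fs = fs_in * frac.numerator / frac.denominator
    return x, fs


def preprocess_epochs(epochs: EpochStack,
                      baseline_ms: tuple[float, float] = (-100.0, 0.0),
                      threshold_uV: float = 75.0,
                      bad_fraction_threshold: float = 0.20
                      ) -> tuple[EpochStack, PreprocessReport]:
    """Standard order: baseline-correct, interpolate bad channels, then
    reject remaining artifact trials (rejection recomputed after
    interpolation so a repaired channel no longer forces rejection)."""
    bc = baseline_correct(epochs, baseline_ms)
    interp, rep_i = interpolate_bad_channels(
        bc, bad_fraction_threshold, threshold_uV)
    clean, rep_r = reject_artifacts(interp, threshold_uV)
    rep_r.interpolated = rep_i.interpolated
    rep_r.interpolation_method = rep_i.interpolation_method
    rep_r.filter_settings = {"baseline_ms": list(baseline_ms),
                             "threshold_uV": threshold_uV}
    return clean, rep_r
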
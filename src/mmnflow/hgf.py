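"""Three-level binary hierarchical Gaussian filter (HGF).

Level 1 is the binary tone, level 2 tracks the tendency of the high tone in
logit space, level 3 tracks the (log-)volatility of that tendency. Levels are
coupled through their variances: the level-2 random-walk variance on trial k
is ``exp(kappa * mu3 + omega2)``, so a higher volatility belief speeds up
low-level learning. The filter is run in "observer" mode: it sees the tone
sequence ``u`` and produces per-trial predictions, prediction errors (delta1,
delta2), precisions, precision ratios (psi2, psi3), precision-weighted
prediction errors (eps2 = psi2*delta1, eps3 = psi3*delta2) and Shannon
surprise in nats.

Two variants are provided. ``variant="hgf"`` is the classical update, which
raises when the level-3 posterior precision goes non-positive.
``variant="ehgf"`` (the default, matching the enhanced binary
implementation) updates the level-3 mean with the *predicted* precision
before updating the precision, and floors the posterior precision at a small
positive value instead of raising; a counter of floored trials is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HGFParams", "HGFTrajectories", "hgf_step", "filter_sequence",
           "regressor_collinearity", "PrecisionViolation"]

_PI3_FLOOR = 1e-8

TRAJECTORY_COLUMNS = (
    "muhat1", "pihat1", "delta1", "mu2", "sigma2", "pi2", "pihat2",
    "delta2", "mu3", "sigma3", "pi3", "pihat3", "psi2", "psi3",
    "eps2", "eps3", "surprise", "w2",
)


class PrecisionViolation(RuntimeError):
    """Raised when a posterior precision goes non-positive (variant='hgf')."""

    def __init__(self, trial: int, value: float):
        self.trial = trial
        super().__init__(
            f"non-positive level-3 posterior precision ({value:.6g}) at "
            f"trial {trial}")


@dataclass(frozen=True)
class HGFParams:
    """Perceptual parameters of the 3-level binary HGF.

    kappa : level-3 -> level-2 coupling strength (> 0), fixed to 1 by default.
    omega2, omega3 : tonic log-volatilities of levels 2 and 3.
    mu2_0, sigma2_0, mu3_0, sigma3_0 : initial means / variances.
    variant : "ehgf" (enhanced, default) or "hgf" (classical).
    psi2_convention : "unit_input" gives psi2 = 1/pi2 (so eps2 equals the
        level-2 belief update exactly); "pihat1_ratio" gives psi2 = pihat1/pi2.
    """

    kappa: float = 1.0
    omega2: float = -3.0
    omega3: float = -6.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    variant: str = "ehgf"
    psi2_convention: str = "unit_input"

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be > 0")
        if self.variant not in ("hgf", "ehgf"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.psi2_convention not in ("unit_input", "pihat1_ratio"):
            raise ValueError(
                f"unknown psi2 convention {self.psi2_convention!r}")


@dataclass
class HGFState:
    """Posterior after trial k-1 (sufficient statistics for the next step)."""

    mu2: float
    sigma2: float
    mu3: float
    sigma3: float


@dataclass
class HGFTrajectories:
    """Per-trial HGF quantities as a tidy table (one row per trial)."""

    table: pd.DataFrame
    params: HGFParams
    n_floored: int = 0  # ehgf level-3 precision floor activations

    def __len__(self) -> int:
        return len(self.table)

    def __getattr__(self, name):
        if name in TRAJECTORY_COLUMNS:
            return self.table[name].to_numpy()
        raise AttributeError(name)

    def regressors(self, names) -> pd.DataFrame:
        return self.table[list(names)].copy()

    def to_tsv(self, path) -> None:
        import json
        header = {
            "params": {k: getattr(self.params, k)
                       for k in ("kappa", "omega2", "omega3", "mu2_0",
                                 "sigma2_0", "mu3_0", "sigma3_0", "variant",
                                 "psi2_convention")},
            "n_floored": self.n_floored,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            cols = ["muhat1", "delta1", "psi2", "eps2", "delta2", "psi3",
                    "eps3", "surprise"]
            self.table[cols].to_csv(fh, sep="\t", index=False)


def hgf_step(state: HGFState, u: int, params: HGFParams,
             trial: int = 0) -> tuple[dict, HGFState, bool]:
    """One filtering step: predict from `state`, observe tone `u`, update.

    Returns the trial record, the new state, and whether the ehgf precision
    floor fired on this trial.
    """
    if state.sigma2 <= 0 or state.sigma3 <= 0:
        raise ValueError("state variances must be positive")
    k, w2o, w3o = params.kappa, params.omega2, params.omega3

    # predictions (no drift: muhat_i = mu_i from the previous trial)
    muhat2, muhat3 = state.mu2, state.mu3
    muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
    pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
    delta1 = u - muhat1

    sigmahat2 = state.sigma2 + np.exp(k * muhat3 + w2o)
    pihat2 = 1.0 / sigmahat2

    # level-2 update
    pi2 = pihat2 + muhat1 * (1.0 - muhat1)
    sigma2 = 1.0 / pi2
    mu2 = muhat2 + delta1 / pi2

    # volatility prediction error and weight
    delta2 = (sigma2 + (mu2 - muhat2) ** 2) / sigmahat2 - 1.0
    w2 = np.exp(k * muhat3 + w2o) / sigmahat2

    # level-3 update
    pihat3 = 1.0 / (state.sigma3 + np.exp(w3o))
    floored = False
    if params.variant == "ehgf":
        # mean first, with the predicted precision; then precision, floored
        mu3 = muhat3 + (1.0 / pihat3) * (k / 2.0) * w2 * delta2
        pi3 = pihat3 + (k ** 2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0:
            pi3 = _PI3_FLOOR
            floored = True
    else:
        pi3 = pihat3 + (k ** 2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if pi3 <= 0:
            raise PrecisionViolation(trial, float(pi3))
        mu3 = muhat3 + (1.0 / pi3) * (k / 2.0) * w2 * delta2
    sigma3 = 1.0 / pi3

    if params.psi2_convention == "unit_input":
        psi2 = 1.0 / pi2
    else:
        psi2 = pihat1 / pi2
    psi3 = pihat2 / pi3
    eps2 = psi2 * delta1
    eps3 = psi3 * delta2
    surprise = -(u * np.log(muhat1) + (1 - u) * np.log1p(-muhat1))

    record = dict(muhat1=muhat1, pihat1=pihat1, delta1=delta1, mu2=mu2,
                  sigma2=sigma2, pi2=pi2, pihat2=pihat2, delta2=delta2,
                  mu3=mu3, sigma3=sigma3, pi3=pi3, pihat3=pihat3,
                  psi2=psi2, psi3=psi3, eps2=eps2, eps3=eps3,
                  surprise=surprise, w2=w2)
    return record, HGFState(mu2=mu2, sigma2=sigma2, mu3=mu3, sigma3=sigma3), \
        floored


def filter_sequence(u, params: HGFParams | None = None) -> HGFTrajectories:
    """Run the filter over a tone sequence (online, causal).

    Trial-k quantities depend only on u(1..k). Raises
    :class:`PrecisionViolation` (with the 0-based trial index) for the
    classical variant when the level-3 precision goes non-positive.
    """
    from .paradigm import ToneSequence
    if isinstance(u, ToneSequence):
        u = u.u
    u = np.asarray(u)
    if not np.isin(u, (0, 1)).all():
        raise ValueError("input sequence must be binary")
    params = params or HGFParams()
    state = HGFState(mu2=params.mu2_0, sigma2=params.sigma2_0,
                     mu3=params.mu3_0, sigma3=params.sigma3_0)
    rows = np.empty((u.shape[0], len(TRAJECTORY_COLUMNS)))
    n_floored = 0
    for kk, uk in enumerate(u):
        rec, state, floored = hgf_step(state, int(uk), params, trial=kk)
        n_floored += floored
        rows[kk] = [rec[c] for c in TRAJECTORY_COLUMNS]
    table = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
    return HGFTrajectories(table=table, params=params, n_floored=n_floored)


def _surprise_kernel_py(u, kappa, w2o, w3o, mu2, sigma2, mu3, sigma3,
                        ehgf):
    """Total surprise of the filter over u; inf on a precision violation.

    Scalar fast path used by the observer objective; agreement with
    :func:`filter_sequence` is covered by tests.
    """
    total = 0.0
    for uk in u:
        muhat2, muhat3 = mu2, mu3
        e = np.exp(kappa * muhat3 + w2o)
        if not np.isfinite(e):
            return np.inf
        muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
        delta1 = uk - muhat1
        sigmahat2 = sigma2 + e
        if sigmahat2 <= 0 or not np.isfinite(sigmahat2):
            return np.inf
        pihat2 = 1.0 / sigmahat2
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        if pi2 <= 0:
            return np.inf
        sigma2 = 1.0 / pi2
        mu2 = muhat2 + delta1 / pi2
        delta2 = (sigma2 + (mu2 - muhat2) ** 2) / sigmahat2 - 1.0
        w2 = e / sigmahat2
        e3 = np.exp(w3o)
        if not np.isfinite(e3):
            return np.inf
        denom3 = sigma3 + e3
        if denom3 <= 0 or not np.isfinite(denom3):
            return np.inf
        pihat3 = 1.0 / denom3
        if pihat3 <= 0:
            return np.inf
        if ehgf:
            mu3 = muhat3 + (1.0 / pihat3) * (kappa / 2.0) * w2 * delta2
            pi3 = pihat3 + (kappa ** 2 / 2.0) * w2 * (
                w2 + (2.0 * w2 - 1.0) * delta2)
            if pi3 <= 0:
                pi3 = _PI3_FLOOR
        else:
            pi3 = pihat3 + (kappa ** 2 / 2.0) * w2 * (
                w2 + (2.0 * w2 - 1.0) * delta2)
            if pi3 <= 0:
                return np.inf
            mu3 = muhat3 + (1.0 / pi3) * (kappa / 2.0) * w2 * delta2
        sigma3 = 1.0 / pi3
        if uk == 1:
            total -= np.log(muhat1)
        else:
            total -= np.log1p(-muhat1)
    return total


try:  # jit-compiled fast path; the pure-python kernel is the fallback
    from numba import njit as _njit
    _surprise_kernel = _njit(cache=False, fastmath=False)(
        _surprise_kernel_py)
except ImportError:  # pragma: no cover
    _surprise_kernel = _surprise_kernel_py


def total_surprise(u, params: HGFParams) -> float:
    """Total Shannon surprise (nats) of the observer on sequence u.

    Returns +inf for parameters that violate a precision constraint
    (classical variant) or overflow, instead of raising.
    """
    u = np.ascontiguousarray(np.asarray(u, dtype=np.float64))
    with np.errstate(over="ignore", invalid="ignore"):
        return float(_surprise_kernel(
            u, params.kappa, params.omega2, params.omega3, params.mu2_0,
            params.sigma2_0, params.mu3_0, params.sigma3_0,
            params.variant == "ehgf"))


def regressor_collinearity(traj: HGFTrajectories, pair, mask=None) -> float:
    """Pearson correlation of two z-standardised regressors over retained
    trials.

    `mask` is a boolean retained-trial indicator (default: all retained).
    Raises on fewer than 3 retained trials or zero variance (z-scoring is an
    affine map, so the correlation equals that of the raw regressors; it is
    computed on the standardised values to match how the regressors enter
    the GLM).
    """
    a, b = pair
    x = traj.table[a].to_numpy(float)
    y = traj.table[b].to_numpy(float)
    if mask is not None:
        mask = np.asarray(mask, bool)
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 retained trials")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"zero variance in regressor pair ({a}, {b})")
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    return float(np.mean(zx * zy))
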
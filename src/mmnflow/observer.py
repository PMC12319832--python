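"""Bayes-optimal (surprise-minimising) observer fitting.

Because the oddball task is passive, perceptual parameters cannot be fit to
behaviour; instead the observer's free parameters (by default the tonic
log-volatilities omega2 and omega3) are chosen to minimise cumulative
Shannon surprise over the experienced tone sequence, plus a Gaussian prior
penalty — a maximum-a-posteriori fit of an ideal observer.

The module follows the Model/Results pattern: build a
:class:`BayesOptimalObserver` from a tone sequence, call :meth:`fit`, and
receive an :class:`ObserverResults` carrying the fitted parameters,
objective value and optimiser diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .hgf import HGFParams, HGFTrajectories, filter_sequence, \
    total_surprise
from .paradigm import ToneSequence

__all__ = ["ObserverPriors", "BayesOptimalObserver", "ObserverResults",
           "FitFailure"]


class FitFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class ObserverPriors:
    """Gaussian priors over the free parameters, in native space.

    Defaults are wide: omega2 ~ N(-3, 16), omega3 ~ N(-6, 16). An infinite
    variance makes the prior flat (pure surprise minimisation).
    """

    mean: dict = field(default_factory=lambda: {"omega2": -3.0,
                                                "omega3": -6.0})
    var: dict = field(default_factory=lambda: {"omega2": 16.0,
                                               "omega3": 16.0})

    def __post_init__(self):
        if set(self.mean) != set(self.var):
            raise ValueError("prior means and variances name different "
                             "parameters")
        if not self.mean:
            raise ValueError("at least one free parameter required")
        if any(v <= 0 for v in self.var.values()):
            raise ValueError("prior variances must be > 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.mean))


@dataclass
class ObserverResults:
    """Result of a Bayes-optimal observer fit."""

    params: HGFParams
    objective: float            # negative log-joint at the optimum, nats
    free_names: tuple[str, ...]
    converged: bool
    n_restarts: int
    n_iterations: int
    seed: int
    model: "BayesOptimalObserver"

    def trajectories(self) -> HGFTrajectories:
        return filter_sequence(self.model.u, self.params)

    def summary(self) -> str:
        lines = [
            "Bayes-optimal observer fit",
            "=" * 40,
            f"n trials            {self.model.u.shape[0]}",
            f"variant             {self.params.variant}",
            f"objective (nats)    {self.objective:.4f}",
            f"converged           {self.converged}",
            f"restarts/iterations {self.n_restarts}/{self.n_iterations}",
        ]
        for name in self.free_names:
            lines.append(f"{name:<19} {getattr(self.params, name): .4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k)
                       for k in ("kappa", "omega2", "omega3", "mu2_0",
                                 "sigma2_0", "mu3_0", "sigma3_0", "variant",
                                 "psi2_convention")},
            "priors": {"mean": dict(self.model.priors.mean),
                       "var": dict(self.model.priors.var)},
            "objective": self.objective,
            "converged": self.converged,
            "seed": self.seed,
        }


class BayesOptimalObserver:
    """MAP fit of HGF perceptual parameters to a tone sequence.

    Parameters
    ----------
    u
        Binary tone sequence (array or :class:`ToneSequence`).
    priors
        Gaussian priors over the free parameters; the prior means double as
        the optimiser's central starting point.
    base_params
        Fixed-parameter template (kappa, initial conditions, variant).
        Any parameter named in `priors` is treated as free.
    """

    def __init__(self, u, priors: ObserverPriors | None = None,
                 base_params: HGFParams | None = None):
        if isinstance(u, ToneSequence):
            u = u.u
        self.u = np.asarray(u)
        if not np.isin(self.u, (0, 1)).all():
            raise ValueError("tone sequence must be binary")
        if self.u.shape[0] < 50:
            warnings.warn("fewer than 50 trials: surprise-minimising fits "
                          "may be poorly constrained", stacklevel=2)
        self.priors = priors or ObserverPriors()
        self.base_params = base_params or HGFParams()

    # -- objective ---------------------------------------------------------

    def _params_at(self, theta: np.ndarray) -> HGFParams:
        return replace(self.base_params,
                       **dict(zip(self.priors.free_names, theta)))

    def objective(self, theta) -> float:
        """Negative log-joint: total surprise + Gaussian prior penalty.

        Parameter values that make the filter violate a precision constraint
        (classical variant) or produce non-finite trajectories are penalised
        with +inf rather than raising.
        """
        theta = np.asarray(theta, float)
        try:
            params = self._params_at(theta)
        except ValueError:
            return np.inf
        total = total_surprise(self.u, params)
        if not np.isfinite(total):
            return np.inf
        for name, value in zip(self.priors.free_names, theta):
            total += (value - self.priors.mean[name]) ** 2 \
                / (2.0 * self.priors.var[name])
        return float(total)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0, n_restarts: int = 8, n_scan: int = 256,
            jitter_scale: float = 2.5, ftol: float = 1e-8) -> ObserverResults:
        """Scan-seeded multi-start quasi-Newton minimisation.

        The surprise surface is multimodal (a slow-learning basin near the
        prior mean can coexist, behind a barrier, with a fast-learning
        basin at larger omegas), so the objective is first evaluated on
        `n_scan` Latin-hypercube points spanning `jitter_scale` prior
        standard deviations per free parameter; the prior mean and the
        best scan points seed `n_restarts` L-BFGS-B runs, and the winner
        is polished with a Nelder-Mead simplex. Deterministic given
        `seed`.
        """
        names = self.priors.free_names
        d = len(names)
        mu0 = np.array([self.priors.mean[n] for n in names])
        sd0 = np.array([np.sqrt(self.priors.var[n]) for n in names])
        starts = [mu0]
        if n_restarts > 1 and n_scan > 0:
            sampler = stats.qmc.LatinHypercube(d=d, seed=seed)
            cand = mu0 + (sampler.random(n_scan) - 0.5) * 2 \
                * jitter_scale * sd0
            vals = np.array([self.objective(c) for c in cand])
            order = np.argsort(vals)
            starts.extend(cand[i] for i in order[:n_restarts - 1]
                          if np.isfinite(vals[i]))
        best, best_res, n_iter = None, None, 0
        with warnings.catch_warnings():
            # finite differencing across an infinite-penalty boundary
            warnings.simplefilter("ignore", RuntimeWarning)
            for x0 in starts:
                res = optimize.minimize(
                    self.objective, x0, method="L-BFGS-B",
                    options={"ftol": ftol, "maxiter": 500})
                n_iter += res.nit
                if np.isfinite(res.fun) and (best is None or
                                             res.fun < best):
                    best, best_res = res.fun, res
            if best_res is not None:
                polish = optimize.minimize(
                    self.objective, best_res.x, method="Nelder-Mead",
                    options={"xatol": 1e-7, "fatol": 1e-10,
                             "maxiter": 2000})
                n_iter += polish.nit
                if np.isfinite(polish.fun) and polish.fun <= best_res.fun:
                    best_res = polish
        if best_res is None:
            raise FitFailure(
                f"all {len(starts)} restarts failed to produce a finite "
                f"objective (free parameters: {names})")
        fitted = self._params_at(best_res.x)
        return ObserverResults(
            params=fitted, objective=float(best_res.fun), free_names=names,
            converged=bool(best_res.success), n_restarts=len(starts),
            n_iterations=int(n_iter), seed=seed, model=self)
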
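"""Sensor-space statistics: difference waveforms, scalp-image conversion and
smoothing, single-trial GLMs, group/covariate inference with
permutation-based family-wise-error control.

Channel x time data are linearly interpolated onto a 2-D scalp grid
(azimuthal-equidistant head projection), smoothed with a mask-aware Gaussian
kernel, and analysed mass-univariately. First-level models regress per-trial
voltage images on z-standardised learning trajectories; the resulting beta
images feed second-level one-sample or covariate GLMs. Family-wise error is
controlled by permutation (subject sign-flipping for one-sample designs,
covariate-row permutation otherwise) using max-cluster-mass and
max-statistic null distributions; clusters are connected components of the
supra-threshold |t| map with 26-connectivity over (x, y, time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import Delaunay, QhullError

from .synthetic import EpochStack, SensorLayout

__all__ = [
    "ScalpGrid", "ScalpMapper", "ScalpImageStack", "StatMap",
    "difference_waveform", "component_mean", "to_scalp_images",
    "smooth_images", "SingleTrialGLM", "SingleTrialGLMResults",
    "GroupModel", "GroupResults", "second_level_onesample",
    "second_level_covariate", "cluster_inference", "CANONICAL_DESIGNS",
]

HEAD_RADIUS_MM = 100.0  # unit-disc radius -> mm scale of the projection

CANONICAL_DESIGNS = {
    "lowlevel": ("delta1", "psi2"),
    "highlevel": ("delta2", "psi3"),
    "pwpe": ("eps2", "eps3"),
}


# --------------------------------------------------------------------------
# waveform-level operations
# --------------------------------------------------------------------------

def difference_waveform(epochs: EpochStack, selector_deviant=None,
                        selector_standard=None, phase: str | None = None
                        ) -> np.ndarray:
    """Average deviant ERP minus average standard ERP (channels x time).

    Selectors are boolean masks over trials; by default trial_type metadata
    is used, optionally restricted to one phase.
    """
    tt = epochs.trials["trial_type"].to_numpy()
    if selector_deviant is None:
        selector_deviant = tt == "deviant"
    if selector_standard is None:
        selector_standard = tt == "standard"
    selector_deviant = np.asarray(selector_deviant, bool)
    selector_standard = np.asarray(selector_standard, bool)
    if phase is not None:
        ph = epochs.trials["phase"].to_numpy() == phase
        selector_deviant = selector_deviant & ph
        selector_standard = selector_standard & ph
    if not selector_deviant.any():
        raise ValueError("empty deviant selection"
                         + (f" (phase={phase})" if phase else ""))
    if not selector_standard.any():
        raise ValueError("empty standard selection"
                         + (f" (phase={phase})" if phase else ""))
    return (epochs.voltages[selector_deviant].mean(axis=0)
            - epochs.voltages[selector_standard].mean(axis=0))


def component_mean(waveform: np.ndarray, times: np.ndarray,
                   window_ms: tuple[float, float]) -> np.ndarray:
    """Time-mean of a channels x time waveform over a component window."""
    lo, hi = window_ms
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        raise ValueError(f"window {window_ms} outside epoch times")
    return waveform[..., sel].mean(axis=-1)


# --------------------------------------------------------------------------
# scalp images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalpGrid:
    """Regular 2-D grid over the projected head (unit disc)."""

    n_x: int = 32
    n_y: int = 32
    extent: float = 1.0

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.n_x)

    @property
    def ys(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.n_y)

    @property
    def mm_per_voxel(self) -> tuple[float, float]:
        return (2 * self.extent * HEAD_RADIUS_MM / (self.n_x - 1),
                2 * self.extent * HEAD_RADIUS_MM / (self.n_y - 1))


class ScalpMapper:
    """Precomputed linear interpolation from channels to grid voxels.

    Barycentric weights over the Delaunay triangulation of the projected
    channel positions are computed once; mapping any channels x time array is
    then a single matrix product. Voxels outside the channel convex hull are
    masked invalid.
    """

    def __init__(self, layout: SensorLayout, grid: ScalpGrid | None = None):
        self.layout = layout
        self.grid = grid or ScalpGrid()
        pts = layout.pos2d
        try:
            tri = Delaunay(pts)
        except QhullError as exc:
            raise ValueError("degenerate (collinear) channel layout") from exc
        gx, gy = np.meshgrid(self.grid.xs, self.grid.ys, indexing="ij")
        q = np.column_stack([gx.ravel(), gy.ravel()])
        simplex = tri.find_simplex(q)
        inside = simplex >= 0
        self.mask = inside.reshape(self.grid.n_x, self.grid.n_y)
        W = np.zeros((q.shape[0], layout.n_channels))
        T = tri.transform[simplex[inside]]
        bary = np.einsum("ijk,ik->ij", T[:, :2], q[inside] - T[:, 2])
        bary = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
        verts = tri.simplices[simplex[inside]]
        rows = np.flatnonzero(inside)
        for j in range(3):
            W[rows, verts[:, j]] += bary[:, j]
        self.weights = W  # (n_voxels_total, n_channels)

    def map(self, data: np.ndarray) -> np.ndarray:
        """channels-first-last mapping: (..., channels, time) ->
        (..., n_x, n_y, time); out-of-mask voxels are NaN."""
        out = np.einsum("vc,...ct->...vt", self.weights, data)
        shape = data.shape[:-2] + (self.grid.n_x, self.grid.n_y,
                                   data.shape[-1])
        out = out.reshape(shape)
        out[..., ~self.mask, :] = np.nan
        return out


@dataclass
class ScalpImageStack:
    """units (trials or subjects) x grid_x x grid_y x time images."""

    images: np.ndarray   # (n_units, n_x, n_y, n_t); NaN outside mask
    mask: np.ndarray     # (n_x, n_y) bool, in-head/in-hull voxels
    times: np.ndarray    # ms
    grid: ScalpGrid
    layout: SensorLayout | None = None

    @property
    def n_units(self) -> int:
        return self.images.shape[0]

    def restrict(self, window_ms: tuple[float, float]) -> "ScalpImageStack":
        lo, hi = window_ms
        sel = (self.times >= lo) & (self.times <= hi)
        if not sel.any():
            raise ValueError(f"window {window_ms} excludes all samples")
        return ScalpImageStack(images=self.images[..., sel], mask=self.mask,
                               times=self.times[sel], grid=self.grid,
                               layout=self.layout)

    def nearest_channel(self, ix: int, iy: int) -> str | None:
        if self.layout is None:
            return None
        p = np.array([self.grid.xs[ix], self.grid.ys[iy]])
        d = np.linalg.norm(self.layout.pos2d - p, axis=1)
        return self.layout.names[int(np.argmin(d))]


def to_scalp_images(data: np.ndarray, layout: SensorLayout,
                    times: np.ndarray, grid: ScalpGrid | None = None,
                    mapper: ScalpMapper | None = None) -> ScalpImageStack:
    """Convert (units x) channels x time data to scalp images.

    2-D linear interpolation per time sample; a 2-D input is treated as one
    unit. Pass a prebuilt `mapper` to amortise the triangulation.
    """
    if layout.n_channels < 3:
        raise ValueError("need at least 3 channels")
    if data.ndim == 2:
        data = data[None]
    mapper = mapper or ScalpMapper(layout, grid)
    return ScalpImageStack(images=mapper.map(data), mask=mapper.mask.copy(),
                           times=np.asarray(times), grid=mapper.grid,
                           layout=layout)


def smooth_images(stack: ScalpImageStack,
                  fwhm_mm: tuple[float, float] = (16.0, 16.0),
                  temporal_fwhm_ms: float = 0.0) -> ScalpImageStack:
    """Mask-aware Gaussian smoothing (invalid voxels carry no kernel mass).

    Spatial FWHM is given in mm and converted through the grid's mm-per-voxel
    scale; FWHM 0 is the identity. Implemented by smoothing the zero-filled
    image and the mask separately and renormalising.
    """
    if min(fwhm_mm) < 0 or temporal_fwhm_ms < 0:
        raise ValueError("FWHM must be >= 0")
    mmx, mmy = stack.grid.mm_per_voxel
    sig = [fwhm_mm[0] / 2.3548 / mmx, fwhm_mm[1] / 2.3548 / mmy]
    if temporal_fwhm_ms > 0:
        dt = float(np.median(np.diff(stack.times)))
        sig.append(temporal_fwhm_ms / 2.3548 / dt)
    else:
        sig.append(0.0)
    if all(s == 0 for s in sig):
        return ScalpImageStack(images=stack.images.copy(),
                               mask=stack.mask.copy(), times=stack.times,
                               grid=stack.grid, layout=stack.layout)
    filled = np.nan_to_num(stack.images, nan=0.0)
    m3 = np.broadcast_to(stack.mask[..., None].astype(float),
                         stack.images.shape[1:])
    sm_mask = ndimage.gaussian_filter(np.ascontiguousarray(m3), sigma=sig)
    out = np.empty_like(stack.images)
    for i in range(stack.n_units):
        sm = ndimage.gaussian_filter(filled[i], sigma=sig)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(sm_mask > 1e-12, sm / sm_mask, np.nan)
    out[..., ~stack.mask, :] = np.nan
    return ScalpImageStack(images=out, mask=stack.mask.copy(),
                           times=stack.times, grid=stack.grid,
                           layout=stack.layout)


# --------------------------------------------------------------------------
# first level: single-trial GLM
# --------------------------------------------------------------------------

def _ols_tmaps(X: np.ndarray, Y: np.ndarray):
    """OLS betas and per-column t for Y (n x V). Returns (betas, t, dof)."""
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise ValueError("not enough observations for the design")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        raise ValueError(
            f"rank-deficient design (regressor correlations:\n{corr})"
        ) from exc
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        t = np.where(se > 0, beta / se,
                     np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    return beta, t, dof


class SingleTrialGLM:
    """First-level mass-univariate GLM of per-trial scalp images on
    z-standardised learning trajectories.

    Design: intercept + named regressors, z-scored over the retained trials
    and deliberately *not* orthogonalised. Three canonical designs are
    available by name: ``lowlevel`` (delta1, psi2), ``highlevel``
    (delta2, psi3), ``pwpe`` (eps2, eps3).
    """

    def __init__(self, images: ScalpImageStack, regressors: pd.DataFrame):
        if len(regressors) != images.n_units:
            raise ValueError("regressors must align with retained trials")
        if images.n_units < regressors.shape[1] + 3:
            raise ValueError("too few retained trials for the design")
        self.images = images
        self.regressors = regressors

    @classmethod
    def from_design(cls, images: ScalpImageStack, traj_table: pd.DataFrame,
                    design: str, retained=None) -> "SingleTrialGLM":
        names = CANONICAL_DESIGNS[design]
        reg = traj_table[list(names)]
        if retained is not None:
            reg = reg.iloc[np.asarray(retained)]
        return cls(images, reg.reset_index(drop=True))

    def fit(self) -> "SingleTrialGLMResults":
        Z = self.regressors.to_numpy(float)
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            bad = [c for c, s in zip(self.regressors.columns, sd) if s == 0]
            raise ValueError(f"zero-variance regressors: {bad}")
        Z = (Z - Z.mean(axis=0)) / sd
        X = np.column_stack([np.ones(len(Z)), Z])
        flat = self.images.images.reshape(self.images.n_units, -1)
        valid = ~np.isnan(flat[0])
        beta, t, dof = _ols_tmaps(X, flat[:, valid])
        shape = self.images.images.shape[1:]
        names = ["intercept"] + list(self.regressors.columns)
        betas, tmaps = {}, {}
        for j, name in enumerate(names):
            b = np.full(flat.shape[1], np.nan)
            b[valid] = beta[j]
            betas[name] = b.reshape(shape)
            tm = np.full(flat.shape[1], np.nan)
            tm[valid] = t[j]
            tmaps[name] = tm.reshape(shape)
        return SingleTrialGLMResults(model=self, betas=betas, tmaps=tmaps,
                                     dof=dof, design_matrix=X, names=names)


@dataclass
class SingleTrialGLMResults:
    """Beta/t/F images per design column (F = t^2 for single columns)."""

    model: SingleTrialGLM
    betas: dict
    tmaps: dict
    dof: int
    design_matrix: np.ndarray
    names: list

    def fmap(self, name: str) -> np.ndarray:
        return self.tmaps[name] ** 2

    def beta_stack(self, name: str) -> ScalpImageStack:
        im = self.model.images
        return ScalpImageStack(images=self.betas[name][None], mask=im.mask,
                               times=im.times, grid=im.grid, layout=im.layout)

    def summary(self) -> str:
        lines = ["Single-trial GLM", "=" * 40,
                 f"trials {self.design_matrix.shape[0]}, "
                 f"columns {self.names}, dof {self.dof}"]
        for name in self.names[1:]:
            t = self.tmaps[name]
            lines.append(f"{name:<10} max|t| "
                         f"{np.nanmax(np.abs(t)):.2f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# second level
# --------------------------------------------------------------------------

@dataclass
class StatMap:
    """Statistic map with permutation-corrected cluster/peak table."""

    tmap: np.ndarray              # (n_x, n_y, n_t), NaN outside mask
    mask: np.ndarray
    times: np.ndarray
    dof: int
    cdt_p: float
    clusters: pd.DataFrame        # id, mass, extent, peak stats, p values
    method: str = "permutation_maxstat"
    n_perm: int = 0
    seed: int | None = None

    @property
    def fmap(self) -> np.ndarray:
        return self.tmap ** 2

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.clusters[self.clusters["p_cluster"] <= alpha]

    def label_volume(self) -> np.ndarray:
        """Cluster-id volume (0 outside clusters), matching the table ids."""
        thr = stats.t.ppf(1 - self.cdt_p / 2, self.dof)
        above = np.nan_to_num(np.abs(self.tmap)) > thr
        lab, _ = ndimage.label(above, structure=np.ones((3, 3, 3), int))
        return lab

    def covers(self, ix: int, iy: int, time_ms: float,
               alpha: float = 0.05, tol_ms: float = 0.0) -> bool:
        """Does a significant cluster contain voxel (ix, iy) at time_ms
        (or within +-tol_ms of it)?"""
        sig_ids = set(self.significant(alpha)["cluster"])
        if not sig_ids:
            return False
        lab = self.label_volume()
        sel = np.abs(self.times - time_ms) <= max(
            tol_ms, np.median(np.diff(self.times)) / 2)
        return bool(np.isin(lab[ix, iy, sel], list(sig_ids)).any())

    def summary(self) -> str:
        lines = [f"StatMap ({self.method}, n_perm={self.n_perm}, "
                 f"cdt p<{self.cdt_p}, dof={self.dof})"]
        if self.clusters.empty:
            lines.append("no supra-threshold clusters")
        else:
            lines.append(self.clusters.to_string(index=False,
                                                 float_format="%.4g"))
        return "\n".join(lines)


class GroupModel:
    """Second-level model over subject images.

    With ``covariate=None`` this is a one-sample test on subject images
    (mean against zero, permutation null by sign-flipping). With a covariate
    it is a per-voxel regression of subject images on
    [1, covariate, nuisance...] with the covariate's t as the target
    statistic (permutation null by covariate-row shuffling).
    """

    def __init__(self, subject_images: ScalpImageStack,
                 covariate: np.ndarray | None = None,
                 nuisance: np.ndarray | None = None):
        if subject_images.n_units < 3:
            raise ValueError("need at least 3 subjects")
        self.images = subject_images
        self.covariate = None if covariate is None else np.asarray(
            covariate, float)
        if self.covariate is not None:
            if self.covariate.shape[0] != subject_images.n_units:
                raise ValueError("covariate length must equal n subjects")
            if np.std(self.covariate) == 0:
                raise ValueError("constant covariate")
        self.nuisance = None
        if nuisance is not None:
            self.nuisance = np.atleast_2d(np.asarray(nuisance, float))
            if self.nuisance.shape[0] == subject_images.n_units:
                pass
            elif self.nuisance.shape[1] == subject_images.n_units:
                self.nuisance = self.nuisance.T
            else:
                raise ValueError("nuisance shape mismatch")

    # -- statistic computation --------------------------------------------

    def _design(self, covariate) -> np.ndarray:
        cols = [np.ones(self.images.n_units), covariate]
        if self.nuisance is not None:
            cols.extend(self.nuisance.T)
        return np.column_stack(cols)

    def _tmap_flat(self, Y: np.ndarray, covariate=None,
                   signs=None) -> tuple[np.ndarray, int]:
        n = Y.shape[0]
        if self.covariate is None:
            ys = Y if signs is None else signs[:, None] * Y
            mean = ys.mean(axis=0)
            var = ys.var(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var > 0, mean / np.sqrt(var / n),
                             np.where(mean == 0, 0.0,
                                      np.sign(mean) * np.inf))
            return t, n - 1
        cov = self.covariate if covariate is None else covariate
        X = self._design(cov)
        _, t, dof = _ols_tmaps(X, Y)
        return t[1], dof

    def fit(self) -> "GroupResults":
        flat = self.images.images.reshape(self.images.n_units, -1)
        valid = ~np.isnan(flat[0])
        t, dof = self._tmap_flat(flat[:, valid])
        tmap = np.full(flat.shape[1], np.nan)
        tmap[valid] = t
        return GroupResults(model=self,
                            tmap=tmap.reshape(self.images.images.shape[1:]),
                            dof=dof)


@dataclass
class GroupResults:
    model: GroupModel
    tmap: np.ndarray
    dof: int

    def cluster_inference(self, cdt_p: float = 0.001, alpha: float = 0.05,
                          n_perm: int = 1000, seed: int = 0,
                          window_ms: tuple[float, float] | None = (100.0,
                                                                   400.0)
                          ) -> StatMap:
        """Permutation-corrected cluster and peak inference.

        Clusters are 26-connected components of |t| above the two-sided
        cluster-defining threshold; the null distributions of max cluster
        mass and max |t| are built by sign-flipping (one-sample) or
        covariate permutation. Corrected p = (1 + #{null >= obs})/(1 + n_perm).
        """
        import warnings
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} gives coarse p-values",
                          stacklevel=2)
        images = self.model.images
        if window_ms is not None:
            images = images.restrict(window_ms)
        flat = images.images.reshape(images.n_units, -1)
        valid = ~np.isnan(flat[0])
        Yv = flat[:, valid]
        t_obs, dof = self.model._tmap_flat(Yv)
        thr = stats.t.ppf(1 - cdt_p / 2, dof)
        shape = images.images.shape[1:]
        mask3d = np.zeros(np.prod(shape), bool)
        mask3d[valid] = True
        mask3d = mask3d.reshape(shape)

        def cluster_stats(t_flat):
            tvol = np.zeros(shape)
            tvol[mask3d] = t_flat
            lab, nlab = ndimage.label(np.abs(tvol) > thr,
                                      structure=np.ones((3, 3, 3), int))
            if nlab == 0:
                return tvol, lab, []
            out = []
            for cid in range(1, nlab + 1):
                sel = lab == cid
                vals = np.abs(tvol[sel])
                out.append((cid, float(vals.sum()), int(sel.sum()),
                            float(vals.max())))
            return tvol, lab, out

        tvol, lab, obs = cluster_stats(t_obs)

        rng = np.random.default_rng(seed)
        null_mass = np.zeros(n_perm)
        null_max = np.zeros(n_perm)
        for b in range(n_perm):
            if self.model.covariate is None:
                signs = rng.choice([-1.0, 1.0], size=images.n_units)
                t_b, _ = self.model._tmap_flat(Yv, signs=signs)
            else:
                perm = rng.permutation(images.n_units)
                t_b, _ = self.model._tmap_flat(
                    Yv, covariate=self.model.covariate[perm])
            finite = np.isfinite(t_b)
            if not finite.any():
                continue
            null_max[b] = np.abs(t_b[finite]).max()
            above = np.abs(t_b) > thr
            if above.any():
                tvol_b = np.zeros(shape)
                tvol_b[mask3d] = np.where(np.isfinite(t_b), t_b, 0.0)
                lab_b, n_b = ndimage.label(
                    np.abs(tvol_b) > thr, structure=np.ones((3, 3, 3), int))
                if n_b:
                    masses = ndimage.sum_labels(np.abs(tvol_b), lab_b,
                                                np.arange(1, n_b + 1))
                    null_mass[b] = masses.max()

        rows = []
        for cid, mass, extent, peak in sorted(
                obs, key=lambda r: (-r[1], -r[2])):
            sel = lab == cid
            absvol = np.where(sel, np.abs(tvol), -np.inf)
            ix, iy, it = np.unravel_index(np.argmax(absvol), shape)
            rows.append({
                "cluster": cid, "mass": mass, "extent": extent,
                "peak_t": float(tvol[ix, iy, it]),
                "peak_x": int(ix), "peak_y": int(iy),
                "peak_time_ms": float(images.times[it]),
                "peak_channel": images.nearest_channel(int(ix), int(iy)),
                "p_cluster": float((1 + (null_mass >= mass).sum())
                                   / (1 + n_perm)),
                "p_peak": float((1 + (null_max >= abs(tvol[ix, iy, it]))
                                 .sum()) / (1 + n_perm)),
            })
        table = pd.DataFrame(
            rows, columns=["cluster", "mass", "extent", "peak_t", "peak_x",
                           "peak_y", "peak_time_ms", "peak_channel",
                           "p_cluster", "p_peak"])
        return StatMap(tmap=np.where(mask3d, tvol, np.nan), mask=mask3d,
                       times=images.times, dof=dof, cdt_p=cdt_p,
                       clusters=table, n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# spec-surface convenience wrappers
# --------------------------------------------------------------------------

def second_level_onesample(subject_images: ScalpImageStack) -> GroupResults:
    return GroupModel(subject_images).fit()


def second_level_covariate(subject_images: ScalpImageStack, covariate,
                           nuisance=None) -> GroupResults:
    return GroupModel(subject_images, covariate=covariate,
                      nuisance=nuisance).fit()


def cluster_inference(results: GroupResults, cdt_p: float = 0.001,
                      alpha: float = 0.05, n_perm: int = 1000, seed: int = 0,
                      window_ms=(100.0, 400.0)) -> StatMap:
    return results.cluster_inference(cdt_p=cdt_p, alpha=alpha, n_perm=n_perm,
                                     seed=seed, window_ms=window_ms)
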
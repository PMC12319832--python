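"""Simulation studies of the pipeline's statistical behaviour.

Monte-Carlo helpers that measure, on synthetic cohorts with known ground
truth: family-wise error of the permutation cluster inference under the
null, detection power and localisation of embedded trajectory effects, the
direction/significance of the stable-vs-volatile MMN contrast, and the
agreement of the quasi-Newton observer fit with an exhaustive grid search.

Speed note: the first-level beta images used here are computed on
channel-level data and then mapped/smoothed as images. Both the
channel-to-grid mapping and the mask-aware smoothing are fixed linear
operators and OLS is linear in the data, so this equals mapping and
smoothing per-trial images before fitting; the equivalence is asserted in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import hgf, observer, paradigm, preprocess, sensor_stats, synthetic

__all__ = ["empirical_fwe", "effect_recovery", "mmn_contrast_study",
           "fit_vs_grid", "first_level_beta_images"]


def _null_truth() -> synthetic.GroundTruth:
    return synthetic.GroundTruth(erp_components=(), effects=(),
                                 noise=synthetic.NoiseModel(),
                                 p_artifact=0.0, link=None)


def _cohort_design(n_trials: int, seed: int):
    sched = paradigm.default_schedule(n_trials)
    seq = paradigm.sample_sequence(sched, seed)
    labels = paradigm.attach_phase(paradigm.label_trials(seq), sched)
    traj = hgf.filter_sequence(seq)
    return sched, seq, labels, traj


def first_level_beta_images(stack: synthetic.EpochStack,
                            traj_table: pd.DataFrame, design: str,
                            mapper: sensor_stats.ScalpMapper,
                            retained=None) -> dict:
    """Smoothed first-level beta images per regressor of a canonical design.

    Fits the GLM on channel x time data and maps/smooths the channel-level
    betas (see module docstring for why this is exact).
    """
    names = sensor_stats.CANONICAL_DESIGNS[design]
    reg = traj_table[list(names)]
    if retained is not None:
        reg = reg.iloc[np.asarray(retained)]
    Z = reg.to_numpy(float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    X = np.column_stack([np.ones(len(Z)), Z])
    n_tr = stack.voltages.shape[0]
    flat = stack.voltages.reshape(n_tr, -1)
    beta = np.linalg.solve(X.T @ X, X.T @ flat)
    out = {}
    for j, name in enumerate(names, start=1):
        b_chan = beta[j].reshape(stack.voltages.shape[1:])
        img = sensor_stats.to_scalp_images(b_chan, stack.layout,
                                           stack.times, mapper=mapper)
        out[name] = sensor_stats.smooth_images(img).images[0]
    return out


def empirical_fwe(n_cohorts: int = 200, n_subjects: int = 8,
                  n_trials: int = 60, n_channels: int = 16, grid: int = 12,
                  n_perm: int = 200, alpha: float = 0.05, cdt_p: float = 0.001,
                  seed: int = 0, window_ms=(100.0, 400.0)) -> dict:
    """Family-wise error of cluster inference on pure-noise cohorts.

    Each cohort: subjects' deviant-minus-standard difference-waveform images
    from zero-effect epochs, one-sample permutation cluster inference; a
    family-wise error occurs when any cluster reaches corrected
    p <= alpha. Returns the empirical rate and its binomial 95% CI.
    """
    rng = np.random.default_rng(seed)
    layout = synthetic.SensorLayout.standard_1020(n_channels)
    g = sensor_stats.ScalpGrid(grid, grid)
    mapper = sensor_stats.ScalpMapper(layout, g)
    truth = _null_truth()
    # arbitrary half/half trial labelling: no signal, any split is null
    tt = np.where(np.arange(n_trials) % 2 == 0, "standard", "deviant")
    labels = paradigm.TrialLabels(
        trial_type=tt.astype("U8"),
        phase=np.full(n_trials, "stable", dtype="U8"))
    u = (np.arange(n_trials) % 2).astype(np.int8)
    traj = hgf.filter_sequence(u)
    n_fp = 0
    for _ in range(n_cohorts):
        imgs = []
        for _s in range(n_subjects):
            st = synthetic.generate_subject(
                traj, labels, truth, seed=int(rng.integers(2 ** 31)),
                layout=layout)
            wf = sensor_stats.difference_waveform(st)
            img = sensor_stats.to_scalp_images(wf, layout, st.times,
                                               mapper=mapper)
            imgs.append(sensor_stats.smooth_images(img).images[0])
        stack = sensor_stats.ScalpImageStack(
            images=np.array(imgs), mask=mapper.mask.copy(), times=st.times,
            grid=g, layout=layout)
        smap = sensor_stats.GroupModel(stack).fit().cluster_inference(
            cdt_p=cdt_p, alpha=alpha, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)), window_ms=window_ms)
        n_fp += int((smap.clusters["p_cluster"] <= alpha).any())
    rate = n_fp / n_cohorts
    se = np.sqrt(alpha * (1 - alpha) / n_cohorts)
    return {"fwe": rate, "n_cohorts": n_cohorts, "alpha": alpha,
            "ci_low": alpha - 1.96 * se, "ci_high": alpha + 1.96 * se}


def effect_recovery(n_cohorts: int = 50, n_subjects: int = 20,
                    n_trials: int = 400, n_channels: int = 16,
                    grid: int = 12, n_perm: int = 200, alpha: float = 0.05,
                    cdt_p: float = 0.001, seed: int = 0,
                    targets=(("lowlevel", "delta1"), ("highlevel", "psi3")),
                    tol_ms: float = 12.0,
                    window_ms=(100.0, 400.0)) -> dict:
    """Detection power for embedded trajectory effects.

    A target counts as detected in a cohort when a cluster with corrected
    p <= alpha contains the embedded topography-centre voxel within
    `tol_ms` of the embedded latency.
    """
    rng = np.random.default_rng(seed)
    layout = synthetic.SensorLayout.standard_1020(n_channels)
    g = sensor_stats.ScalpGrid(grid, grid)
    mapper = sensor_stats.ScalpMapper(layout, g)
    truth = synthetic.default_truth()
    truth = replace(truth, link=None, p_artifact=0.0)
    _, seq, labels, traj = _cohort_design(n_trials, seed=int(
        rng.integers(2 ** 31)))
    eff_by_name = {e.regressor: e for e in truth.effects}
    xs, ys = g.xs, g.ys
    hits = {f"{d}:{r}": 0 for d, r in targets}
    for _c in range(n_cohorts):
        stacks, _ = synthetic.generate_cohort(
            n_subjects, traj, labels, truth,
            master_seed=int(rng.integers(2 ** 31)), layout=layout,
            tones=seq.u)
        betas = {key: [] for key in hits}
        for st in stacks:
            clean, rep = preprocess.preprocess_epochs(st)
            for design, regname in targets:
                b = first_level_beta_images(clean, traj.table, design,
                                            mapper, retained=rep.retained)
                betas[f"{design}:{regname}"].append(b[regname])
        for design, regname in targets:
            key = f"{design}:{regname}"
            stack = sensor_stats.ScalpImageStack(
                images=np.array(betas[key]), mask=mapper.mask.copy(),
                times=stacks[0].times, grid=g, layout=layout)
            smap = sensor_stats.GroupModel(stack).fit().cluster_inference(
                cdt_p=cdt_p, alpha=alpha, n_perm=n_perm,
                seed=int(rng.integers(2 ** 31)), window_ms=window_ms)
            eff = eff_by_name[regname]
            c = synthetic._center2d(layout, eff.channel)
            cx = int(np.argmin(np.abs(xs - c[0])))
            cy = int(np.argmin(np.abs(ys - c[1])))
            hits[key] += int(smap.covers(cx, cy, eff.latency_ms,
                                         alpha=alpha, tol_ms=tol_ms))
    return {key: n / n_cohorts for key, n in hits.items()} | {
        "n_cohorts": n_cohorts}


def mmn_contrast_study(n_subjects: int = 43, n_trials: int = 1800,
                       n_channels: int = 16, grid: int = 12,
                       n_perm: int = 400, cdt_p: float = 0.001,
                       seed: int = 0) -> dict:
    """Paired stable-minus-volatile difference-waveform contrast on one
    embedded-MMN cohort at study scale.

    Returns the grand-average MMN-window amplitudes per phase at the
    frontocentral centre, and the most significant cluster of the paired
    contrast (expected negative: stable difference more negative).
    """
    rng = np.random.default_rng(seed)
    layout = synthetic.SensorLayout.standard_1020(n_channels)
    g = sensor_stats.ScalpGrid(grid, grid)
    mapper = sensor_stats.ScalpMapper(layout, g)
    truth = replace(synthetic.default_truth(), effects=(), link=None)
    _, seq, labels, traj = _cohort_design(n_trials, seed=int(
        rng.integers(2 ** 31)))
    stacks, _ = synthetic.generate_cohort(
        n_subjects, traj, labels, truth,
        master_seed=int(rng.integers(2 ** 31)), layout=layout, tones=seq.u)
    imgs, mmn_amp = [], {"stable": [], "volatile": []}
    fc = np.argmin(np.linalg.norm(
        layout.pos2d - synthetic._center2d(layout, "FCz"), axis=1))
    for st in stacks:
        clean, _ = preprocess.preprocess_epochs(st)
        wfs = {}
        for ph in ("stable", "volatile"):
            wfs[ph] = sensor_stats.difference_waveform(clean, phase=ph)
            mmn_amp[ph].append(float(sensor_stats.component_mean(
                wfs[ph], clean.times, (150.0, 200.0))[fc]))
        diff = wfs["stable"] - wfs["volatile"]
        img = sensor_stats.to_scalp_images(diff, layout, clean.times,
                                           mapper=mapper)
        imgs.append(sensor_stats.smooth_images(img).images[0])
    stack = sensor_stats.ScalpImageStack(
        images=np.array(imgs), mask=mapper.mask.copy(),
        times=stacks[0].times, grid=g, layout=layout)
    smap = sensor_stats.GroupModel(stack).fit().cluster_inference(
        cdt_p=cdt_p, alpha=0.05, n_perm=n_perm,
        seed=int(rng.integers(2 ** 31)))
    out = {
        "mmn_stable_uV": float(np.mean(mmn_amp["stable"])),
        "mmn_volatile_uV": float(np.mean(mmn_amp["volatile"])),
        "n_subjects": n_subjects,
    }
    if not smap.clusters.empty:
        top = smap.clusters.iloc[0]
        out |= {"peak_t": float(top["peak_t"]),
                "p_cluster": float(top["p_cluster"]),
                "peak_time_ms": float(top["peak_time_ms"])}
    else:
        out |= {"peak_t": np.nan, "p_cluster": np.nan,
                "peak_time_ms": np.nan}
    return out


def fit_vs_grid(n_seeds: int = 10, n_trials: int = 200, n_grid: int = 201,
                omega2_range=(-8.0, 2.0), omega3_range=(-9.0, 3.0),
                seed: int = 0) -> dict:
    """Distance between the quasi-Newton optimum and an exhaustive
    omega-grid minimum, over several simulated sequences."""
    from scipy import optimize

    rng = np.random.default_rng(seed)
    w2s = np.linspace(*omega2_range, n_grid)
    w3s = np.linspace(*omega3_range, n_grid)
    gaps = []
    for _ in range(n_seeds):
        seq = paradigm.sample_sequence(
            paradigm.default_schedule(n_trials), int(rng.integers(2 ** 31)))
        model = observer.BayesOptimalObserver(seq)
        res = model.fit(seed=int(rng.integers(2 ** 31)))
        vals = np.array([[model.objective([w2, w3]) for w3 in w3s]
                         for w2 in w2s])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        # two-stage oracle: exhaustive grid localises the global basin, a
        # local descent from the grid argmin resolves the within-basin
        # discretisation (the surprise valley floor can be very shallow)
        polish = optimize.minimize(model.objective, [w2s[i], w3s[j]],
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-6, "fatol": 1e-10})
        gaps.append(max(abs(res.params.omega2 - polish.x[0]),
                        abs(res.params.omega3 - polish.x[1])))
    return {"max_gap": float(np.max(gaps)), "gaps": [float(x) for x in gaps],
            "grid": n_grid, "n_seeds": n_seeds}
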
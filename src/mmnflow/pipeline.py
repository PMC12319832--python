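"""End-to-end orchestration: simulate -> trajectories -> preprocess ->
stats -> report, with config, seeds and provenance."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import hgf, observer, paradigm, preprocess, sensor_stats, synthetic

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Full run configuration; round-trips losslessly through YAML."""

    n_trials: int = 600
    n_subjects: int = 5
    n_channels: int = 16
    grid: int = 16
    n_perm: int = 200
    cdt_p: float = 0.001
    alpha: float = 0.05
    window_ms: tuple = (100.0, 400.0)
    threshold_uV: float = 75.0
    baseline_ms: tuple = (-100.0, 0.0)
    designs: tuple = ("lowlevel", "highlevel", "pwpe")
    fit_observer: bool = True
    seed: int = 0
    out_dir: str = "mmnflow_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def validate(self) -> None:
        lo, hi = self.window_ms
        if not (-100.0 <= lo < hi <= 500.0):
            raise ValueError(f"invalid analysis window {self.window_ms}")
        for d in self.designs:
            if d not in sensor_stats.CANONICAL_DESIGNS:
                raise ValueError(f"unknown design {d!r}")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)   # path -> sha256
    warnings: list = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def add_file(self, path) -> None:
        p = Path(path)
        self.files[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seeds": self.seeds,
                       "stages": self.stages, "files": self.files,
                       "warnings": self.warnings}, fh, indent=2)


def _derive_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ["sequence", "cohort", "fit", "perm"]
    return {n: int(s.generate_state(1)[0] % (2 ** 31))
            for n, s in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; aborts with the failing stage's name and
    persists the partial manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    config.to_yaml(cfg_path)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_path.read_bytes()).hexdigest(),
        seeds=_derive_seeds(config.seed))
    manifest.add_file(cfg_path)

    state: dict = {}
    stages = [
        ("paradigm", _stage_paradigm), ("observer", _stage_observer),
        ("simulate", _stage_simulate), ("preprocess", _stage_preprocess),
        ("stats", _stage_stats),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            fn(config, manifest, state, out)
        except Exception as exc:
            manifest.stages.append(
                {"stage": name, "status": "failed", "error": str(exc)})
            manifest.save(out / "manifest.json")
            raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}"
                               ) from exc
        manifest.stages.append({"stage": name, "status": "ok",
                                "seconds": round(time.time() - t0, 2)})
    manifest.save(out / "manifest.json")
    manifest.add_file(out / "manifest.json")
    state["manifest"] = manifest
    return manifest


def _stage_paradigm(cfg, manifest, state, out):
    sched = paradigm.default_schedule(cfg.n_trials)
    seq = paradigm.sample_sequence(sched, manifest.seeds["sequence"])
    labels = paradigm.attach_phase(paradigm.label_trials(seq), sched)
    paradigm.write_design_tsv(out / "design.tsv", sched, seq)
    manifest.add_file(out / "design.tsv")
    state.update(schedule=sched, sequence=seq, labels=labels)


def _stage_observer(cfg, manifest, state, out):
    if cfg.fit_observer:
        model = observer.BayesOptimalObserver(state["sequence"])
        fit = model.fit(seed=manifest.seeds["fit"])
        params = fit.params
        (out / "observer_fit.json").write_text(
            json.dumps(fit.to_dict(), indent=2))
        manifest.add_file(out / "observer_fit.json")
    else:
        params = hgf.HGFParams()
    traj = hgf.filter_sequence(state["sequence"], params)
    traj.to_tsv(out / "trajectories.tsv")
    manifest.add_file(out / "trajectories.tsv")
    state["trajectories"] = traj
    state["collinearity"] = {
        f"{a}~{b}": hgf.regressor_collinearity(traj, (a, b))
        for a, b in sensor_stats.CANONICAL_DESIGNS.values()}


def _stage_simulate(cfg, manifest, state, out):
    layout = synthetic.SensorLayout.standard_1020(cfg.n_channels)
    truth = synthetic.default_truth()
    stacks, covars = synthetic.generate_cohort(
        cfg.n_subjects, state["trajectories"], state["labels"], truth,
        master_seed=manifest.seeds["cohort"], layout=layout,
        tones=state["sequence"].u)
    covars.to_csv(out / "covariates.csv", index=False)
    manifest.add_file(out / "covariates.csv")
    state.update(stacks=stacks, covariates=covars, layout=layout,
                 truth=truth)


def _stage_preprocess(cfg, manifest, state, out):
    clean, reports = [], []
    for st in state["stacks"]:
        c, rep = preprocess.preprocess_epochs(
            st, baseline_ms=tuple(cfg.baseline_ms),
            threshold_uV=cfg.threshold_uV)
        clean.append(c)
        reports.append(rep.to_dict())
    (out / "preprocess_report.json").write_text(
        json.dumps(reports, indent=2))
    manifest.add_file(out / "preprocess_report.json")
    state["clean"] = clean
    state["reports"] = reports


def _stage_stats(cfg, manifest, state, out):
    grid = sensor_stats.ScalpGrid(cfg.grid, cfg.grid)
    mapper = sensor_stats.ScalpMapper(state["layout"], grid)
    traj = state["trajectories"]
    results = {}

    # ERP contrast: stable vs volatile difference waveform (paired)
    diff_imgs = {ph: [] for ph in ("stable", "volatile")}
    for st in state["clean"]:
        for ph in diff_imgs:
            wf = sensor_stats.difference_waveform(st, phase=ph)
            img = sensor_stats.to_scalp_images(wf, st.layout, st.times,
                                               mapper=mapper)
            diff_imgs[ph].append(sensor_stats.smooth_images(img).images[0])
    paired = sensor_stats.ScalpImageStack(
        images=np.array(diff_imgs["stable"]) - np.array(
            diff_imgs["volatile"]),
        mask=mapper.mask.copy(), times=state["clean"][0].times, grid=grid,
        layout=state["layout"])
    sm = sensor_stats.GroupModel(paired).fit().cluster_inference(
        cdt_p=cfg.cdt_p, alpha=cfg.alpha, n_perm=cfg.n_perm,
        seed=manifest.seeds["perm"], window_ms=tuple(cfg.window_ms))
    results["mmn_stable_vs_volatile"] = sm

    # first-level trajectory GLMs -> second-level one-sample maps
    # (trial images are design-independent: convert and smooth once)
    subj_imgs = []
    for st in state["clean"]:
        imgs = sensor_stats.to_scalp_images(
            st.voltages, st.layout, st.times, mapper=mapper)
        subj_imgs.append(sensor_stats.smooth_images(imgs))
    for design in cfg.designs:
        names = sensor_stats.CANONICAL_DESIGNS[design]
        subj_betas = {n: [] for n in names}
        for imgs, rep in zip(subj_imgs, state["reports"]):
            retained = np.array(rep["retained"], int)
            glm = sensor_stats.SingleTrialGLM.from_design(
                imgs, traj.table, design, retained=retained).fit()
            for n in names:
                subj_betas[n].append(glm.betas[n])
        for n in names:
            stack = sensor_stats.ScalpImageStack(
                images=np.array(subj_betas[n]), mask=mapper.mask.copy(),
                times=state["clean"][0].times, grid=grid,
                layout=state["layout"])
            res = sensor_stats.GroupModel(stack).fit()
            results[f"{design}:{n}"] = res.cluster_inference(
                cdt_p=cfg.cdt_p, alpha=cfg.alpha, n_perm=cfg.n_perm,
                seed=manifest.seeds["perm"], window_ms=tuple(cfg.window_ms))

    tables = []
    for name, smap in results.items():
        tab = smap.clusters.copy()
        tab.insert(0, "analysis", name)
        tables.append(tab)
    non_empty = [t for t in tables if not t.empty]
    all_tab = pd.concat(non_empty, ignore_index=True) if non_empty \
        else tables[0]
    all_tab.to_csv(out / "cluster_table.tsv", sep="\t", index=False)
    manifest.add_file(out / "cluster_table.tsv")
    state["statmaps"] = results


def make_report(config: RunConfig, state: dict, out_dir=None) -> Path:
    """Markdown report with schedule, trajectory, ERP and stat-map panels."""
    out = Path(out_dir or config.out_dir)
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    lines = ["# mmnflow run report", ""]

    sched, traj = state["schedule"], state["trajectories"]
    fig, axes = plt.subplots(3, 1, figsize=(8, 7), sharex=True)
    axes[0].plot(sched.p_high, "k")
    axes[0].set_ylabel("p(high tone)")
    stable = sched.phase == "stable"
    axes[0].fill_between(np.arange(sched.n_trials), 0, 1, where=stable,
                         alpha=0.15, color="tab:blue", label="stable")
    axes[0].legend(loc="upper right")
    axes[1].plot(traj.muhat1, lw=0.7)
    axes[1].set_ylabel(r"$\hat\mu_1$")
    axes[2].plot(traj.eps2, lw=0.7, label=r"$\epsilon_2$")
    axes[2].plot(traj.eps3, lw=0.7, label=r"$\epsilon_3$")
    axes[2].set_ylabel("pwPE")
    axes[2].set_xlabel("trial")
    axes[2].legend()
    fig.tight_layout()
    fig.savefig(figdir / "schedule_trajectories.png", dpi=110)
    plt.close(fig)
    lines += ["## Paradigm and observer trajectories",
              "![](figures/schedule_trajectories.png)", ""]

    lines += ["## Regressor collinearity (Pearson r over retained trials)",
              "", "| pair | r |", "|---|---|"]
    for pair, r in state["collinearity"].items():
        lines.append(f"| {pair} | {r:.3f} |")
    lines.append("")

    clean = state["clean"][0]
    fig, ax = plt.subplots(figsize=(7, 4))
    for ph, color in (("stable", "tab:blue"), ("volatile", "tab:orange")):
        wf = np.mean([sensor_stats.difference_waveform(c, phase=ph)
                      for c in state["clean"]], axis=0)
        fcz = clean.layout.index("FCz") if "FCz" in clean.layout.names else 0
        ax.plot(clean.times, wf[fcz], color=color, label=f"{ph} difference")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "difference_waveforms.png", dpi=110)
    plt.close(fig)
    lines += ["## Difference waveforms (frontocentral)",
              "![](figures/difference_waveforms.png)", ""]

    lines.append("## Cluster tables (permutation FWE)")
    for name, smap in state.get("statmaps", {}).items():
        lines += ["", f"### {name}", "```", smap.summary(), "```"]
        fig, ax = plt.subplots(figsize=(6, 3))
        mip = np.nanmax(np.abs(np.nan_to_num(smap.tmap)), axis=1)
        im = ax.imshow(mip, aspect="auto", origin="lower",
                       extent=[smap.times[0], smap.times[-1], 0,
                               mip.shape[0]])
        fig.colorbar(im, ax=ax, label="|t| (MIP)")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("anterior-posterior grid")
        fig.tight_layout()
        safe = name.replace(":", "_")
        fig.savefig(figdir / f"statmap_{safe}.png", dpi=110)
        plt.close(fig)
        lines.append(f"![](figures/statmap_{safe}.png)")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
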
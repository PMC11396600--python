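"""End-to-end orchestration: generate → observables → MSM → TPT → energetics.

A run is declared by a YAML/dict config naming the stages to execute and
their parameters; every stochastic stage must carry an explicit seed.
Each stage writes plain-text artifacts (CSV/JSON) into the output
directory and registers them in ``manifest.json`` together with the seeds
and a SHA-256 digest of every file, so a rerun with the same config
produces a byte-identical manifest.

Stages
------
simulate     synthetic inputs: Langevin well samples, a Gaussian positional
             ensemble, and a per-frame energy-component table
observables  RMSD/Rg/RMSF/DCCM/pocket-distance series over the ensemble
discretize   k-means microstates over the well samples
msm          transition-matrix estimation, implied timescales, CK test
tpt          PCCA macrostates, committors, flux network, pathway table
energetics   MM/PBSA-style component aggregation
report       human-readable summary of everything above
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import energetics as en
from . import msm as m
from . import observables as obs
from . import synthdata as sd
from . import tpt
from .trajio import write_trajectory

__all__ = ["RunConfig", "run", "report", "STAGES", "DEMO_CONFIG"]

log = logging.getLogger("luciflux")

STAGES = ("simulate", "observables", "discretize", "msm", "tpt",
          "energetics", "report")

#: A self-contained demo: a two-well system discretized into microstates,
#: a correlated Gaussian ensemble for the structural observables, and a
#: synthetic energy table with realistic component scales.
DEMO_CONFIG: dict = {
    "stages": list(STAGES),
    "simulate": {
        "seed": 20,
        "langevin": {"n_frames": 20000, "centers": [-1.0, 1.0],
                     "barrier_height": 2.0, "diffusion_coeff": 1.0},
        "ensemble": {"n_frames": 2000, "n_sites": 24, "site_sd": 0.6,
                     "coupled_pair": [2, 7], "coupling": 0.8},
        "energy": {
            "n_frames": 450,
            "means": {"dE_vdw": -65.0, "dE_ele": -105.0, "dG_solv": 125.0},
            "sds": {"dE_vdw": 4.3, "dE_ele": 32.0, "dG_solv": 30.0},
        },
    },
    "observables": {"pocket_groups": [[1, 2, 3], [22, 23, 24]]},
    "discretize": {"k": 2, "seed": 21},
    "msm": {"lag_steps": 5, "lag_grid": [1, 2, 5, 10, 20], "ck_k": 5,
            "n_macro": 2, "reversible": True},
    "tpt": {"n_macrostates": 2},
    "energetics": {},
}

_STOCHASTIC_STAGES = ("simulate", "discretize")


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, cfg: dict, out_dir):
        self.cfg = cfg
        self.out_dir = Path(out_dir)
        stages = cfg.get("stages")
        if not stages:
            raise ValueError("config must list stages")
        for s in stages:
            if s not in STAGES:
                raise ValueError(
                    f"unknown stage {s!r}; valid stages: {', '.join(STAGES)}"
                )
        for s in stages:
            if s in _STOCHASTIC_STAGES:
                params = cfg.get(s, {})
                if "seed" not in params:
                    raise ValueError(
                        f"stochastic stage {s!r} requires an explicit seed"
                    )
        self.stages = list(stages)

    @classmethod
    def from_yaml(cls, path, out_dir):
        with open(path) as fh:
            return cls(yaml.safe_load(fh), out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.cfg, "stages": {}}
    state: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        fn = _STAGE_FUNCS[stage]
        outputs = fn(config.cfg.get(stage, {}), out, state)
        dt = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs (%d outputs)", stage, dt, len(outputs))
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(out / name) for name in sorted(outputs)},
            "seed": config.cfg.get(stage, {}).get("seed"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations

def _stage_simulate(p: dict, out: Path, state: dict):
    seed = int(p["seed"])
    outputs = []
    lv = p.get("langevin", {})
    spec = sd.WellSpec(
        centers=tuple(lv.get("centers", (-1.0, 1.0))),
        barrier_height=float(lv.get("barrier_height", 2.0)),
        diffusion_coeff=float(lv.get("diffusion_coeff", 1.0)),
    )
    cfg = sd.GeneratorConfig(seed=seed, n_frames=int(lv.get("n_frames", 20000)))
    samples = sd.langevin_double_well(spec, cfg)
    state["samples"] = samples
    pd.DataFrame(samples, columns=[f"x{d}" for d in range(samples.shape[1])]).to_csv(
        out / "well_samples.csv", index=False, float_format="%.10g")
    outputs.append("well_samples.csv")

    ens = p.get("ensemble", {})
    n_sites = int(ens.get("n_sites", 24))
    rng = np.random.default_rng(seed + 1)
    reference = np.cumsum(rng.normal(scale=1.5, size=(n_sites, 3)), axis=0) + 20.0
    sdvec = np.full(n_sites, float(ens.get("site_sd", 0.6)))
    corr = np.eye(n_sites)
    if "coupled_pair" in ens:
        i, j = (int(v) for v in ens["coupled_pair"])
        corr[i, j] = corr[j, i] = float(ens.get("coupling", 0.8))
    traj = sd.gaussian_ensemble(
        reference, sdvec, corr,
        sd.GeneratorConfig(seed=seed + 2, n_frames=int(ens.get("n_frames", 2000))))
    state["ensemble"] = traj
    write_trajectory(traj, out / "ensemble.csv", fmt="csv-array")
    outputs.append("ensemble.csv")

    eg = p.get("energy", {})
    table = sd.synth_energy_table(
        eg.get("means", {"dE_vdw": -65.0, "dE_ele": -105.0, "dG_solv": 125.0}),
        eg.get("sds", {"dE_vdw": 4.3, "dE_ele": 32.0, "dG_solv": 30.0}),
        sd.GeneratorConfig(seed=seed + 3, n_frames=int(eg.get("n_frames", 450))))
    state["energy"] = table
    _save_csv(table, out / "energy_components.csv")
    outputs.append("energy_components.csv")
    return outputs


def _stage_observables(p: dict, out: Path, state: dict):
    traj = state["ensemble"]
    outputs = []
    series = [obs.rmsd_series(traj, selection="calpha"),
              obs.rg_series(traj, selection="calpha"),
              obs.pocket_distance(traj, *p.get(
                  "pocket_groups", [[1, 2, 3],
                                    list(range(traj.n_atoms - 2, traj.n_atoms + 1))]))]
    for s in series:
        df = pd.DataFrame({"frame": np.arange(len(s)), s.name: s.values})
        _save_csv(df, out / f"{s.name}.csv")
        outputs.append(f"{s.name}.csv")
    fl = obs.rmsf(traj, selection="calpha", superpose=False)
    _save_csv(pd.DataFrame({"site": np.arange(fl.size), "rmsf": fl}), out / "rmsf.csv")
    outputs.append("rmsf.csv")
    C = obs.dccm(traj, selection="calpha", superpose=False)
    np.savetxt(out / "dccm.csv", C, delimiter=",", fmt="%.10g")
    outputs.append("dccm.csv")
    return outputs


def _stage_discretize(p: dict, out: Path, state: dict):
    samples = state["samples"]
    res = m.kmeans(samples, int(p.get("k", 2)), seed=int(p["seed"]))
    state["dtraj"] = res.assignments
    pd.DataFrame({"microstate": res.assignments}).to_csv(
        out / "dtraj.csv", index=False)
    return ["dtraj.csv"]


def _stage_msm(p: dict, out: Path, state: dict):
    d = state["dtraj"]
    lag = int(p.get("lag_steps", 5))
    reversible = bool(p.get("reversible", True))
    model = m.estimate_msm(d, lag, reversible=reversible)
    state["model"] = model
    with open(out / "msm.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
    its = m.implied_timescales(d, p.get("lag_grid", [1, 2, 5, 10, 20]),
                               reversible=reversible)
    rows = [{"lag_steps": lag_i,
             **{f"t{k + 2}_ns": v for k, v in enumerate(ts)}}
            for lag_i, ts in sorted(its.items())]
    _save_csv(pd.DataFrame(rows), out / "implied_timescales.csv")
    ck = m.ck_test(d, lag, k=int(p.get("ck_k", 5)),
                   n_macro_for_test=int(p.get("n_macro", 2)), reversible=reversible)
    state["ck"] = ck
    with open(out / "ck_test.json", "w") as fh:
        json.dump({"k": ck.k, "agreement": ck.agreement,
                   "predicted": ck.predicted.tolist(),
                   "estimated": ck.estimated.tolist()}, fh, indent=1, sort_keys=True)
    return ["msm.json", "implied_timescales.csv", "ck_test.json"]


def _stage_tpt(p: dict, out: Path, state: dict):
    model = state["model"]
    n_macro = int(p.get("n_macrostates", 2))
    part = tpt.pcca(model, n_macro)
    state["partition"] = part
    # endpoint macrostates: least / most stationary-weighted forward committor
    first = part.members(0)
    last = part.members(part.n_macrostates - 1)
    comm = tpt.committor(model, first, last)
    flux = tpt.flux_network(model, comm)
    summary = tpt.macrostate_flux_summary(flux, part)
    state["flux_summary"] = summary
    decomp = tpt.decompose_paths(
        flux, mode="exhaustive" if model.n_states <= 12 else "bottleneck_greedy")
    rows = [{"path": "→".join(map(str, path)), "flux": f, "probability": pr}
            for path, f, pr in decomp.paths]
    _save_csv(pd.DataFrame(rows), out / "pathways.csv")
    with open(out / "flux_summary.json", "w") as fh:
        json.dump({"names": summary["names"],
                   "dominant_pathway": summary["dominant_pathway"],
                   "dominant_share": summary["dominant_share"],
                   "total_flux": summary["total_flux"],
                   "pathways": [
                       {"path": s, "flux": f, "probability": pr}
                       for s, f, pr in summary["pathways"]]},
                  fh, indent=1, sort_keys=True)
    return ["pathways.csv", "flux_summary.json"]


def _stage_energetics(p: dict, out: Path, state: dict):
    table = state["energy"]
    summary = en.aggregate(table, entropy_term=p.get("entropy_term"))
    state["energy_summary"] = summary
    summary.to_csv(out / "energy_summary.csv", float_format="%.4f")
    (out / "energy_summary.txt").write_text(
        en.format_summary(summary, title="MM/PBSA-style aggregation (kcal/mol)") + "\n")
    return ["energy_summary.csv", "energy_summary.txt"]


def _stage_report(p: dict, out: Path, state: dict):
    report_text = report(out)
    (out / "report.txt").write_text(report_text)
    return ["report.txt"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "observables": _stage_observables,
    "discretize": _stage_discretize,
    "msm": _stage_msm,
    "tpt": _stage_tpt,
    "energetics": _stage_energetics,
    "report": _stage_report,
}


def report(artifact_dir) -> str:
    """Render a human-readable summary from a run's artifact directory."""
    out = Path(artifact_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}")
    lines = ["luciflux run report", "===================", ""]
    ck_path = out / "ck_test.json"
    if ck_path.exists():
        ck = json.loads(ck_path.read_text())
        lines += [f"Chapman–Kolmogorov test (k={ck['k']}): "
                  f"agreement {100 * ck['agreement']:.1f}%", ""]
    its_path = out / "implied_timescales.csv"
    if its_path.exists():
        lines += ["Implied timescales (ns):", its_path.read_text().strip(), ""]
    fs_path = out / "flux_summary.json"
    if fs_path.exists():
        fs = json.loads(fs_path.read_text())
        lines += [f"Dominant pathway: {fs['dominant_pathway']} "
                  f"({100 * fs['dominant_share']:.1f}% of total flux)"]
        for p in fs["pathways"]:
            lines.append(f"  {p['path']}: flux {p['flux']:.4g} "
                         f"({100 * p['probability']:.1f}%)")
        lines.append("")
    es_path = out / "energy_summary.txt"
    if es_path.exists():
        lines += [es_path.read_text().strip(), ""]
    return "\n".join(lines) + "\n"
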
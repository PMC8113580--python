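"""Configuration-driven orchestration of the full analysis chain.

Stages run in the order simulate → process → histfit → doseresponse →
idealize → kinetics; each stage reads the previous stage's outputs from disk
(TSV tables + JSON sidecars) so any suffix of the chain can be re-run from a
directory.  Reports are deterministic functions of (config, seed): no
timestamps or machine state enter the output files.
"""

from __future__ import annotations

import copy
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd

from . import histograms as ha
from . import idealize as ide
from . import kinetics as kin
from . import synthetic as syn
from . import traces as tp

log = logging.getLogger("atdfret.pipeline")

STAGES = ("simulate", "process", "histfit", "doseresponse", "idealize", "kinetics")

DEFAULT_CONFIG: dict = {
    "generator": {
        "kon": 1.0,
        "koff": 0.46,
        "concentrations": [0.0, 0.1, 0.3, 1.0, 3.0, 1000.0],
        "state_means": [0.52, 0.40, 0.28],
        "total_intensity": 500.0,
        "noise_sd": 33.0,
        "crosstalk": 0.105,
        "gamma": 1.1,
        "donor_bleach_mean": 80.0,
        "acceptor_bleach_mean": 120.0,
        "background_level": 0.0,
        "n_movies": 5,
        "traces_per_movie": 120,
        "duration": 60.0,
        "frame_interval": 0.1,
        "bad_fraction": 0.0,
    },
    "processing": {
        "crosstalk": 0.105,
        "gamma": 1.1,
        "min_duration": 20.0,
        "require_single_donor_bleach": True,
        "require_single_acceptor_bleach": True,
        "total_stability_cv_max": 0.15,
        "window": 20.0,
        "bin_width": 0.02,
        "hist_range": [-0.2, 1.2],
    },
    "analysis": {
        "n_components": 3,
        "share_sds": True,
    },
    "idealization": {
        "n_states": 3,
        "restarts": 3,
        "max_iter": 100,
    },
    "kinetics": {
        "topology": "linear",
        "constraint": "independent_sites",
        "dead_time": 0.2,
        "n_starts": 5,
        "conc": None,  # default: first positive concentration
        "also_free": True,
    },
}


class StageDependencyError(RuntimeError):
    """A stage's upstream outputs are missing from the output directory."""


def load_config(path: str | pathlib.Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, deep-merged with a YAML file and/or an override mapping."""
    import yaml

    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                _merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        _merge(cfg, yaml.safe_load(pathlib.Path(path).read_text()) or {})
    if overrides:
        _merge(cfg, overrides)
    return cfg


def _clabel(conc: float) -> str:
    return f"c{conc:g}"


def _gen_objects(g: dict, conc: float):
    kp = syn.KineticParams(kon=g["kon"], koff=g["koff"], conc=conc)
    em = syn.EmissionParams(state_means=tuple(g["state_means"]),
                            total_intensity=g["total_intensity"],
                            noise_sd=g["noise_sd"], crosstalk=g["crosstalk"],
                            gamma=g["gamma"])
    ph = syn.PhotophysicsParams(donor_bleach_mean=g["donor_bleach_mean"],
                                acceptor_bleach_mean=g["acceptor_bleach_mean"],
                                background_level=g["background_level"])
    return kp, em, ph


def derive_seed(seed: int, *key: int) -> int:
    """A child seed below 2**31, reproducibly derived from the master seed."""
    return int(np.random.SeedSequence((seed, *key)).generate_state(1)[0] % (2**31))


def _fit_conc(cfg: dict) -> float:
    conc = cfg["kinetics"]["conc"]
    if conc is None:
        positives = [c for c in cfg["generator"]["concentrations"] if c > 0]
        if not positives:
            raise ValueError("no positive concentration available for kinetics")
        conc = positives[0]
    return float(conc)


def stage_simulate(cfg: dict, outdir: pathlib.Path, seed: int) -> dict:
    g = cfg["generator"]
    out = {}
    for idx, conc in enumerate(g["concentrations"]):
        kp, em, ph = _gen_objects(g, conc)
        ts = syn.simulate_experiment(
            kp, em, ph, n_movies=g["n_movies"], traces_per_movie=g["traces_per_movie"],
            duration=g["duration"], frame_interval=g["frame_interval"],
            seed=derive_seed(seed, idx), bad_fraction=g.get("bad_fraction", 0.0),
            condition={"conc": conc})
        syn.write_traceset(ts, outdir / "traces" / _clabel(conc))
        out[_clabel(conc)] = {"n_traces": len(ts), "n_movies": g["n_movies"]}
    return out


def _selection_criteria(p: dict) -> tp.SelectionCriteria:
    return tp.SelectionCriteria(
        min_duration=p["min_duration"],
        require_single_donor_bleach=p["require_single_donor_bleach"],
        require_single_acceptor_bleach=p["require_single_acceptor_bleach"],
        total_stability_cv_max=p["total_stability_cv_max"])


def _bin_edges(p: dict) -> np.ndarray:
    lo, hi = p["hist_range"]
    return tp.default_bin_edges(p["bin_width"], lo, hi)


def stage_process(cfg: dict, outdir: pathlib.Path, seed: int) -> dict:
    p = cfg["processing"]
    tr_root = outdir / "traces"
    if not tr_root.is_dir():
        raise StageDependencyError("process requires the simulate stage outputs (traces/)")
    crit = _selection_criteria(p)
    edges = _bin_edges(p)
    out = {}
    for cdir in sorted(tr_root.iterdir()):
        if not cdir.is_dir():
            continue
        ts = syn.read_traceset(cdir)
        fts, reasons = tp.select_traces(ts, crit, p["crosstalk"], p["gamma"])
        pdir = outdir / "processed" / cdir.name
        pdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"trace_id": list(reasons), "reason": [reasons[k] or "accepted"
                                                            for k in reasons]}
                     ).to_csv(pdir / "selection.tsv", sep="\t", index=False)
        rows = []
        for ft in fts:
            rows.append(pd.DataFrame({
                "trace_id": ft.trace_id, "movie_id": ft.movie_id,
                "frame_index": np.arange(len(ft.usable)), "fret": ft.usable}))
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                pdir / "fret.tsv", sep="\t", index=False, float_format="%.6f")
        hists = tp.compile_histograms(fts, window=p["window"], bin_edges=edges,
                                      condition=dict(ts.condition))
        for h in hists:
            pd.DataFrame({"bin_center": h.bin_centers, "density": h.density}).to_csv(
                pdir / f"hist_movie_{h.movie_id:02d}.tsv", sep="\t", index=False,
                float_format="%.8f")
        if hists:
            agg = tp.aggregate_histograms(hists)
            pd.DataFrame({"bin_center": agg.bin_centers, "density": agg.density,
                          "sem": agg.sem}).to_csv(pdir / "hist_aggregate.tsv", sep="\t",
                                                  index=False, float_format="%.8f")
        n_sel = len(fts)
        out[cdir.name] = {"n_input": len(ts), "n_selected": n_sel,
                          "n_movies_with_data": len(hists),
                          "conc": ts.condition.get("conc")}
    return out


def _load_movie_hists(outdir: pathlib.Path, p: dict):
    proot = outdir / "processed"
    if not proot.is_dir():
        raise StageDependencyError("stage requires the process stage outputs (processed/)")
    edges = _bin_edges(p)
    series: list[tp.FretHistogram] = []
    for cdir in sorted(proot.iterdir()):
        conc = float(cdir.name[1:])
        for f in sorted(cdir.glob("hist_movie_*.tsv")):
            df = pd.read_csv(f, sep="\t")
            series.append(tp.FretHistogram(
                bin_edges=edges, density=df["density"].to_numpy(float), n_molecules=0,
                movie_id=int(f.stem.split("_")[-1]), condition={"conc": conc}))
    return series


def stage_histfit(cfg: dict, outdir: pathlib.Path, seed: int) -> dict:
    p, a = cfg["processing"], cfg["analysis"]
    series = _load_movie_hists(outdir, p)
    if not series:
        raise StageDependencyError("no per-movie histograms found under processed/")
    concs = sorted({h.condition["conc"] for h in series})
    k = a["n_components"]
    if len(series) >= 3 and len(concs) >= 2:
        gf = ha.global_fit(series, k=k, share_sds=a["share_sds"])
        areas = gf.areas.rename(columns={i: f"area_{i}" for i in gf.areas.columns})
        areas["conc"] = [h.condition["conc"] for h in series]
        areas["movie_id"] = [h.movie_id for h in series]
        result = {
            "mode": "global",
            "state_means": [c.mean for c in gf.components],
            "state_sds": [c.sd for c in gf.components],
            "areas": areas.to_dict(orient="list"),
            "residual": gf.residual, "success": gf.success,
        }
    else:
        agg = tp.aggregate_histograms(series)
        fit = ha.fit_gaussians(agg, k=min(k, int(np.count_nonzero(agg.density))))
        result = {
            "mode": "single",
            "state_means": [c.mean for c in fit.components],
            "state_sds": [c.sd for c in fit.components],
            "areas": {"component": list(range(len(fit.components))),
                      "area": [c.area for c in fit.components]},
            "residual": fit.residual, "success": fit.success,
        }
    (outdir / "histfit.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result


def stage_doseresponse(cfg: dict, outdir: pathlib.Path, seed: int) -> dict:
    f = outdir / "histfit.json"
    if not f.exists():
        raise StageDependencyError("doseresponse requires the histfit stage outputs")
    hf = json.loads(f.read_text())
    if hf["mode"] != "global":
        raise StageDependencyError("doseresponse requires a multi-concentration global fit")
    areas = pd.DataFrame(hf["areas"])
    k = len(hf["state_means"])
    occ = areas.groupby("conc")[f"area_{k - 1}"].mean()
    fit = ha.fit_dose_response(occ.index.to_numpy(), occ.to_numpy())
    result = {"ec50": fit.ec50, "hill": fit.hill, "fmax": fit.fmax,
              "ec50_se": fit.ec50_se, "hill_se": fit.hill_se, "fmax_se": fit.fmax_se,
              "occupancy": {"conc": occ.index.tolist(), "low_fret_area": occ.tolist()}}
    (outdir / "doseresponse.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result


def stage_idealize(cfg: dict, outdir: pathlib.Path, seed: int) -> dict:
    p, i = cfg["processing"], cfg["idealization"]
    conc = _fit_conc(cfg)
    pdir = outdir / "processed" / _clabel(conc)
    f = pdir / "fret.tsv"
    if not f.exists():
        raise StageDependencyError(f"idealize requires processed FRET traces at {f}")
    df = pd.read_csv(f, sep="\t")
    dt = cfg["generator"]["frame_interval"]
    fts = []
    for (tid, mid), grp in df.groupby(["trace_id", "movie_id"], sort=True):
        fts.append(tp.FretTrace(fret=grp.sort_values("frame_index")["fret"].to_numpy(float),
                                frame_interval=dt, trace_id=str(tid), movie_id=int(mid)))
    ens = ide.skm_idealize_ensemble(fts, n_states=i["n_states"], restarts=i["restarts"],
                                    max_iter=i["max_iter"],
                                    seed=derive_seed(seed, 90))
    td = ide.transition_density(ens.traces)
    dead = cfg["kinetics"]["dead_time"]
    rows = []
    for it in ens.traces:
        ds = ide.extract_dwells(it, dead_time=dead)
        for j, (s, d) in enumerate(ds.dwells):
            rows.append({"trace_id": it.trace_id, "dwell_index": j,
                         "state": s, "duration": d})
    idir = outdir / "idealized" / _clabel(conc)
    idir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(idir / "dwells.tsv", sep="\t", index=False,
                              float_format="%.6f")
    result = {"conc": conc,
              "state_means": ens.state_means.tolist(),
              "state_sds": ens.state_sds.tolist(),
              "transition_matrix": ens.transition_matrix.tolist(),
              "n_traces": len(ens.traces), "n_transitions": td.n_transitions,
              "transitions_per_s": td.t_per_s, "n_dwells": len(rows),
              "dead_time": dead}
    (idir / "idealize.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result


def _read_dwells(idir: pathlib.Path, dead_time: float, dt: float):
    df = pd.read_csv(idir / "dwells.tsv", sep="\t")
    seqs = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("dwell_index")
        seqs.append(ide.DwellSequence(
            dwells=[(int(s), float(d)) for s, d in zip(grp["state"], grp["duration"])],
            dead_time=dead_time, frame_interval=dt, trace_id=str(tid)))
    return seqs


def stage_kinetics(cfg: dict, outdir: pathlib.Path, seed: int) -> dict:
    kcfg = cfg["kinetics"]
    conc = _fit_conc(cfg)
    idir = outdir / "idealized" / _clabel(conc)
    if not (idir / "dwells.tsv").exists():
        raise StageDependencyError("kinetics requires the idealize stage outputs")
    dead = kcfg["dead_time"]
    seqs = _read_dwells(idir, dead, cfg["generator"]["frame_interval"])
    scheme = kin.SchemeSpec(topology=kcfg["topology"], constraint=kcfg["constraint"],
                            conc=conc)
    fit = kin.fit_rates(seqs, scheme, dead_time=dead, n_starts=kcfg["n_starts"],
                        seed=derive_seed(seed, 91))
    result = {"conc": conc, "scheme": {"topology": scheme.topology,
                                       "constraint": scheme.constraint},
              "rates": fit.rates, "ses": fit.ses, "loglik": fit.loglik,
              "n_dwells": fit.n_dwells, "kd": fit.kd, "kd_se": fit.kd_se,
              "converged": fit.converged, "pinned": fit.pinned}
    if kcfg.get("also_free") and scheme.constraint == "independent_sites":
        free = kin.fit_rates(seqs, kin.SchemeSpec("linear", "free", conc),
                             dead_time=dead, n_starts=kcfg["n_starts"],
                             seed=derive_seed(seed, 92))
        r = free.rates
        result["free_fit"] = {
            "rates": r, "loglik": free.loglik, "converged": free.converged,
            "forward_ratio": r["k_R_RA"] / r["k_RA_RAA"],
            "backward_ratio": r["k_RAA_RA"] / r["k_RA_R"]}
    (outdir / "kinetics.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return result


_STAGE_FNS = {
    "simulate": stage_simulate,
    "process": stage_process,
    "histfit": stage_histfit,
    "doseresponse": stage_doseresponse,
    "idealize": stage_idealize,
    "kinetics": stage_kinetics,
}


def run(config: dict, outdir: str | pathlib.Path, seed: int,
        stages: tuple[str, ...] | list[str] = STAGES) -> dict:
    """Execute the requested stages in order; write and return the run report."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in _STAGE_FNS]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    report_file = outdir / "report.json"
    report = json.loads(report_file.read_text()) if report_file.exists() else {}
    report["config"] = config
    report["seed"] = seed
    report.setdefault("stages", {})
    for name in STAGES:
        if name not in stages:
            continue
        t0 = time.perf_counter()
        result = _STAGE_FNS[name](config, outdir, seed)
        log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
        report["stages"][name] = result
    report["summary"] = _summary(report["stages"])
    report_file.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _summary(stages: dict) -> dict:
    out: dict = {}
    if "histfit" in stages:
        out["state_means"] = stages["histfit"].get("state_means")
    if "idealize" in stages:
        out.setdefault("state_means", stages["idealize"].get("state_means"))
        out["transitions_per_s"] = stages["idealize"].get("transitions_per_s")
    if "doseresponse" in stages:
        out["ec50"] = stages["doseresponse"].get("ec50")
        out["hill"] = stages["doseresponse"].get("hill")
    if "kinetics" in stages:
        out["kd"] = stages["kinetics"].get("kd")
        out["rates"] = stages["kinetics"].get("rates")
    return out
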
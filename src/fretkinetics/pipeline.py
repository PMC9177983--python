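"""Run orchestration: config-driven simulation and analysis bundles.

A run is described by a plain YAML config.  ``run_simulate`` writes every
synthetic input (trace tables, decay curves, binding series, spectra) plus a
ground-truth sidecar for recovery testing; ``run_analyze`` executes the
five-layer trajectory workflow (FRET conversion, idealization,
classification, transition-density analysis, dwell kinetics) and any
configured ensemble fits, and writes a manifest sufficient to re-run any
stage.  All randomness derives from the single master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, dwells as dw, ensemble, fret, idealize as ideal_mod, io, simulate as sim, states

log = logging.getLogger("fretkinetics")

__all__ = ["ConfigError", "load_config", "run_simulate", "run_analyze"]


class ConfigError(ValueError):
    """A run config is missing or misusing a field; message names the path."""


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _build_scheme(node: dict, where: str) -> sim.KineticScheme:
    try:
        specs = [
            sim.StateSpec(s["label"], float(s["fret_level"]), float(s.get("emission_sd", 0.0)))
            for s in node["states"]
        ]
        return sim.KineticScheme(
            states=specs,
            rates=np.asarray(node["rates"], dtype=float),
            initial_probs=(
                np.asarray(node["initial_probs"], dtype=float)
                if "initial_probs" in node
                else None
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: invalid kinetic scheme ({exc})") from exc


def run_simulate(cfg: dict, output_dir=None) -> dict:
    """Generate every configured synthetic input under ``output_dir``.

    Returns a dict of written file paths.  A ground-truth sidecar
    (``ground_truth.json``) records true state paths, bleach frames and all
    generating parameters.
    """
    out = Path(output_dir or cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(master_seed)
    written: dict[str, str] = {}
    truth: dict = {"seed": master_seed, "config_digest": _config_digest(cfg)}

    sim_cfg = cfg.get("simulate", {})
    if "scheme" in sim_cfg:
        scheme = _build_scheme(sim_cfg["scheme"], "simulate.scheme")
        phot_node = sim_cfg.get("photophysics", {})
        phot = sim.PhotophysicsModel(**phot_node)
        config = sim.SimConfig(
            frame_interval=float(cfg.get("frame_interval", 0.2)),
            n_frames=int(sim_cfg.get("n_frames", 600)),
            n_molecules=int(sim_cfg.get("n_molecules", 1)),
            seed=master_seed,
        )
        traces, paths = [], {}
        for m in range(config.n_molecules):
            mol_id = f"mol{m:04d}"
            trace, path = sim.simulate_molecule(scheme, phot, config, rng, mol_id)
            traces.append(trace)
            paths[mol_id] = path.tolist()
        trace_path = out / "traces.csv"
        io.write_traces(traces, trace_path)
        written["traces"] = str(trace_path)
        truth["state_paths"] = paths
        truth["fret_levels"] = scheme.fret_levels.tolist()
        truth["bleach_frames"] = {
            t.molecule_id: t.metadata for t in traces
        }
        truth["scheme"] = {
            "rates": scheme.rates.tolist(),
            "initial_probs": scheme.initial_probs.tolist(),
        }
        log.info("simulate: wrote %d traces to %s", len(traces), trace_path)

    for decay_node in sim_cfg.get("decays", []):
        cid = decay_node["condition"]
        t = np.arange(0.0, float(decay_node.get("t_max", 60.0)) + 1e-9,
                      float(decay_node.get("dt", 0.2)))
        _, y = sim.simulate_ensemble_decay(
            decay_node["amplitudes"], decay_node["lifetimes"], t,
            float(decay_node.get("noise_sd", 0.0)), rng,
        )
        p = out / f"decay_{cid}.csv"
        io.write_decay(ensemble.DecayCurve(cid, t, y), p)
        written[f"decay_{cid}"] = str(p)
        truth.setdefault("decays", {})[cid] = {
            "amplitudes": list(decay_node["amplitudes"]),
            "lifetimes": list(decay_node["lifetimes"]),
        }

    if "binding" in sim_cfg:
        b = sim_cfg["binding"]
        series = sim.simulate_binding_series(
            kd=float(b["kd_m"]),
            rmax=float(b["rmax"]),
            concentrations=b.get("concentrations_m", sim.DEFAULT_TITRATION_M),
            noise_frac=float(b.get("noise_frac", 0.0)),
            rng=rng,
        )
        p = out / "binding.csv"
        io.write_binding(series, p)
        written["binding"] = str(p)
        truth["binding"] = {"kd_m": float(b["kd_m"]), "rmax": float(b["rmax"])}

    if "fret_sample" in sim_cfg:
        node = sim_cfg["fret_sample"]
        sample = sim.simulate_fret_sample(
            [(c["weight"], c["mean"], c["sd"]) for c in node["components"]],
            int(node["n"]), rng,
        )
        p = out / "fret_sample.csv"
        import pandas as pd

        pd.DataFrame({"fret": sample}).to_csv(p, index=False)
        written["fret_sample"] = str(p)
        truth["fret_sample"] = node

    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    written["ground_truth"] = str(out / "ground_truth.json")
    return written


def run_analyze(cfg: dict, output_dir=None) -> dict:
    """Execute the trajectory workflow per condition, plus ensemble fits.

    Per condition: FRET trajectories, idealized segments, class-percentage
    table, TDP matrix, dwell table and dwell fits.  Failures in one condition
    are logged and the remaining conditions still run; the returned manifest
    lists per-condition status and is also written to ``manifest.json``.
    """
    out = Path(output_dir or cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    analyze_cfg = cfg.get("analyze", {})
    bounds_node = analyze_cfg.get("regime_bounds", {})
    manifest = {
        "version": __version__,
        "seed": master_seed,
        "config_digest": _config_digest(cfg),
        "conditions": {},
    }
    failures = 0

    for ci, cond in enumerate(analyze_cfg.get("conditions", [])):
        cid = cond.get("id", f"cond{ci}")
        cdir = out / cid
        cdir.mkdir(parents=True, exist_ok=True)
        status = {"ok": False}
        try:
            if "dwell_window" not in cond and cond.get("fit_dwells", True):
                raise ConfigError(
                    f"analyze.conditions[{cid}]: dwell_window is required when dwell fits are requested"
                )
            traces = io.read_traces(cond["traces"])
            bg_d = float(cond.get("background_donor", 0.0))
            bg_a = float(cond.get("background_acceptor", 0.0))
            trajs = [fret.compute_fret(t, bg_d, bg_a) for t in traces]
            io.write_traces(
                traces, cdir / "traces_fret.csv",
                fret={tr.molecule_id: tj.efficiency for tr, tj in zip(traces, trajs)},
            )

            rng = np.random.default_rng(master_seed + 1000 + ci)
            k_max = int(cond.get("k_max", 6))
            restarts = int(cond.get("restarts", 10))
            ideals = []
            for tj in trajs:
                try:
                    ideals.append(
                        ideal_mod.idealize_trajectory(tj, k_max=k_max, seed=rng, n_restarts=restarts)
                    )
                except ideal_mod.InsufficientDataError:
                    log.warning("analyze[%s]: %s too short, skipped", cid, tj.molecule_id)
            if not ideals:
                raise RuntimeError("no trajectory survived idealization")
            io.write_segments(ideals, cdir / "segments.csv")

            bounds = states.RegimeBounds(**bounds_node) if bounds_node else states.RegimeBounds()
            classes = states.class_percentages(ideals, bounds)
            classes.to_csv(cdir / "classes.csv", index=False)

            transitions = [tr for i in ideals for tr in states.extract_transitions(i)]
            tdp = states.build_tdp(transitions, grid_size=int(cond.get("tdp_grid", 100)))
            np.savetxt(cdir / "tdp.csv", tdp.density, delimiter=",")

            window = tuple(float(x) for x in cond["dwell_window"])
            dwell_records = [d for i in ideals for d in dw.extract_dwells(i, window)]
            io.write_dwells(dwell_records, cdir / "dwells.csv")
            try:
                comparison = dw.compare_dwell_models(dwell_records)
                exp_fit, gam_fit = comparison["exponential"], comparison["gamma"]
                io.write_report(
                    io.FitReport(
                        model="exponential-dwell",
                        parameters={"tau": exp_fit.tau},
                        stderrs={"tau": exp_fit.se_tau},
                        goodness={"log_likelihood": exp_fit.log_likelihood,
                                  "aic": exp_fit.aic(), "bic": exp_fit.bic()},
                        n_obs=exp_fit.n_events + exp_fit.n_censored,
                        config_digest=manifest["config_digest"],
                    ),
                    cdir / "dwell_exponential.txt",
                )
                io.write_report(
                    io.FitReport(
                        model="gamma-dwell",
                        parameters={"shape": gam_fit.shape, "scale": gam_fit.scale},
                        stderrs={"shape": gam_fit.se_shape, "scale": gam_fit.se_scale},
                        goodness={"log_likelihood": gam_fit.log_likelihood,
                                  "aic": gam_fit.aic(), "bic": gam_fit.bic()},
                        n_obs=gam_fit.n_events + gam_fit.n_censored,
                        config_digest=manifest["config_digest"],
                    ),
                    cdir / "dwell_gamma.txt",
                )
                status["preferred_dwell_model"] = comparison["preferred"]
            except (dw.InestimableError, RuntimeError) as exc:
                log.warning("analyze[%s]: dwell fits unavailable (%s)", cid, exc)
                status["dwell_fit_error"] = str(exc)
            status.update(
                ok=True,
                n_molecules=len(traces),
                n_idealized=len(ideals),
                n_transitions=len(transitions),
                n_dwells=len(dwell_records),
            )
        except Exception as exc:  # keep remaining conditions running
            log.error("analyze[%s] failed: %s", cid, exc)
            status["error"] = str(exc)
            failures += 1
        manifest["conditions"][cid] = status

    if "decay_fit" in analyze_cfg:
        node = analyze_cfg["decay_fit"]
        curves = [io.read_decay(p) for p in node["curves"]]
        fit = ensemble.global_decay_fit(
            curves, single_component=tuple(node.get("single_component", []))
        )
        params = {"tau": fit.tau}
        for cidd in fit.amplitudes_1:
            params[f"a1_{cidd}"] = fit.amplitudes_1[cidd]
            params[f"a2_{cidd}"] = fit.amplitudes_2[cidd]
            if fit.tau_2[cidd] is not None:
                params[f"tau2_{cidd}"] = fit.tau_2[cidd]
        io.write_report(
            io.FitReport(
                model="global-two-exponential",
                parameters=params,
                stderrs=fit.se,
                goodness={"chi_square": fit.chi_square},
                n_obs=fit.n_obs,
                config_digest=manifest["config_digest"],
            ),
            out / "decay_fit.txt",
        )
        manifest["decay_fit"] = {"tau": fit.tau, "success": fit.success}

    if "ssa_fit" in analyze_cfg:
        node = analyze_cfg["ssa_fit"]
        series = io.read_binding(node["series"])
        fit = ensemble.fit_ssa(series)
        io.write_report(
            io.FitReport(
                model="steady-state-affinity",
                parameters={"kd_m": fit.kd, "rmax": fit.rmax},
                stderrs={"kd_m": fit.se_kd, "rmax": fit.se_rmax},
                goodness={"rss": fit.rss},
                n_obs=len(series.concentration),
                config_digest=manifest["config_digest"],
            ),
            out / "ssa_fit.txt",
        )
        manifest["ssa_fit"] = {"kd_m": fit.kd}

    if "mixture_fit" in analyze_cfg:
        import pandas as pd

        node = analyze_cfg["mixture_fit"]
        sample = pd.read_csv(node["sample"])["fret"].to_numpy()
        fit = ensemble.fit_three_gaussians(sample, method=node.get("method", "histogram-ls"))
        params = {}
        for i, comp in enumerate(fit.components):
            params[f"mean_{i}"] = comp.mean
            params[f"sd_{i}"] = comp.sd
            params[f"weight_{i}"] = comp.weight
        io.write_report(
            io.FitReport(
                model="three-gaussian-mixture",
                parameters=params,
                goodness={"chi_square": fit.chi_square},
                n_obs=fit.n_obs,
                config_digest=manifest["config_digest"],
            ),
            out / "mixture_fit.txt",
        )
        manifest["mixture_fit"] = {"means": fit.means.tolist()}

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["n_failures"] = failures
    return manifest
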
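"""Config-driven orchestration: simulate -> preprocess -> fit -> analyze.

A single YAML (or JSON) config describes the cohort, the task design, the
estimator and the analysis toggles; ``run_all`` executes the enabled stages
in dependency order, writes every stage's TSV/JSON exports under the output
directory, and returns a consolidated report. All randomness derives from
one master seed (per-stage seeds are spawned deterministically from it), so
identical configs reproduce bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io, netmetrics, stability, stats, synth
from .controllability import node_controllability
from .mdsi import EstimationConfig, extract_networks, fit_mdsi
from .preprocess import ROITimeSeries, clean_timeseries

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_all"]


_DEFAULTS = {
    "seed": 0,
    "output_dir": "dynconn_out",
    "cohort": {
        "n_subjects": 20,
        "n_regions": 5,
        "between_subject_sd": 0.05,
        "behavior_noise_sd": 0.02,
        "coupling_scale": 0.35,
        "accuracy_loadings": {},   # "condition,m,n" -> weight
        "rt_loadings": {},
    },
    "design": {
        "tr_seconds": 0.72,
        "n_sessions": 1,
        "blocks_per_session": 8,
        "trials_per_block": 10,
        "trial_seconds": 2.5,
        "cue_seconds": 2.5,
        "fixation_blocks": 4,
        "fixation_seconds": 15.0,
        "frames_per_session": 405,
        "condition_names": ["0-back", "2-back"],
    },
    "hrf": {"duration_seconds": 10.08, "n_basis": 2},
    "preprocess": {"highpass_hz": 0.008, "enabled": True},
    "estimation": {
        "max_iterations": 30,
        "loglik_tolerance": 1e-4,
        "n_random_starts": 1,
        "estimate_baseline": True,
        "n_lags": None,
    },
    "analyses": {
        "hubs": True,
        "communities": True,
        "controllability": {
            "enabled": True,
            "time_convention": "discrete",
            "stabilization": "strict",
            "weight_normalization": "none",
        },
        "classification": {"enabled": True, "k": 10, "n_perm": 100},
        "cca": {"enabled": True, "n_perm": 1000},
        "stability": {
            "enabled": False,
            "sizes": [10, 15, 20],
            "n_boot": 50,
            "alpha": 0.01,
        },
        "communities_iterations": 200,
    },
}


@dataclass
class PipelineConfig:
    raw: dict
    path: str | None = None

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])


@dataclass
class RunReport:
    config: dict
    results: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    version: str = ""
    log: list = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return any(v == "failed" for v in self.stages.values())


def _merge(defaults: dict, user: dict, errors: list, path: str = ""):
    out = {}
    for key, dv in defaults.items():
        if isinstance(dv, dict) and key != "accuracy_loadings" and key != "rt_loadings":
            uv = user.get(key, {})
            if not isinstance(uv, dict):
                errors.append(f"{path}{key}: expected a mapping")
                uv = {}
            out[key] = _merge(dv, uv, errors, f"{path}{key}.")
        else:
            out[key] = user.get(key, dv)
    for key in user:
        if key not in defaults:
            errors.append(f"{path}{key}: unknown key")
    return out


def validate_config(path_or_dict) -> PipelineConfig:
    """Load, schema-check and normalize a pipeline config.

    Unknown keys, negative durations, and inconsistent dimensions are
    collected into one itemized error. An empty file yields the defaults.
    """
    path = None
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        path = str(path_or_dict)
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
    errors: list = []
    cfg = _merge(_DEFAULTS, user, errors)
    d = cfg["design"]
    if d["tr_seconds"] <= 0:
        errors.append("design.tr_seconds: must be positive")
    for key in ("trial_seconds", "cue_seconds", "fixation_seconds"):
        if d[key] < 0:
            errors.append(f"design.{key}: must be non-negative")
    if cfg["cohort"]["n_subjects"] < 0:
        errors.append("cohort.n_subjects: must be >= 0")
    if cfg["hrf"]["duration_seconds"] < d["tr_seconds"] and d["tr_seconds"] > 0:
        errors.append("hrf.duration_seconds: must be at least one TR")
    st = cfg["analyses"]["stability"]
    st["sizes"] = sorted(set(int(s) for s in st["sizes"]))
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return PipelineConfig(raw=cfg, path=path)


def _parse_loadings(raw: dict) -> dict:
    out = {}
    for key, w in (raw or {}).items():
        if isinstance(key, str):
            cond, m, n = key.split(",")
            out[(cond.strip(), int(m), int(n))] = float(w)
        else:
            cond, m, n = key
            out[(cond, int(m), int(n))] = float(w)
    return out


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc is None:
                report.stages[name] = "ok"
                report.log.append(f"{name}: ok ({dt:.1f}s)")
                return False
            report.stages[name] = "failed"
            report.log.append(
                f"{name}: FAILED ({exc}); "
                + "".join(traceback.format_exception_only(exc_type, exc)).strip())
            return True  # swallow; dependents are skipped explicitly

    return _Ctx()


def run_all(config: PipelineConfig, output_dir=None) -> RunReport:
    """Execute the enabled pipeline stages on a synthetic cohort.

    Stage order: simulate -> preprocess -> fit -> (hubs, communities,
    controllability, classification, CCA, stability). A failed stage marks
    the report and skips its dependents.
    """
    from . import __version__

    cfg = config.raw
    out_dir = Path(output_dir or cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg, version=__version__)
    master = np.random.SeedSequence(cfg["seed"])
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31))
                  for name, s in zip(
                      ["simulate", "fit", "hubs", "communities", "control",
                       "classify", "cca", "stability"], master.spawn(8))}

    # ---- simulate ------------------------------------------------------
    subjects = None
    basis = None
    design = None
    with _stage(report, "simulate"):
        dcfg = dict(cfg["design"])
        dcfg["condition_names"] = tuple(dcfg["condition_names"])
        design = synth.make_nback_design(**dcfg)
        basis = synth.make_hrf_basis(
            tr_seconds=cfg["design"]["tr_seconds"],
            duration_seconds=cfg["hrf"]["duration_seconds"],
            n_basis=cfg["hrf"]["n_basis"])
        template = synth.default_template_model(
            n_regions=cfg["cohort"]["n_regions"],
            condition_names=dcfg["condition_names"],
            basis=basis,
            coupling_scale=cfg["cohort"]["coupling_scale"],
            seed=stage_seed["simulate"])
        template = synth.calibrate_obs_noise(
            template, design, snr=1.0, seed=stage_seed["simulate"])
        spec = synth.CohortSpec(
            n_subjects=cfg["cohort"]["n_subjects"],
            between_subject_sd=cfg["cohort"]["between_subject_sd"],
            accuracy_loadings=_parse_loadings(cfg["cohort"]["accuracy_loadings"]),
            rt_loadings=_parse_loadings(cfg["cohort"]["rt_loadings"]),
            behavior_noise_sd=cfg["cohort"]["behavior_noise_sd"],
            master_seed=stage_seed["simulate"])
        subjects = synth.simulate_cohort(spec, template, design)
        report.results["simulate"] = {
            "n_subjects": len(subjects),
            "n_regions": template.n_regions,
            "n_frames": design.n_timepoints,
            "conditions": list(design.condition_names),
        }

    if subjects is None:
        return _finish(report, out_dir)

    # ---- preprocess + fit ---------------------------------------------
    fits, networks = [], {}
    with _stage(report, "fit"):
        est = cfg["estimation"]
        econf = EstimationConfig(
            max_iterations=est["max_iterations"],
            loglik_tolerance=est["loglik_tolerance"],
            n_random_starts=est["n_random_starts"],
            estimate_baseline=est["estimate_baseline"],
            n_lags=est["n_lags"],
            seed=stage_seed["fit"])
        for subj in subjects:
            bold = subj.bold
            if cfg["preprocess"]["enabled"]:
                ts = ROITimeSeries(
                    values=bold,
                    region_names=[f"R{i}" for i in range(bold.shape[1])],
                    tr_seconds=design.tr_seconds)
                bold = clean_timeseries(
                    ts, highpass_hz=cfg["preprocess"]["highpass_hz"]).values
            fit = fit_mdsi(bold, design, basis, econf,
                           subject_id=subj.subject_id)
            fits.append(fit)
            for net in extract_networks(fit):
                networks.setdefault(net.condition, []).append(net)
        report.results["fit"] = {
            "n_fits": len(fits),
            "all_monotone": bool(all(
                (np.diff(f.loglik_trace) >= -1e-6).all() for f in fits)),
            "mean_final_loglik": float(np.mean(
                [f.loglik_trace[-1] for f in fits])),
        }

    if not fits:
        return _finish(report, out_dir)
    conds = list(design.condition_names)
    region_names = fits[0].region_names

    # ---- hubs ----------------------------------------------------------
    if cfg["analyses"]["hubs"]:
        with _stage(report, "hubs"):
            hub_res = {}
            for cond in conds:
                res = netmetrics.group_hub_test(networks[cond])
                hub_res[cond] = {
                    "outflow_hub": res.outflow_hub,
                    "inflow_hub": res.inflow_hub,
                    "mean_net": res.mean_net,
                    "q_value": res.q_value,
                }
            contrast = netmetrics.group_hub_test(
                networks[conds[-1]], contrast_nets=networks[conds[0]])
            hub_res["contrast"] = {
                "outflow_hub": contrast.outflow_hub,
                "inflow_hub": contrast.inflow_hub,
                "mean_net": contrast.mean_net,
            }
            report.results["hubs"] = hub_res

    # ---- communities ---------------------------------------------------
    if cfg["analyses"]["communities"]:
        with _stage(report, "communities"):
            comm = {}
            for cond in conds:
                mean_w = np.mean([n.weights for n in networks[cond]], axis=0)
                part = netmetrics.louvain_consensus(
                    mean_w,
                    n_iterations=cfg["analyses"]["communities_iterations"],
                    seed=stage_seed["communities"],
                    region_names=region_names)
                comm[cond] = {
                    "labels": part.labels,
                    "n_communities": part.n_communities,
                    "modularity": part.modularity,
                }
            report.results["communities"] = comm

    # ---- controllability ----------------------------------------------
    ctr_cfg = cfg["analyses"]["controllability"]
    if ctr_cfg["enabled"]:
        with _stage(report, "control"):
            rows = []
            for cond in conds:
                for net in networks[cond]:
                    vals = node_controllability(
                        net,
                        stabilization=ctr_cfg["stabilization"],
                        weight_normalization=ctr_cfg["weight_normalization"],
                        time_convention=ctr_cfg["time_convention"])
                    for name, v in zip(region_names, vals):
                        rows.append({"subject": net.subject_id,
                                     "condition": cond, "region": name,
                                     "value": float(v)})
            import pandas as pd

            table = pd.DataFrame(rows)
            table.to_csv(out_dir / "controllability.tsv", sep="\t",
                         index=False)
            per_cond = table.groupby("condition")["value"].mean().to_dict()
            report.results["control"] = {
                "mean_by_condition": per_cond,
                "table": "controllability.tsv",
            }

    # ---- classification ------------------------------------------------
    cls_cfg = cfg["analyses"]["classification"]
    if cls_cfg["enabled"] and len(subjects) >= 4:
        with _stage(report, "classify"):
            feats, labels, groups = [], [], []
            for cond in conds:
                for net in networks[cond]:
                    feats.append(net.offdiagonal_vector())
                    labels.append(cond)
                    groups.append(net.subject_id)
            res = stats.svm_cv_perm(
                np.asarray(feats), labels,
                k=min(cls_cfg["k"], len(subjects)),
                n_perm=cls_cfg["n_perm"],
                group_ids=np.asarray(groups),
                seed=stage_seed["classify"])
            report.results["classify"] = {
                "mean_accuracy": res.mean_accuracy,
                "permutation_p": res.permutation_p,
                "n_features": len(feats[0]),
                "feature_order": "row-major off-diagonal (m, n), m != n",
            }

    # ---- CCA -----------------------------------------------------------
    cca_cfg = cfg["analyses"]["cca"]
    if cca_cfg["enabled"] and len(subjects) > 4:
        with _stage(report, "cca"):
            cca_out = {}
            for cond in conds:
                X = np.asarray(
                    [n.offdiagonal_vector() for n in networks[cond]])
                Y = np.asarray([[s.behavior[cond]["accuracy"],
                                 s.behavior[cond]["rt"]] for s in subjects])
                if X.shape[0] <= X.shape[1]:
                    cca_out[cond] = {"skipped": "fewer subjects than features"}
                    continue
                res = stats.cca_perm(X, Y, n_perm=cca_cfg["n_perm"],
                                     seed=stage_seed["cca"])
                cca_out[cond] = {
                    "first_r": res.first_r,
                    "pillai": res.pillai,
                    "permutation_p": res.permutation_p,
                }
            report.results["cca"] = cca_out

    # ---- stability -----------------------------------------------------
    st_cfg = cfg["analyses"]["stability"]
    if st_cfg["enabled"]:
        with _stage(report, "stability"):
            curve = stability.pattern_stability(
                networks[conds[-1]],
                sizes=[s for s in st_cfg["sizes"] if s <= len(subjects)],
                n_boot=st_cfg["n_boot"], alpha=st_cfg["alpha"],
                seed=stage_seed["stability"])
            report.results["stability"] = {
                "sizes": curve.sizes,
                "mean": curve.mean,
                "n_boot": curve.n_boot,
            }

    return _finish(report, out_dir)


def _finish(report: RunReport, out_dir: Path) -> RunReport:
    payload = {
        "version": report.version,
        "config": report.config,
        "stages": report.stages,
        "results": report.results,
        "log": report.log,
    }
    io.write_json(out_dir / "report.json", payload)
    return report


def save_config_template(path) -> None:
    Path(path).write_text(yaml.safe_dump(_DEFAULTS, sort_keys=False))
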
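"""Orchestration: one path from synthetic cohort to full comparison report.

Stages (generate -> measure -> fit -> perturb -> compare) read and write
plain-text artefacts (TSV tables, JSON summaries) under a run directory,
so any stage can be re-run in isolation on saved outputs.  A run manifest
records inputs, seeds and per-stage status.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .geometry import pairwise_distances
from .hopf import HopfCouplingEstimator
from .perturbation import PerturbationProtocol, run_protocol
from .signal import bandpass, extract_phases
from .stats import build_report
from .synthetic import SyntheticCohort, generate_cohort, load_cohort, save_cohort
from .turbulence import TurbulenceAnalyzer

log = logging.getLogger("neuroturb")

__all__ = [
    "run_generate",
    "run_measure",
    "run_fit",
    "run_perturb",
    "run_compare",
    "run_all",
]


def _manifest_append(out_dir: Path, stage: str, status: str, extra: dict | None = None) -> None:
    path = out_dir / "run_manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append(
        {"stage": stage, "status": status, "time": time.time(), **(extra or {})}
    )
    path.write_text(json.dumps(entries, indent=2))


def _resolve_out(out_dir: str | Path, config: PipelineConfig) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "resolved_config.yaml")
    return out


def run_generate(config: PipelineConfig, out_dir: str | Path) -> SyntheticCohort:
    out = _resolve_out(out_dir, config)
    t0 = time.time()
    states = [
        {"label": s.label, "n_subjects": s.n_subjects, "params": {"G": s.G, "a": config.hopf.a,
                                                                  "noise_sd": config.hopf.noise_sd,
                                                                  "lambda_c": config.geometry.lambda_c,
                                                                  "dt": config.hopf.dt}}
        for s in config.cohort.states
    ]
    from .geometry import generate_parcellation

    geom = generate_parcellation(
        config.geometry.n_nodes,
        layout=config.geometry.layout,
        n_networks=config.geometry.n_networks,
        seed=config.seed,
        radius_mm=config.geometry.radius_mm,
    )
    cohort = generate_cohort(
        states,
        geom=geom,
        duration_volumes=config.cohort.duration_volumes,
        tr=config.cohort.tr,
        seed=config.seed,
        regime=config.cohort.regime,
    )
    save_cohort(cohort, out / "cohort")
    log.info("generate: %d subjects in %.1fs", len(cohort.subjects), time.time() - t0)
    _manifest_append(out, "generate", "ok", {"seed": config.seed,
                                             "n_subjects": len(cohort.subjects)})
    return cohort


def _phases_for(cohort: SyntheticCohort, config: PipelineConfig):
    for label, ts in cohort.subjects:
        tsb = bandpass(ts, config.signal.low_hz, config.signal.high_hz, config.signal.order)
        yield label, extract_phases(tsb, edge_discard=config.signal.edge_discard)


def run_measure(
    config: PipelineConfig, out_dir: str | Path, cohort: SyntheticCohort | None = None
) -> pd.DataFrame:
    out = _resolve_out(out_dir, config)
    t0 = time.time()
    if cohort is None:
        cohort = load_cohort(out / "cohort")
    dist = pairwise_distances(cohort.geometry)
    analyzer = TurbulenceAnalyzer(
        lambdas=config.lambdas(),
        dt_steps=config.turbulence.dt_steps,
        r_range=(config.turbulence.r_min_mm, config.turbulence.r_max_mm),
        n_bins=config.turbulence.n_bins,
    ).fit(dist)
    labels, phase_fields = [], []
    for label, pf in _phases_for(cohort, config):
        labels.append(label)
        phase_fields.append(pf)
    table = analyzer.transform(phase_fields)
    table["state"] = table["subject"].map(dict(enumerate(labels)))
    # node-level metastability at the readout scale, one row per subject
    lam_s = config.perturbation.lambda_s
    nlm_rows = []
    for i, pf in enumerate(phase_fields):
        lam_idx = int(np.argmin(np.abs(analyzer.kernels_.lambdas - lam_s)))
        nlm = analyzer.node_metastability(pf)[:, lam_idx]
        nlm_rows.append([i, labels[i], *nlm])
    nlm_table = pd.DataFrame(
        nlm_rows,
        columns=["subject", "state", *cohort.geometry.node_ids],
    )
    table.to_csv(out / "measures.tsv", sep="\t", index=False)
    nlm_table.to_csv(out / "nlm.tsv", sep="\t", index=False)
    log.info("measure: %d subjects in %.1fs", len(phase_fields), time.time() - t0)
    _manifest_append(out, "measure", "ok", {"n_subjects": len(phase_fields)})
    return table


def run_fit(
    config: PipelineConfig, out_dir: str | Path, cohort: SyntheticCohort | None = None
) -> dict[str, HopfCouplingEstimator]:
    out = _resolve_out(out_dir, config)
    if cohort is None:
        cohort = load_cohort(out / "cohort")
    dist = pairwise_distances(cohort.geometry)
    g_grid = np.arange(config.hopf.g_min, config.hopf.g_max + config.hopf.g_step / 2,
                       config.hopf.g_step)
    fits: dict[str, HopfCouplingEstimator] = {}
    summary = {}
    for state in cohort.states:
        t0 = time.time()
        est = HopfCouplingEstimator(
            dist=dist,
            a=config.hopf.a,
            g_grid=g_grid,
            n_reps=config.hopf.n_reps,
            duration_volumes=config.hopf.duration_volumes,
            tr=config.cohort.tr,
            dt=config.hopf.dt,
            noise_sd=config.hopf.noise_sd,
            r_range=(config.turbulence.r_min_mm, config.turbulence.r_max_mm),
            lambda_c=config.geometry.lambda_c,
            seed=config.seed,
        )
        est.fit(cohort.by_state(state))
        fits[state] = est
        summary[state] = {
            "g_opt": est.g_opt_,
            "g_grid": g_grid.tolist(),
            "fit_errors": [None if not np.isfinite(e) else float(e) for e in est.fit_errors_],
        }
        log.info("fit[%s]: g_opt=%.3g in %.1fs", state, est.g_opt_, time.time() - t0)
    (out / "coupling_fits.json").write_text(json.dumps(summary, indent=2))
    _manifest_append(out, "fit", "ok", {"states": list(fits)})
    return fits


def run_perturb(
    config: PipelineConfig,
    out_dir: str | Path,
    fits: dict[str, HopfCouplingEstimator],
    cohort: SyntheticCohort | None = None,
) -> dict[str, dict]:
    out = _resolve_out(out_dir, config)
    if cohort is None:
        cohort = load_cohort(out / "cohort")
    dist = pairwise_distances(cohort.geometry)
    protocol = PerturbationProtocol(
        kind=config.perturbation.kind,
        F0=config.perturbation.F0,
        a_range=(config.perturbation.a_low, config.perturbation.a_high),
        n_trials=config.perturbation.n_trials,
        lambda_s=config.perturbation.lambda_s,
        seed=config.seed,
    )
    results = {}
    for state, est in fits.items():
        t0 = time.time()
        res = run_protocol(est.system_, protocol, dist,
                           duration_volumes=config.hopf.duration_volumes)
        results[state] = {
            "g_opt": est.g_opt_,
            "chi": res.chi,
            "info_capability": res.info_capability,
            "protocol": {"kind": protocol.kind, "F0": protocol.F0,
                         "n_trials": protocol.n_trials, "lambda_s": protocol.lambda_s,
                         "seed": protocol.seed},
        }
        log.info("perturb[%s]: chi=%.3g I=%.3g in %.1fs", state, res.chi,
                 res.info_capability, time.time() - t0)
    (out / "perturbation.json").write_text(json.dumps(results, indent=2))
    _manifest_append(out, "perturb", "ok", {"states": list(results)})
    return results


def run_compare(config: PipelineConfig, out_dir: str | Path) -> dict:
    out = _resolve_out(out_dir, config)
    measures = pd.read_csv(out / "measures.tsv", sep="\t")
    nlm_path = out / "nlm.tsv"
    nlm = None
    network_label = None
    if nlm_path.exists():
        nlm_table = pd.read_csv(nlm_path, sep="\t")
        node_cols = [c for c in nlm_table.columns if c not in ("subject", "state")]
        nlm = {
            state: grp[node_cols].to_numpy()
            for state, grp in nlm_table.groupby("state", sort=False)
        }
        coords_path = out / "cohort" / "coordinates.tsv"
        if coords_path.exists():
            from .geometry import load_parcellation

            network_label = load_parcellation(coords_path).network_label
    keep = ["subject", "state", "lam", "D", "flow", "A", "cascade"]
    report = build_report(
        measures[[c for c in keep if c in measures.columns]],
        nlm=nlm,
        network_label=network_label,
        q=config.stats.q,
        top_q=config.stats.top_q,
    )
    report["comparisons"].to_csv(out / "comparisons.tsv", sep="\t", index=False)
    (out / "report.json").write_text(
        json.dumps(
            {"ks": report["ks"], "top_nodes": report["top_nodes"]}, indent=2
        )
    )
    _manifest_append(out, "compare", "ok", {})
    return report


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    cohort = run_generate(config, out_dir)
    run_measure(config, out_dir, cohort)
    fits = run_fit(config, out_dir, cohort)
    run_perturb(config, out_dir, fits, cohort)
    return run_compare(config, out_dir)
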
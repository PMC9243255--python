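"""Synthetic parcellated-BOLD cohorts with known ground truth.

The generator emulates the study design the analysis is built for: groups
of subjects whose brain state differs only in the effective global
coupling G of the generative whole-brain model.  Three signal regimes are
available:

- ``independent_noise``: i.i.d. Gaussian noise per node (a null state);
- ``global_sync``: one shared narrowband sinusoid plus small per-node
  noise (a fully synchronised state);
- ``hopf_forward``: the Stuart-Landau whole-brain simulator at a stated
  G*, so the synthetic data carries the statistical structure the
  turbulence measures assume (spatially decaying phase coupling, in-band
  oscillations).

Defaults: 100 nodes uniform in a 70 mm ball, TR = 2 s, 200 volumes,
node frequencies uniform in 0.02-0.07 Hz, noise amplitude 0.01.
Every generator is a pure function of its inputs and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    ParcellationGeometry,
    build_connectome,
    generate_parcellation,
    pairwise_distances,
)
from .hopf import DEFAULT_BIFURCATION_A, DEFAULT_NOISE_SD, HopfSystem, simulate
from .signal import BoldTimeSeries

__all__ = [
    "SyntheticCohort",
    "generate_bold",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "default_node_frequencies",
]

DEFAULT_TR_S = 2.0
DEFAULT_VOLUMES = 200
DEFAULT_FREQ_BAND_HZ = (0.02, 0.07)


def default_node_frequencies(n_nodes: int, seed: int, band=DEFAULT_FREQ_BAND_HZ) -> np.ndarray:
    """Angular node frequencies drawn uniformly inside the analysis band."""
    rng = np.random.default_rng(seed)
    return 2 * np.pi * rng.uniform(band[0], band[1], n_nodes)


@dataclass
class SyntheticCohort:
    """State-labelled subjects plus the ground-truth generating parameters."""

    geometry: ParcellationGeometry
    subjects: list[tuple[str, BoldTimeSeries]]
    ground_truth: dict = field(default_factory=dict)

    @property
    def states(self) -> list[str]:
        seen: list[str] = []
        for label, _ in self.subjects:
            if label not in seen:
                seen.append(label)
        return seen

    def by_state(self, label: str) -> list[BoldTimeSeries]:
        return [ts for s, ts in self.subjects if s == label]


def generate_bold(
    geom: ParcellationGeometry,
    regime: str = "hopf_forward",
    params: dict | None = None,
    duration_volumes: int = DEFAULT_VOLUMES,
    tr: float = DEFAULT_TR_S,
    seed: int = 0,
) -> BoldTimeSeries:
    """One subject's node-by-time BOLD matrix under a stated regime.

    ``params`` for ``hopf_forward``: G (default 1.0), a (default -0.02),
    omega (default: drawn in-band from the seed), noise_sd, lambda_c;
    for ``global_sync``: f_hz (default 0.04), noise_sd (default 0.01);
    for ``independent_noise``: noise_sd (default 1.0).
    """
    if duration_volumes < 64:
        raise ValueError("duration_volumes must be >= 64")
    if tr <= 0:
        raise ValueError("tr must be > 0")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    n = geom.n_nodes
    if regime == "independent_noise":
        sd = params.get("noise_sd", 1.0)
        values = sd * rng.standard_normal((n, duration_volumes))
    elif regime == "global_sync":
        f = params.get("f_hz", 0.04)
        sd = params.get("noise_sd", 0.01)
        t = np.arange(duration_volumes) * tr
        shared = np.cos(2 * np.pi * f * t)
        values = shared[None, :] + sd * rng.standard_normal((n, duration_volumes))
    elif regime == "hopf_forward":
        omega = params.get("omega")
        if omega is None:
            omega = default_node_frequencies(n, seed=rng.integers(0, 2**31))
        dist = pairwise_distances(geom)
        C = build_connectome(dist, lambda_c=params.get("lambda_c", 0.18))
        system = HopfSystem(
            connectome=C,
            a=params.get("a", DEFAULT_BIFURCATION_A),
            omega=omega,
            G=params.get("G", 1.0),
            noise_sd=params.get("noise_sd", DEFAULT_NOISE_SD),
            dt=params.get("dt", 0.1),
            tr=tr,
        )
        return simulate(system, duration_volumes, seed=int(rng.integers(0, 2**31)))
    else:
        raise ValueError(
            f"unknown regime {regime!r}; expected independent_noise, "
            "global_sync or hopf_forward"
        )
    return BoldTimeSeries(values=values, tr=tr, geometry_ref="synthetic")


def generate_cohort(
    states: list[dict],
    geom: ParcellationGeometry | None = None,
    n_nodes: int = 100,
    duration_volumes: int = DEFAULT_VOLUMES,
    tr: float = DEFAULT_TR_S,
    seed: int = 0,
    regime: str = "hopf_forward",
) -> SyntheticCohort:
    """State-labelled cohort; each state dict: {label, n_subjects, params}.

    For ``hopf_forward`` states the key parameter is ``params["G"]`` — the
    known effect the downstream comparison is designed to detect.  Node
    frequencies are shared across the cohort (drawn once from the seed) so
    groups differ only in their stated parameters.  Reproducible from seed.
    """
    labels = [s["label"] for s in states]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate state labels in {labels}")
    if geom is None:
        geom = generate_parcellation(n_nodes, seed=seed)
    root = np.random.SeedSequence(seed)
    omega = default_node_frequencies(geom.n_nodes, seed=int(root.generate_state(1)[0] & 0x7FFFFFFF))
    subject_seeds = iter(int(s & 0x7FFFFFFF) for s in root.generate_state(
        sum(int(s["n_subjects"]) for s in states) + 1)[1:])
    subjects: list[tuple[str, BoldTimeSeries]] = []
    gt_states = {}
    for st in states:
        params = dict(st.get("params", {}))
        if regime == "hopf_forward":
            params.setdefault("omega", omega)
        seeds_used = []
        for _ in range(int(st["n_subjects"])):
            s_seed = next(subject_seeds)
            seeds_used.append(s_seed)
            ts = generate_bold(
                geom, regime=regime, params=params,
                duration_volumes=duration_volumes, tr=tr, seed=s_seed,
            )
            subjects.append((st["label"], ts))
        gt_states[st["label"]] = {
            "n_subjects": int(st["n_subjects"]),
            "params": {k: v for k, v in params.items() if k != "omega"},
            "seeds": seeds_used,
        }
    ground_truth = {
        "seed": seed,
        "regime": regime,
        "tr": tr,
        "duration_volumes": duration_volumes,
        "states": gt_states,
    }
    return SyntheticCohort(geometry=geom, subjects=subjects, ground_truth=ground_truth)


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write time series (TSV), coordinates, manifest and sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.geometry.to_tsv(out / "coordinates.tsv")
    manifest_rows = []
    for i, (label, ts) in enumerate(cohort.subjects):
        name = f"sub-{i:03d}_{label}.tsv"
        np.savetxt(out / name, ts.values, delimiter="\t", fmt="%.8g")
        manifest_rows.append(
            (f"sub-{i:03d}", label, name, ts.tr, ts.n_volumes)
        )
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("subject_id\tstate\tpath\ttr\tn_volumes\n")
        for row in manifest_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    with open(out / "generation.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2, default=_json_default)
    return out


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`save_cohort` (or user files of the
    same layout: coordinates.tsv + manifest.tsv + per-subject TSV matrices)."""
    from .geometry import load_parcellation

    in_dir = Path(in_dir)
    geom = load_parcellation(in_dir / "coordinates.tsv")
    subjects = []
    with open(in_dir / "manifest.tsv") as fh:
        header = fh.readline().strip().split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or parts == [""]:
                continue
            values = np.loadtxt(in_dir / parts[cols["path"]], delimiter="\t")
            ts = BoldTimeSeries(values=values, tr=float(parts[cols["tr"]]))
            subjects.append((parts[cols["state"]], ts))
    ground_truth = {}
    gen = in_dir / "generation.json"
    if gen.exists():
        ground_truth = json.loads(gen.read_text())
    return SyntheticCohort(geometry=geom, subjects=subjects, ground_truth=ground_truth)
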
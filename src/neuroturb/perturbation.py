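"""In-silico perturbation of a fitted whole-brain model.

Two protocols probe how a model at its optimal working point reacts to
external input:

- ``periodic_force``: an additive periodic forcing term F0 cos(w0 t) /
  F0 sin(w0 t) on the real/imaginary node equations, with w0 the mean of
  the node frequencies and F0 = 5e-4 by default;
- ``bifurcation_shift``: each node's bifurcation parameter is redrawn
  uniformly in a stated subcritical range (default [-0.02, 0]).

Each trial pairs a perturbed and an unperturbed simulation on the same
noise stream, so the perturbation — not the noise realisation — drives
their difference.  The readout is the modulus of the local Kuramoto order
parameter at a single scale ``lambda_s`` (default 0.12 /mm):

- susceptibility  chi = <<<R~>_t - <R>_t>_trials>_x  (signed mean shift);
- information encoding capability
  I = sqrt(< Var_trials(<R~>_t - <R>_t) >_x), the across-trial variability
  of that shift, space-averaged under a single square root.

The normalised Lempel-Ziv complexity (LZ76 phrase count over per-node
binarised signals, normalised by the random-sequence asymptote) is the
complexity yardstick the perturbation measures are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .hopf import ForcingSpec, HopfSystem, SimulationDiverged, simulate
from .signal import BoldTimeSeries, bandpass, extract_phases
from .turbulence import KernelSet, build_kernels, local_kuramoto

__all__ = [
    "PerturbationProtocol",
    "PerturbationResult",
    "run_protocol",
    "susceptibility",
    "information_capability",
    "lempel_ziv",
    "normalized_lz76",
    "DEFAULT_F0",
    "DEFAULT_LAMBDA_S",
]

DEFAULT_F0 = 5e-4
DEFAULT_LAMBDA_S = 0.12
DEFAULT_N_TRIALS = 10


@dataclass(frozen=True)
class PerturbationProtocol:
    """Which perturbation to apply and how the readout is taken."""

    kind: str  # "periodic_force" | "bifurcation_shift"
    F0: float = DEFAULT_F0
    a_range: tuple[float, float] = (-0.02, 0.0)
    n_trials: int = DEFAULT_N_TRIALS
    lambda_s: float = DEFAULT_LAMBDA_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("periodic_force", "bifurcation_shift"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.kind == "bifurcation_shift" and self.a_range[1] > 0:
            raise ValueError("bifurcation_shift a_range must stay subcritical (<= 0)")


@dataclass
class PerturbationResult:
    """Susceptibility, information capability and per-trial intermediates."""

    chi: float
    info_capability: float
    protocol: PerturbationProtocol
    trial_shift: np.ndarray = field(default=None)  # (n_trials, n_nodes) time-mean diffs


def _order_modulus(ts: BoldTimeSeries, kernels: KernelSet, lam: float) -> np.ndarray:
    phases = extract_phases(bandpass(ts))
    return local_kuramoto(phases, kernels, lam).modulus


def run_protocol(
    system: HopfSystem,
    protocol: PerturbationProtocol,
    dist: np.ndarray,
    duration_volumes: int = 200,
) -> PerturbationResult:
    """Paired perturbed/unperturbed trials on a fitted system.

    ``dist`` is the node distance matrix (mm) used for the readout kernel.
    A diverging trial is rerun with a fresh derived seed, at most 3 times.
    """
    kernels = build_kernels(dist, np.array([protocol.lambda_s]))
    ss = np.random.SeedSequence(protocol.seed)
    trial_seeds = [int(s & 0x7FFFFFFF) for s in ss.generate_state(protocol.n_trials * 4)]
    shift_rng = np.random.default_rng(int(ss.generate_state(1)[0] & 0x3FFFFFFF) + 1)

    pert_mod = []
    unpert_mod = []
    attempts = iter(trial_seeds)
    for trial in range(protocol.n_trials):
        for attempt in range(3):
            seed = next(attempts)
            try:
                base = simulate(system, duration_volumes, seed=seed)
                if protocol.kind == "periodic_force":
                    forcing = ForcingSpec(
                        amplitude=protocol.F0,
                        omega0=float(np.mean(system.omega)),
                        enabled=True,
                    )
                    pert = simulate(system, duration_volumes, forcing=forcing, seed=seed)
                else:
                    a_new = shift_rng.uniform(
                        protocol.a_range[0], protocol.a_range[1], system.n_nodes
                    )
                    pert = simulate(replace(system, a=a_new), duration_volumes, seed=seed)
                break
            except SimulationDiverged:
                if attempt == 2:
                    raise
        unpert_mod.append(_order_modulus(base, kernels, protocol.lambda_s))
        pert_mod.append(_order_modulus(pert, kernels, protocol.lambda_s))

    pert_arr = np.stack(pert_mod)  # (trials, nodes, time)
    unpert_arr = np.stack(unpert_mod)
    chi = susceptibility(pert_arr, unpert_arr)
    info = information_capability(pert_arr, unpert_arr)
    shift = pert_arr.mean(axis=2) - unpert_arr.mean(axis=2)
    return PerturbationResult(
        chi=chi, info_capability=info, protocol=protocol, trial_shift=shift
    )


def _time_mean_shift(perturbed: np.ndarray, unperturbed: np.ndarray) -> np.ndarray:
    perturbed = np.asarray(perturbed, dtype=float)
    unperturbed = np.asarray(unperturbed, dtype=float)
    if perturbed.shape != unperturbed.shape or perturbed.ndim != 3:
        raise ValueError(
            "expected matching (n_trials, n_nodes, n_times) arrays, got "
            f"{perturbed.shape} and {unperturbed.shape}"
        )
    return perturbed.mean(axis=2) - unperturbed.mean(axis=2)  # (trials, nodes)


def susceptibility(perturbed: np.ndarray, unperturbed: np.ndarray) -> float:
    """Mean over trials then space of the time-mean modulus shift (signed)."""
    shift = _time_mean_shift(perturbed, unperturbed)
    return float(shift.mean(axis=0).mean())


def information_capability(perturbed: np.ndarray, unperturbed: np.ndarray) -> float:
    """sqrt of the space-averaged across-trial variance of the shift.

    The across-trial variance (population, ddof=0) of the per-node
    time-mean shift is averaged over nodes before the square root.
    """
    shift = _time_mean_shift(perturbed, unperturbed)
    if shift.shape[0] < 2:
        raise ValueError("information capability needs >= 2 trials")
    var_across_trials = shift.var(axis=0, ddof=0)  # per node
    return float(np.sqrt(var_across_trials.mean()))


def _lz76_phrases(seq: np.ndarray) -> int:
    """LZ76 phrase count of a binary sequence (Kaspar-Schuster scan)."""
    s = seq.tolist()
    n = len(s)
    if n == 0:
        return 0
    c = 1  # the first symbol is always a phrase
    l, k, i, k_max = 1, 1, 0, 1
    while l + k <= n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    if k != 1:
        c += 1
    return c


def normalized_lz76(seq: np.ndarray) -> float:
    """Normalised LZ76 complexity of a binary sequence.

    The phrase count c is normalised by the asymptotic count n/log2(n) of a
    random binary sequence, so an i.i.d. fair coin scores ~1 and a constant
    sequence is near 0.
    """
    seq = np.asarray(seq).reshape(-1)
    n = seq.size
    if n < 2:
        raise ValueError("sequence too short")
    return float(_lz76_phrases(seq) * np.log2(n) / n)


def lempel_ziv(ts: BoldTimeSeries | np.ndarray, binarization: str = "median") -> float:
    """Normalised Lempel-Ziv complexity of binarised node signals.

    Each node is binarised at its own median (or mean) and the node
    sequences are concatenated in node order; the LZ76 phrase count c is
    normalised by the random-binary asymptote n / log2(n), so an i.i.d.
    fair-coin sequence scores ~1 and a constant sequence is near 0.
    """
    values = ts.values if isinstance(ts, BoldTimeSeries) else np.atleast_2d(np.asarray(ts))
    if values.shape[1] < 64:
        raise ValueError("need at least 64 samples per node")
    if binarization == "median":
        thresh = np.median(values, axis=1, keepdims=True)
    elif binarization == "mean":
        thresh = values.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown binarization {binarization!r}")
    binary = (values > thresh).astype(np.int8)
    if np.any(values.std(axis=1) == 0):
        warnings.warn("constant node signal: contributes minimal complexity", stacklevel=2)
    return normalized_lz76(binary.reshape(-1))
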
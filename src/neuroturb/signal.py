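"""Narrowband filtering, instantaneous phases and node frequencies.

The analysis object downstream is never the raw BOLD amplitude but the
instantaneous phase of its narrowband (0.008-0.08 Hz) component, obtained
via the Hilbert transform.  Filtering is zero-phase (forward-backward
Butterworth) because any filter phase shift would contaminate the phase
field directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, periodogram

__all__ = [
    "BoldTimeSeries",
    "PhaseField",
    "NodeFrequencies",
    "bandpass",
    "extract_phases",
    "estimate_node_frequencies",
    "DEFAULT_BAND_HZ",
]

DEFAULT_BAND_HZ = (0.008, 0.08)
MIN_VOLUMES = 64
DEFAULT_EDGE_DISCARD = 10
MIN_VALID_WINDOW = 10


@dataclass
class BoldTimeSeries:
    """Parcellated BOLD: node-by-time real matrix sampled every ``tr`` seconds."""

    values: np.ndarray  # (n_nodes, n_volumes)
    tr: float
    geometry_ref: str = ""
    bandpassed: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2D (nodes x time), got {values.ndim}D")
        if values.shape[1] < MIN_VOLUMES:
            raise ValueError(
                f"need at least {MIN_VOLUMES} volumes for spectral estimation, "
                f"got {values.shape[1]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("BOLD values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.values = values

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class PhaseField:
    """Instantaneous phases per node and volume, wrapped to [-pi, pi).

    ``valid_window`` is the (first, last+1) slice of volumes retained after
    discarding filter/Hilbert edge effects; every downstream statistic is
    computed inside it.  ``flagged_nodes`` lists zero-variance nodes whose
    phase was set to 0.
    """

    phases: np.ndarray  # (n_nodes, n_volumes), radians
    valid_window: tuple[int, int]
    tr: float
    flagged_nodes: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        ph = np.asarray(self.phases, dtype=float)
        lo, hi = self.valid_window
        if not (0 <= lo < hi <= ph.shape[1]):
            raise ValueError(f"invalid valid_window {self.valid_window}")
        self.phases = ph

    @property
    def valid(self) -> np.ndarray:
        """Phases restricted to the valid window."""
        lo, hi = self.valid_window
        return self.phases[:, lo:hi]


@dataclass(frozen=True)
class NodeFrequencies:
    """Per-node spectral peak: ``f_peak`` in Hz, ``omega = 2*pi*f_peak`` rad/s."""

    f_peak: np.ndarray
    omega: np.ndarray


def bandpass(
    ts: BoldTimeSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 2,
) -> BoldTimeSeries:
    """Zero-phase Butterworth bandpass; each node demeaned first."""
    nyquist = 0.5 / ts.tr
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz implied by tr={ts.tr} s"
        )
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    b, a = butter(order, [low_hz * 2 * ts.tr, high_hz * 2 * ts.tr], btype="band")
    filtered = filtfilt(b, a, x, axis=1)
    return BoldTimeSeries(
        values=filtered, tr=ts.tr, geometry_ref=ts.geometry_ref, bandpassed=True
    )


def extract_phases(
    ts: BoldTimeSeries,
    edge_discard: int = DEFAULT_EDGE_DISCARD,
    allow_unfiltered: bool = False,
) -> PhaseField:
    """Instantaneous phase per node via the analytic (Hilbert) signal.

    Constant nodes are flagged and carried with phase 0 rather than NaN.
    """
    if not ts.bandpassed and not allow_unfiltered:
        raise ValueError(
            "time series is not marked bandpassed; filter first or pass "
            "allow_unfiltered=True"
        )
    n_t = ts.n_volumes
    lo = edge_discard
    hi = n_t - edge_discard
    if hi - lo < MIN_VALID_WINDOW:
        lo = max(0, (n_t - MIN_VALID_WINDOW) // 2)
        hi = min(n_t, lo + MIN_VALID_WINDOW)
    x = ts.values
    var = x.var(axis=1)
    flagged = tuple(int(i) for i in np.nonzero(var == 0.0)[0])
    analytic = hilbert(x, axis=1)
    phases = np.angle(analytic)
    for i in flagged:
        phases[i, :] = 0.0
    # np.angle returns (-pi, pi]; fold +pi to -pi for a [-pi, pi) convention
    phases[phases == np.pi] = -np.pi
    return PhaseField(
        phases=phases, valid_window=(lo, hi), tr=ts.tr, flagged_nodes=flagged
    )


def estimate_node_frequencies(
    ts: BoldTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    smooth_bins: int = 3,
) -> NodeFrequencies:
    """Per-node peak of a (lightly smoothed) periodogram inside ``band``.

    These peaks are the intrinsic frequencies handed to the whole-brain
    model.  A flat in-band spectrum resolves to the lowest in-band bin,
    with a warning.
    """
    fs = 1.0 / ts.tr
    freqs, pxx = periodogram(ts.values, fs=fs, axis=1, detrend="constant")
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pxx = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, pxx)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError(f"no periodogram bins inside band {band}")
    band_freqs = freqs[in_band]
    band_pxx = pxx[:, in_band]
    ptp = band_pxx.max(axis=1) - band_pxx.min(axis=1)
    if np.any(ptp == 0.0):
        warnings.warn(
            "flat in-band spectrum for some nodes; using lowest in-band frequency",
            stacklevel=2,
        )
    f_peak = band_freqs[np.argmax(band_pxx, axis=1)]
    return NodeFrequencies(f_peak=f_peak, omega=2 * np.pi * f_peak)
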
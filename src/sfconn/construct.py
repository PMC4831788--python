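"""Connectome construction from raw measurements.

Functional connectomes are precision (inverse covariance) matrices of
region time series: directly for haemodynamic (fMRI-like) series, and of
band-limited Hilbert envelopes for electrophysiological (EEG-like) series.
Off-diagonal precision entries encode conditional dependence between
regions given all others, which discounts indirect network paths that
plain correlation conflates.

Structural edge weights summarise a microstructural index along the tract
connecting two regions: a streamline-visitation-weighted average of the
per-voxel index values, or a normalised streamline count.  The orientation
dispersion index (ODI) and the Watson concentration parameter kappa are
related by the closed form ODI = 2/pi * arctan(1/kappa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .atlas import RegionAtlas
from .io import ConnectivityMatrix


@dataclass
class RegionTimeSeries:
    """Time-by-region array of regional signals at a fixed sampling rate."""

    data: np.ndarray
    rate: float
    atlas: Optional[RegionAtlas] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series data must be 2-D (time x region)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.atlas is not None and self.atlas.n != self.data.shape[1]:
            raise ValueError("atlas size must match the number of regions")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("band must satisfy 0 < low < high")


#: The five canonical electrophysiological bands.
BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 70.0),
}


@dataclass
class StreamlineVisitation:
    """Per-voxel index values and streamline visitation counts for one edge."""

    edge: Tuple[str, str]
    values: np.ndarray
    counts: np.ndarray
    n_streamlines: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.values.shape != self.counts.shape:
            raise ValueError("values and counts must have equal length")
        if self.values.size and np.any(self.counts < 1):
            raise ValueError("visitation counts must be >= 1")


def precision_connectome(
    ts: RegionTimeSeries,
    shrinkage: str = "ledoit-wolf",
    modality: str = "fMRI",
    subject: Optional[str] = None,
) -> ConnectivityMatrix:
    """Estimate a functional connectome as the precision matrix of ``ts``.

    ``shrinkage`` selects the covariance estimator inverted:

    - ``"ledoit-wolf"`` (default): Ledoit-Wolf shrinkage toward a scaled
      identity, which keeps the inverse stable when the number of samples
      is not much larger than the number of regions;
    - ``"none"``: the raw sample covariance (errors if singular).
    """
    X = ts.data
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant region time series; precision undefined")
    if shrinkage in ("ledoit-wolf", "lw"):
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    elif shrinkage == "none":
        cov = np.cov(X, rowvar=False, ddof=1)
    else:
        raise ValueError("shrinkage must be 'ledoit-wolf' or 'none'")
    try:
        # Cholesky both checks positive definiteness and inverts stably
        L = np.linalg.cholesky(cov)
        inv_l = np.linalg.inv(L)
        prec = inv_l.T @ inv_l
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular; use shrinkage='ledoit-wolf'"
        ) from exc
    prec = (prec + prec.T) / 2.0
    atlas = ts.atlas
    if atlas is None:
        raise ValueError("time series must carry an atlas to build a connectome")
    return ConnectivityMatrix(values=prec, atlas=atlas, modality=modality, subject=subject)


def band_envelope(ts: RegionTimeSeries, band: BandDefinition, order: int = 4) -> RegionTimeSeries:
    """Band-pass each region's series and take its Hilbert envelope.

    The filter is a zero-phase (forward-backward) Butterworth band-pass; the
    envelope is the magnitude of the analytic signal over the whole series.
    """
    nyq = ts.rate / 2.0
    if not band.high < nyq:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) exceeds Nyquist ({nyq} Hz)"
        )
    sos = butter(order, [band.low, band.high], btype="bandpass", fs=ts.rate, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=0)
    env = np.abs(hilbert(filtered, axis=0))
    return RegionTimeSeries(data=env, rate=ts.rate, atlas=ts.atlas)


def envelope_precision_connectome(
    ts: RegionTimeSeries,
    band: BandDefinition,
    shrinkage: str = "ledoit-wolf",
    subject: Optional[str] = None,
) -> ConnectivityMatrix:
    """Precision matrix of band-limited Hilbert envelopes (EEG-style connectome)."""
    env = band_envelope(ts, band)
    return precision_connectome(env, shrinkage=shrinkage, modality=band.name, subject=subject)


def weighted_edge_average(v: StreamlineVisitation) -> float:
    """Visitation-weighted mean of a microstructural index along a tract.

    Weighting by the number of streamlines passing through each voxel
    down-weights voxels unlikely to belong to the tract.
    """
    if v.values.size == 0:
        raise ValueError(f"empty visitation record for edge {v.edge}")
    return float(np.average(v.values, weights=v.counts))


def nstreams_edge(count: float, size_a: float, size_b: float) -> float:
    """Streamline count normalised by the mean voxel count of the two endpoint regions."""
    if size_a <= 0 or size_b <= 0:
        raise ValueError("region voxel counts must be positive")
    if count < 0:
        raise ValueError("streamline count must be non-negative")
    return 2.0 * count / (size_a + size_b)


def odi_from_kappa(kappa):
    """Orientation dispersion index from the Watson concentration parameter.

    ``ODI = 2/pi * arctan(1/kappa)``, extended continuously to ODI(0) = 1.
    Strictly decreasing bijection from [0, inf) onto (0, 1].
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    out = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return float(out) if out.ndim == 0 else out


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa` on (0, 1]."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi > 1)):
        raise ValueError("ODI must lie in (0, 1]")
    out = np.cos(np.pi * odi / 2.0) / np.sin(np.pi * odi / 2.0)
    return float(out) if out.ndim == 0 else out
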
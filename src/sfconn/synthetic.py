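"""Synthetic data with known ground truth for every pipeline stage.

The central generator emulates the statistical structure the sparse CCA
model assumes: a single latent factor shared by a small set of structural
edges and a small set of functional edges across subjects.  Around it sit
generators for per-subject connectome stacks with tractography-style
missingness (biased toward interhemispheric edges), Gaussian region time
series with a known sparse precision matrix, band-limited oscillations with
correlated amplitude envelopes, and streamline visitation records.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_triangular

from .atlas import INTER, RegionAtlas, build_edge_index, default_atlas
from .construct import BandDefinition, RegionTimeSeries, StreamlineVisitation
from .io import ConnectivityMatrix, PanelMatrix, devectorize_upper


@dataclass
class SyntheticConfig:
    """Study conditions for the coupled-panel generator.

    Defaults mirror the cohort the pipeline is designed for: 17 subjects,
    a 68-region bilateral cortical atlas (2278 edges), one latent factor
    linking ``s_x`` structural to ``s_y`` functional edges with loading
    magnitude ``coupling`` (in units of the unit noise SD), and per-subject
    edge missingness at a rate chosen so that roughly 450 of the 2278 edges
    survive the all-subject intersection, with interhemispheric edges three
    times as likely to drop out (tractography under-recovers long-range
    connections).
    """

    m: int = 17
    n: int = 68
    s_x: int = 10
    s_y: int = 10
    latent_dim: int = 1
    coupling: float = 3.0
    missing_rate: float = 0.09
    inter_missing_odds: float = 3.0
    seed: int = 0

    def __post_init__(self):
        k = self.n * (self.n - 1) // 2
        if not (0 < self.s_x <= k and 0 < self.s_y <= k):
            raise ValueError("support sizes must lie in [1, n(n-1)/2]")
        if self.coupling < 0:
            raise ValueError("coupling must be non-negative")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.latent_dim != 1:
            raise ValueError("only a single latent factor is supported")


@dataclass
class GroundTruth:
    """True supports, loadings and latent subject scores of a simulation."""

    support_x: np.ndarray
    support_y: np.ndarray
    loadings_x: np.ndarray
    loadings_y: np.ndarray
    latent: np.ndarray


def generate_coupled_panels(
    cfg: SyntheticConfig,
) -> Tuple[PanelMatrix, PanelMatrix, GroundTruth]:
    """Edge panels sharing one sparse latent factor.

    Each subject s has a latent score z_s ~ N(0,1).  Supported edge rows are
    ``loading * z_s`` plus unit Gaussian noise, with loadings of magnitude
    ``cfg.coupling`` and random signs; unsupported rows are pure unit noise.
    """
    rng = np.random.default_rng(cfg.seed)
    atlas = default_atlas(cfg.n)
    idx = build_edge_index(atlas)
    k, m = idx.k, cfg.m
    z = rng.standard_normal(m)
    support_x = np.sort(rng.choice(k, size=cfg.s_x, replace=False))
    support_y = np.sort(rng.choice(k, size=cfg.s_y, replace=False))
    lx = cfg.coupling * rng.choice([-1.0, 1.0], size=cfg.s_x)
    ly = cfg.coupling * rng.choice([-1.0, 1.0], size=cfg.s_y)
    X = rng.standard_normal((k, m))
    Y = rng.standard_normal((k, m))
    X[support_x] += np.outer(lx, z)
    Y[support_y] += np.outer(ly, z)
    labels = idx.labels()
    subjects = tuple(f"sub{i + 1:02d}" for i in range(m))
    pos = np.arange(k)
    px = PanelMatrix(
        values=X, edge_pos=pos, edge_labels=tuple(labels), subjects=subjects,
        modality="WFA", standardized=False,
    )
    py = PanelMatrix(
        values=Y, edge_pos=pos.copy(), edge_labels=tuple(labels), subjects=subjects,
        modality="fMRI", standardized=False,
    )
    truth = GroundTruth(
        support_x=support_x, support_y=support_y,
        loadings_x=lx, loadings_y=ly, latent=z,
    )
    return px, py, truth


def _missing_probabilities(idx, rate: float, inter_odds: float) -> np.ndarray:
    """Per-edge knockout probability, inflating interhemispheric odds."""
    if rate == 0:
        return np.zeros(idx.k)
    odds = rate / (1.0 - rate)
    p_inter = inter_odds * odds / (1.0 + inter_odds * odds)
    return np.where(idx.hemiclass == INTER, p_inter, rate)


def generate_connectome_stacks(
    cfg: SyntheticConfig,
    X: PanelMatrix,
    Y: PanelMatrix,
    struct_modality: str = "WFA",
    func_modality: str = "fMRI",
):
    """Devectorise panels into per-subject labeled matrices.

    Structural matrices get per-subject missing edges (knockout probability
    ``cfg.missing_rate``, with interhemispheric odds multiplied by
    ``cfg.inter_missing_odds``); functional matrices are complete, as
    precision-matrix connectomes are defined on every region pair.
    The knockout draw is derived from ``cfg.seed`` and is independent of the
    panel noise draws.
    """
    atlas = default_atlas(cfg.n)
    idx = build_edge_index(atlas)
    if X.k != idx.k or Y.k != idx.k:
        raise ValueError("panels must cover the full edge set of the atlas")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    p_miss = _missing_probabilities(idx, cfg.missing_rate, cfg.inter_missing_odds)
    struct, func = [], []
    for s in range(cfg.m):
        vx = X.values[:, s].copy()
        knock = rng.random(idx.k) < p_miss
        vx[knock] = np.nan
        struct.append(
            devectorize_upper(vx, idx, modality=struct_modality, subject=X.subjects[s])
        )
        func.append(
            devectorize_upper(Y.values[:, s], idx, modality=func_modality,
                              subject=Y.subjects[s])
        )
    return struct, func


def make_sparse_precision(
    n: int,
    n_offdiag: int = 10,
    strength: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """A random sparse symmetric positive definite precision matrix.

    ``n_offdiag`` distinct off-diagonal pairs receive weight ±``strength``;
    the diagonal is loaded to guarantee strict diagonal dominance.
    """
    rng = np.random.default_rng(seed)
    k = n * (n - 1) // 2
    if n_offdiag > k:
        raise ValueError("n_offdiag exceeds the number of off-diagonal pairs")
    iu, ju = np.triu_indices(n, k=1)
    chosen = rng.choice(k, size=n_offdiag, replace=False)
    P = np.zeros((n, n))
    vals = strength * rng.choice([-1.0, 1.0], size=n_offdiag)
    P[iu[chosen], ju[chosen]] = vals
    P += P.T
    P[np.diag_indices(n)] = np.abs(P).sum(axis=1) + 1.0
    return P


def generate_gaussian_timeseries(
    precision: np.ndarray,
    T: int,
    seed: int = 0,
    rate: float = 1.0,
    atlas: Optional[RegionAtlas] = None,
) -> RegionTimeSeries:
    """T i.i.d. draws from the zero-mean Gaussian with the given precision."""
    precision = np.asarray(precision, dtype=float)
    n = precision.shape[0]
    if precision.shape != (n, n) or not np.allclose(precision, precision.T):
        raise ValueError("precision must be square symmetric")
    try:
        Lp = np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision must be positive definite") from exc
    rng = np.random.default_rng(seed)
    # x = L^-T z has covariance (L L')^-1 = precision^-1
    z = rng.standard_normal((T, n))
    data = solve_triangular(Lp.T, z.T, lower=False).T
    return RegionTimeSeries(data=data, rate=rate, atlas=atlas)


def _slow_process(rng, T: int, rate: float, cutoff: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian process (smooth modulator)."""
    from scipy.signal import butter, sosfiltfilt

    x = rng.standard_normal(T)
    sos = butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    y = sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_band_oscillations(
    n: int,
    band: BandDefinition,
    envelope_coupling: Sequence[Tuple[int, int]],
    T: int,
    rate: float,
    seed: int = 0,
    atlas: Optional[RegionAtlas] = None,
    shared_weight: float = 1.5,
) -> RegionTimeSeries:
    """Band-centred sinusoids with slow, positive, optionally shared envelopes.

    Each region carries a carrier at the band centre frequency with its own
    random phase, amplitude-modulated by a slow positive envelope.  Region
    pairs listed in ``envelope_coupling`` additionally share a common slow
    component with weight ``shared_weight`` relative to the unit-variance
    private component, so their measured envelopes correlate at
    ``shared_weight^2 / (shared_weight^2 + 1)``.
    """
    if band.high >= rate / 2:
        raise ValueError("band exceeds Nyquist for the requested rate")
    rng = np.random.default_rng(seed)
    t = np.arange(T) / rate
    fc = (band.low + band.high) / 2.0
    # modulator bandwidth: slow relative to the carrier so the AM sidebands
    # stay inside the analysis band, fast enough that envelope correlations
    # stabilise over realistic series lengths
    cutoff = max(band.low / 6.0, 0.05)
    shared = {}
    for pair in envelope_coupling:
        shared[tuple(sorted(pair))] = _slow_process(rng, T, rate, cutoff)
    data = np.empty((T, n))
    base = 5.0
    for r in range(n):
        env = base + _slow_process(rng, T, rate, cutoff)
        for pair, comp in shared.items():
            if r in pair:
                env = env + shared_weight * comp
        env = np.clip(env, 0.05, None)
        phase = rng.uniform(0, 2 * np.pi)
        data[:, r] = env * np.sin(2 * np.pi * fc * t + phase)
    return RegionTimeSeries(data=data, rate=rate, atlas=atlas)


def generate_streamline_visitation(
    edge: Tuple[str, str],
    n_voxels: int,
    count_range: Tuple[int, int] = (1, 100),
    value_range: Tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
) -> StreamlineVisitation:
    """Random per-voxel index values and visitation counts for one edge."""
    lo_c, hi_c = count_range
    lo_v, hi_v = value_range
    if n_voxels < 1 or lo_c < 1 or hi_c < lo_c or hi_v < lo_v:
        raise ValueError("invalid visitation ranges")
    rng = np.random.default_rng(seed)
    counts = rng.integers(lo_c, hi_c + 1, size=n_voxels)
    values = rng.uniform(lo_v, hi_v, size=n_voxels)
    return StreamlineVisitation(
        edge=tuple(edge), values=values, counts=counts,
        n_streamlines=int(counts.max()),
    )
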
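"""Labeled connectivity matrices: file I/O, vectorisation and panel assembly.

The on-disk dialect is a tab-separated table with a header row and a first
column of region names (rows and columns carry the same label set).  Missing
connections are encoded as blank/NaN cells; an alternative convention that
encodes them as zeros is supported via a reader flag.  For streamline-count
connectomes (``NSTREAMS``) a zero is always additionally treated as missing,
because microstructural averages are undefined on empty tracts.

In memory a subject's connectome is a :class:`ConnectivityMatrix` (values +
explicit boolean missing mask).  Group analyses work on a
:class:`PanelMatrix`: an edges-by-subjects array obtained by vectorising the
upper triangle of each subject's matrix, restricting to the edges present in
every subject, and (optionally) standardising each edge row to zero mean and
unit sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import EdgeIndex, RegionAtlas, build_edge_index

#: Canonical modality tags.  Greek band names are accepted as aliases.
MODALITIES = (
    "fMRI",
    "delta",
    "theta",
    "alpha",
    "beta",
    "gamma",
    "NSTREAMS",
    "WFA",
    "WMD",
    "WICVF",
    "WISO",
    "WODI",
    "Wkappa",
)

_ALIASES = {"δ": "delta", "θ": "theta", "α": "alpha", "β": "beta", "γ": "gamma"}

STRUCTURAL_MODALITIES = ("NSTREAMS", "WFA", "WMD", "WICVF", "WISO", "WODI", "Wkappa")

_SYMMETRY_TOL = 1e-6


def canonical_modality(tag: str) -> str:
    tag = _ALIASES.get(tag, tag)
    if tag not in MODALITIES:
        raise ValueError(f"unknown modality tag {tag!r}; expected one of {MODALITIES}")
    return tag


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric region-by-region graph for one modality.

    ``values`` holds NaN at missing entries; ``missing`` is the matching
    symmetric boolean mask.  The diagonal is ignored by every downstream
    operation.
    """

    values: np.ndarray
    atlas: RegionAtlas
    modality: str
    subject: Optional[str] = None
    missing: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.atlas.n
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n} to match the atlas")
        self.modality = canonical_modality(self.modality)
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        # a zero streamline count is an absent tract, not a measured zero
        if self.modality == "NSTREAMS":
            self.missing |= self.values == 0
        self.missing |= self.missing.T
        self.values = np.where(self.missing, np.nan, self.values)
        off = ~np.eye(n, dtype=bool)
        defined = self.values[off & ~self.missing]
        if not np.all(np.isfinite(defined)):
            raise ValueError("non-missing off-diagonal values must be finite")

    @property
    def n(self) -> int:
        return self.atlas.n


def read_connectome(
    path,
    modality: str,
    subject: Optional[str] = None,
    missing: str = "nan",
) -> ConnectivityMatrix:
    """Read a labeled TSV connectivity matrix.

    Parameters
    ----------
    path :
        Tab-separated table with identical row and column name sets.
    modality :
        Modality tag for the matrix (band names may be Greek or ASCII).
    missing :
        ``"nan"`` (default) treats blank/NaN cells as missing connections;
        ``"zero"`` additionally treats exact zeros as missing (for files
        that encode absent connections as 0).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if set(rows) != set(cols):
        raise ValueError(f"row/column name mismatch in {path}")
    df = df.loc[rows, rows]  # align column order to row order
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if missing == "zero":
        vals = np.where(vals == 0, np.nan, vals)
    elif missing != "nan":
        raise ValueError("missing must be 'nan' or 'zero'")
    both = np.isfinite(vals) & np.isfinite(vals.T)
    if both.any():
        asym = np.max(np.abs(vals - vals.T)[both])
        if asym >= _SYMMETRY_TOL:
            raise ValueError(f"matrix in {path} is asymmetric (max dev {asym:.3g})")
    sym = np.where(both, (vals + vals.T) / 2.0, np.nan)
    atlas = RegionAtlas.from_labels(rows)
    return ConnectivityMatrix(values=sym, atlas=atlas, modality=modality, subject=subject)


def write_connectome(cm: ConnectivityMatrix, path) -> None:
    """Write a labeled TSV matrix; missing entries become blank cells."""
    df = pd.DataFrame(cm.values, index=cm.atlas.labels, columns=cm.atlas.labels)
    df.to_csv(path, sep="\t", na_rep="")


def vectorize_upper(cm: ConnectivityMatrix, idx: EdgeIndex) -> np.ndarray:
    """Vectorise the upper triangle of ``cm`` in canonical edge order.

    Missing edges are marked NaN in the returned vector.
    """
    if cm.atlas != idx.atlas:
        raise ValueError("connectivity matrix and edge index use different atlases")
    return cm.values[idx.pairs[:, 0], idx.pairs[:, 1]]


def devectorize_upper(
    vec: np.ndarray,
    idx: EdgeIndex,
    modality: str,
    subject: Optional[str] = None,
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_upper`; the diagonal is left missing."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (idx.k,):
        raise ValueError(f"edge vector must have length {idx.k}")
    n = idx.atlas.n
    vals = np.full((n, n), np.nan)
    vals[idx.pairs[:, 0], idx.pairs[:, 1]] = vec
    vals[idx.pairs[:, 1], idx.pairs[:, 0]] = vec
    return ConnectivityMatrix(values=vals, atlas=idx.atlas, modality=modality, subject=subject)


def common_edge_mask(stack: Sequence[ConnectivityMatrix]) -> np.ndarray:
    """Edges defined (non-missing) in *every* subject of the stack.

    Connections missing in any subject are excluded from group analyses —
    filling them with zeros would fabricate values for quantities that are
    undefined on absent tracts.
    """
    if len(stack) == 0:
        raise ValueError("empty connectome stack")
    first = stack[0]
    idx = build_edge_index(first.atlas)
    mask = np.ones(idx.k, dtype=bool)
    for cm in stack:
        if cm.atlas != first.atlas:
            raise ValueError("all matrices in a stack must share the atlas")
        if cm.modality != first.modality:
            raise ValueError("all matrices in a stack must share the modality")
        mask &= ~np.isnan(vectorize_upper(cm, idx))
    return mask


@dataclass
class PanelMatrix:
    """Edges-by-subjects data panel (the CCA view of a connectome stack)."""

    values: np.ndarray
    edge_pos: np.ndarray  # positions into the canonical EdgeIndex of the atlas
    edge_labels: tuple  # (region, region) label pairs
    subjects: tuple
    modality: str
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.edge_pos), len(self.subjects)):
            raise ValueError("panel shape must be (n_edges, n_subjects)")
        if np.isnan(self.values).any():
            raise ValueError("panel values must be complete (no NaN)")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def assemble_panel(
    stack: Sequence[ConnectivityMatrix],
    mask: Optional[np.ndarray] = None,
) -> PanelMatrix:
    """Stack vectorised connectomes into an edges-by-subjects panel.

    ``mask`` defaults to :func:`common_edge_mask` of the stack; rows are the
    retained edges, columns the subjects, in stack order.
    """
    if mask is None:
        mask = common_edge_mask(stack)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("edge mask excludes all edges")
    idx = build_edge_index(stack[0].atlas)
    cols = [vectorize_upper(cm, idx)[mask] for cm in stack]
    values = np.column_stack(cols)
    if np.isnan(values).any():
        raise ValueError("mask retains edges that are missing in some subject")
    labels = idx.labels()
    pos = np.flatnonzero(mask)
    subjects = tuple(
        cm.subject if cm.subject is not None else f"sub{i + 1:02d}"
        for i, cm in enumerate(stack)
    )
    return PanelMatrix(
        values=values,
        edge_pos=pos,
        edge_labels=tuple(labels[p] for p in pos),
        subjects=subjects,
        modality=stack[0].modality,
        standardized=False,
    )


def standardize_rows(p: PanelMatrix) -> PanelMatrix:
    """Centre and scale each edge row to mean 0 and unit sample SD (ddof=1)."""
    if p.m < 3:
        raise ValueError("standardisation needs at least 3 subjects")
    mu = p.values.mean(axis=1, keepdims=True)
    sd = p.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(
            f"constant edge row (zero variance): {p.edge_labels[zero[0]]}"
        )
    return replace(p, values=(p.values - mu) / sd, standardized=True)
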
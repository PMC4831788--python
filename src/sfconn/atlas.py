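"""Region atlases and canonical edge indexing for cortical connectomes.

A connectome is an undirected graph over a fixed set of cortical regions.
Regions carry a hemisphere tag parsed from their name (FreeSurfer-style
``lh_``/``rh_`` prefixes by default), and every unordered region pair is an
*edge*.  The canonical edge order used throughout the package is the
row-major upper triangle of the region-by-region matrix, so that a
symmetric matrix and its edge vector are mutually convertible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Default regex used to parse hemisphere membership from a region label.
#: The first capture group must be ``lh`` or ``rh``.
HEMI_PATTERN = r"^(lh|rh)[_.]"

INTRA_LEFT = "intra-left"
INTRA_RIGHT = "intra-right"
INTER = "inter"


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered set of cortical regions with hemisphere membership.

    Parameters
    ----------
    labels :
        Unique region names, in matrix row/column order.
    hemisphere :
        Per-region tag, either ``"left"`` or ``"right"``.
    sizes :
        Optional per-region voxel counts (positive integers); used by
        streamline-density edge weights.
    """

    labels: tuple
    hemisphere: tuple
    sizes: Optional[tuple] = None

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("region labels must be unique")
        if len(self.hemisphere) != len(self.labels):
            raise ValueError("hemisphere tags must match labels one-to-one")
        bad = set(self.hemisphere) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")
        if self.sizes is not None:
            if len(self.sizes) != len(self.labels):
                raise ValueError("sizes must match labels one-to-one")
            if any(s <= 0 for s in self.sizes):
                raise ValueError("region sizes must be positive")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[str],
        pattern: str = HEMI_PATTERN,
        sizes: Optional[Sequence[int]] = None,
    ) -> "RegionAtlas":
        """Build an atlas, parsing hemispheres from label prefixes.

        ``pattern`` is a regex whose first group is ``lh`` or ``rh``; it can
        be overridden for atlases that use a different naming convention.
        """
        rx = re.compile(pattern)
        hemis = []
        for lab in labels:
            m = rx.match(lab)
            if m is None:
                raise ValueError(
                    f"cannot parse hemisphere from region label {lab!r} "
                    f"with pattern {pattern!r}"
                )
            hemis.append("left" if m.group(1) == "lh" else "right")
        return cls(
            labels=tuple(labels),
            hemisphere=tuple(hemis),
            sizes=tuple(sizes) if sizes is not None else None,
        )

    def __eq__(self, other):
        if not isinstance(other, RegionAtlas):
            return NotImplemented
        return self.labels == other.labels and self.hemisphere == other.hemisphere


def default_atlas(n: int = 68) -> RegionAtlas:
    """A generic bilateral atlas ``lh_r01.. , rh_r01..`` with ``n`` regions.

    The first ``ceil(n/2)`` regions are assigned to the left hemisphere.
    The default of 68 matches a standard whole-cortex parcellation.
    """
    if n < 2:
        raise ValueError("atlas size must be >= 2")
    half = (n + 1) // 2
    labels = [f"lh_r{i + 1:02d}" for i in range(half)]
    labels += [f"rh_r{i + 1:02d}" for i in range(n - half)]
    return RegionAtlas.from_labels(labels)


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical enumeration of the ``n(n-1)/2`` edges of an atlas.

    ``pairs[e] = (i, j)`` with ``i < j`` in row-major upper-triangle order;
    ``hemiclass[e]`` is ``intra-left``, ``intra-right`` or ``inter``.
    """

    atlas: RegionAtlas
    pairs: np.ndarray
    hemiclass: np.ndarray

    @property
    def k(self) -> int:
        return len(self.pairs)

    def labels(self) -> list:
        """Edge labels as (region, region) name pairs."""
        labs = self.atlas.labels
        return [(labs[i], labs[j]) for i, j in self.pairs]


def build_edge_index(atlas: RegionAtlas) -> EdgeIndex:
    """Enumerate all unordered region pairs of ``atlas`` with hemisphere classes."""
    n = atlas.n
    iu, ju = np.triu_indices(n, k=1)
    pairs = np.column_stack([iu, ju])
    hemi = np.asarray(atlas.hemisphere)
    cls = np.where(
        hemi[iu] != hemi[ju],
        INTER,
        np.where(hemi[iu] == "left", INTRA_LEFT, INTRA_RIGHT),
    )
    return EdgeIndex(atlas=atlas, pairs=pairs, hemiclass=cls)
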
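"""Reporting: index correlation tables, hemispheric fingerprints, probability
maps, graph export and the end-to-end pipeline driver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .atlas import EdgeIndex, INTER, INTRA_LEFT, INTRA_RIGHT, RegionAtlas, build_edge_index
from .io import (
    ConnectivityMatrix,
    PanelMatrix,
    assemble_panel,
    read_connectome,
    standardize_rows,
    write_connectome,
)
from .scca import SCCAConfig
from .stability import (
    SelectionDecision,
    StabilityConfig,
    StabilityResult,
    bootstrap_stability,
    classify_edges,
)
from .synthetic import SyntheticConfig, generate_connectome_stacks, generate_coupled_panels

HEMICLASSES = (INTRA_LEFT, INTRA_RIGHT, INTER)


@dataclass
class IndexCorrelationTable:
    """Squared Pearson correlations between pairs of microstructural indices.

    Each index's retained edge values are concatenated across subjects into
    one long vector; entry (a, b) is the squared correlation of the two
    vectors.  R^2 is sign-blind, so strong anti-correlations (e.g. FA vs
    orientation dispersion) appear as large values.
    """

    indices: tuple
    r2: np.ndarray
    n_points: int


def pairwise_r2(panels: Mapping[str, PanelMatrix]) -> IndexCorrelationTable:
    """Pairwise R^2 of raw edge values, concatenated across subjects.

    All panels must share the same retained edge set and subject order and
    must not be standardised (per-edge standardisation would distort
    cross-index relationships).
    """
    names = tuple(panels.keys())
    if not names:
        raise ValueError("no panels given")
    ref = panels[names[0]]
    for name in names:
        p = panels[name]
        if p.standardized:
            raise ValueError("pairwise R^2 operates on unstandardised values")
        if p.edge_labels != ref.edge_labels or p.subjects != ref.subjects:
            raise ValueError(f"panel {name!r} has mismatched edges or subjects")
    flat = np.vstack([panels[name].values.ravel() for name in names])
    r = np.corrcoef(flat)
    r2 = r**2
    np.fill_diagonal(r2, 1.0)
    return IndexCorrelationTable(indices=names, r2=r2, n_points=ref.k * ref.m)


@dataclass
class FingerprintSummary:
    """Hemispheric composition of a selected-edge set."""

    pair: str
    counts: dict
    fractions: dict
    total: int


def hemispheric_summary(
    decision: SelectionDecision,
    idx: EdgeIndex,
    pair: str = "",
) -> FingerprintSummary:
    """Count selected edges per hemisphere class (intra-left/intra-right/inter)."""
    sel = decision.selected
    if np.any(sel >= idx.k):
        raise ValueError("decision refers to edges outside the edge index")
    counts = {h: int(np.sum(idx.hemiclass[sel] == h)) for h in HEMICLASSES}
    total = int(sel.size)
    fractions = {
        h: (counts[h] / total if total else 0.0) for h in HEMICLASSES
    }
    return FingerprintSummary(pair=pair, counts=counts, fractions=fractions, total=total)


def _hemi_order(atlas: RegionAtlas) -> np.ndarray:
    """Stable permutation placing left-hemisphere regions first."""
    hemi = np.asarray(atlas.hemisphere)
    return np.concatenate([np.flatnonzero(hemi == "left"), np.flatnonzero(hemi == "right")])


def export_probability_map(
    res: StabilityResult,
    panel: str = "structural",
    path: Optional[Path] = None,
) -> ConnectivityMatrix:
    """Selection probabilities as a symmetric labeled matrix.

    Rows are ordered left hemisphere first, then right, so the bottom-left
    quadrant of the written matrix holds intra-left connections, the
    top-right intra-right, and the off quadrants interhemispheric ones.
    Edges never available in any resample are left missing.
    """
    idx = res.edge_index_structural if panel == "structural" else res.edge_index_functional
    if idx is None:
        raise ValueError("stability result carries no edge index for this panel")
    probs = res.probabilities_structural if panel == "structural" else res.probabilities_functional
    tested = res.tested_structural if panel == "structural" else res.tested_functional
    n = idx.atlas.n
    vals = np.full((n, n), np.nan)
    i, j = idx.pairs[:, 0], idx.pairs[:, 1]
    ok = tested > 0
    vals[i[ok], j[ok]] = probs[ok]
    vals[j[ok], i[ok]] = probs[ok]
    order = _hemi_order(idx.atlas)
    atlas = RegionAtlas(
        labels=tuple(idx.atlas.labels[p] for p in order),
        hemisphere=tuple(idx.atlas.hemisphere[p] for p in order),
    )
    cm = ConnectivityMatrix(
        values=vals[np.ix_(order, order)], atlas=atlas, modality="fMRI"
    )
    # reuse the label-matrix writer; the modality tag is not serialised
    if path is not None:
        write_connectome(cm, path)
    return cm


def selected_edge_graph(decision: SelectionDecision, idx: EdgeIndex):
    """Selected edges as a networkx graph (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    for lab, hemi in zip(idx.atlas.labels, idx.atlas.hemisphere):
        g.add_node(lab, hemisphere=hemi)
    labs = idx.atlas.labels
    for e in decision.selected:
        i, j = idx.pairs[e]
        g.add_edge(
            labs[i], labs[j],
            hemiclass=str(idx.hemiclass[e]),
            loading=float(decision.loading_mean[e]),
        )
    return g


def _load_stack(paths, modality, missing="nan"):
    return [
        read_connectome(p, modality=modality, subject=f"sub{i + 1:02d}", missing=missing)
        for i, p in enumerate(paths)
    ]


def run_pipeline(config: dict, output_dir: Optional[Path] = None) -> dict:
    """Execute the full analysis for every requested modality pair.

    ``config`` is a plain mapping (typically parsed from YAML) with keys:

    - ``pairs``: list of ``[structural_index, functional_modality]`` pairs;
    - ``simulate``: :class:`SyntheticConfig` fields (simulation mode), or
    - ``inputs``: ``{"structural": {index: [paths]}, "functional":
      {modality: [paths]}}`` (file mode);
    - ``stability``: :class:`StabilityConfig` fields, with an optional
      nested ``scca`` block.

    For each pair the bootstrap stability selection is run, edges are
    classified against the binomial chance model, and a probability map,
    a decision table and a JSON summary are written under ``output_dir``
    (when given).  Returns the result bundle as a dict.
    """
    stab_kwargs = dict(config.get("stability", {}))
    scca_kwargs = stab_kwargs.pop("scca", {})
    stab_cfg = StabilityConfig(scca=SCCAConfig(**scca_kwargs), **stab_kwargs)
    pairs = config.get("pairs") or [["WFA", "fMRI"]]
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
    bundle = {"pairs": {}, "seed": stab_cfg.seed}
    for i, (s_mod, f_mod) in enumerate(pairs):
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs["seed"] = int(sim_kwargs.get("seed", stab_cfg.seed)) + i
            sim = SyntheticConfig(**sim_kwargs)
            X, Y, truth = generate_coupled_panels(sim)
            struct, func = generate_connectome_stacks(
                sim, X, Y, struct_modality=s_mod, func_modality=f_mod
            )
        elif "inputs" in config:
            struct = _load_stack(
                config["inputs"]["structural"][s_mod], s_mod,
                missing=config.get("missing", "nan"),
            )
            func = _load_stack(
                config["inputs"]["functional"][f_mod], f_mod,
                missing=config.get("missing", "nan"),
            )
        else:
            raise ValueError("config must provide either 'simulate' or 'inputs'")
        res = bootstrap_stability(struct, func, stab_cfg)
        decision = classify_edges(res, stab_cfg)
        idx = res.edge_index_structural
        fp = hemispheric_summary(decision, idx, pair=f"{s_mod}-{f_mod}")
        name = f"{s_mod}_{f_mod}"
        summary = {
            "p_chance": res.p_chance,
            "k_lo": decision.k_lo,
            "k_hi": decision.k_hi,
            "n_selected": int(decision.selected.size),
            "n_rejected": int(decision.rejected.size),
            "n_undetermined": int(decision.undetermined.size),
            "mean_available": float(res.available_per_iter.mean()),
            "mean_selected_per_iter": float(res.selected_per_iter.mean()),
            "fingerprint": {"counts": fp.counts, "fractions": fp.fractions},
        }
        bundle["pairs"][name] = summary
        if output_dir is not None:
            export_probability_map(res, path=output_dir / f"probability_{name}.tsv")
            _write_decision_table(decision, idx, output_dir / f"decision_{name}.tsv")
            with open(output_dir / f"summary_{name}.json", "w") as fh:
                json.dump(summary, fh, indent=2)
    if output_dir is not None:
        with open(output_dir / "bundle.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
    return bundle


def _write_decision_table(decision: SelectionDecision, idx: EdgeIndex, path: Path) -> None:
    import pandas as pd

    status = np.full(idx.k, "untested", dtype=object)
    status[decision.undetermined] = "undetermined"
    status[decision.selected] = "selected"
    status[decision.rejected] = "rejected"
    labs = idx.labels()
    df = pd.DataFrame(
        {
            "region_a": [a for a, _ in labs],
            "region_b": [b for _, b in labs],
            "hemiclass": idx.hemiclass,
            "status": status,
            "mean_loading": decision.loading_mean,
        }
    )
    df.to_csv(path, sep="\t", index=False)
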
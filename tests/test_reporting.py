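"""Index correlation tables, fingerprints, probability maps, pipeline, CLI."""

import json

import numpy as np
import pytest

from sfconn import (
    StabilityConfig,
    SyntheticConfig,
    bootstrap_stability,
    build_edge_index,
    classify_edges,
    default_atlas,
    export_probability_map,
    generate_connectome_stacks,
    generate_coupled_panels,
    hemispheric_summary,
    pairwise_r2,
    read_connectome,
    run_pipeline,
    selected_edge_graph,
    vectorize_upper,
)
from sfconn.io import PanelMatrix
from sfconn.stability import SelectionDecision


def _panel(values, modality="WFA"):
    values = np.asarray(values, float)
    k, m = values.shape
    return PanelMatrix(
        values=values,
        edge_pos=np.arange(k),
        edge_labels=tuple((f"lh_e{i}", f"rh_e{i}") for i in range(k)),
        subjects=tuple(f"sub{j:02d}" for j in range(m)),
        modality=modality,
    )


class TestPairwiseR2:
    def test_self_correlation_is_one(self, rng):
        p = _panel(rng.standard_normal((20, 5)))
        q = _panel(p.values.copy(), "WMD")
        table = pairwise_r2({"WFA": p, "WMD": q})
        np.testing.assert_allclose(table.r2, np.ones((2, 2)))
        assert table.n_points == 100

    def test_anticorrelation_gives_r2_one(self, rng):
        p = _panel(rng.standard_normal((20, 5)))
        q = _panel(-p.values, "WODI")
        table = pairwise_r2({"WFA": p, "WODI": q})
        assert table.r2[0, 1] == pytest.approx(1.0)

    def test_table_symmetric_in_unit_interval(self, rng):
        panels = {
            name: _panel(rng.standard_normal((30, 6)), name)
            for name in ("WFA", "WMD", "WICVF")
        }
        t = pairwise_r2(panels)
        np.testing.assert_allclose(t.r2, t.r2.T)
        assert np.all((t.r2 >= 0) & (t.r2 <= 1 + 1e-12))

    def test_known_r2_recovered(self, rng):
        # y = x + noise with var ratio chosen for a known population R^2
        x = rng.standard_normal((50, 10))
        noise = rng.standard_normal((50, 10))
        y = x + noise  # population R^2 = 0.5
        t = pairwise_r2({"WFA": _panel(x), "WMD": _panel(y, "WMD")})
        assert t.r2[0, 1] == pytest.approx(0.5, abs=0.08)

    def test_common_permutation_invariance(self, rng):
        a = rng.standard_normal((15, 4))
        b = rng.standard_normal((15, 4))
        t1 = pairwise_r2({"WFA": _panel(a), "WMD": _panel(b, "WMD")}).r2[0, 1]
        perm = rng.permutation(15)
        t2 = pairwise_r2(
            {"WFA": _panel(a[perm]), "WMD": _panel(b[perm], "WMD")}
        ).r2[0, 1]
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_standardised_panels_rejected(self, rng):
        p = _panel(rng.standard_normal((10, 4)))
        p.standardized = True
        with pytest.raises(ValueError, match="unstandardised"):
            pairwise_r2({"WFA": p, "WMD": p})

    def test_mismatched_edges_rejected(self, rng):
        p = _panel(rng.standard_normal((10, 4)))
        q = _panel(rng.standard_normal((9, 4)), "WMD")
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_r2({"WFA": p, "WMD": q})


def _decision(selected, k):
    return SelectionDecision(
        selected=np.asarray(selected, int),
        rejected=np.array([], int),
        undetermined=np.array([], int),
        k_lo=0,
        k_hi=1,
        loading_mean=np.zeros(k),
    )


class TestHemisphericSummary:
    def test_mixed_selection(self):
        idx = build_edge_index(default_atlas(4))
        # edges: (l1,l2) intra-left, (l1,r1) inter, ...
        labels = idx.labels()
        want = {("lh_r01", "lh_r02"), ("lh_r01", "rh_r01")}
        sel = [i for i, lab in enumerate(labels) if lab in want]
        fp = hemispheric_summary(_decision(sel, idx.k), idx)
        assert fp.counts == {"intra-left": 1, "intra-right": 0, "inter": 1}
        assert fp.fractions["intra-left"] == 0.5
        assert sum(fp.fractions.values()) == pytest.approx(1.0)

    def test_empty_selection(self):
        idx = build_edge_index(default_atlas(4))
        fp = hemispheric_summary(_decision([], idx.k), idx)
        assert fp.total == 0
        assert all(v == 0 for v in fp.counts.values())

    def test_single_class_fraction_one(self):
        idx = build_edge_index(default_atlas(6))
        sel = np.flatnonzero(idx.hemiclass == "inter")
        fp = hemispheric_summary(_decision(sel, idx.k), idx)
        assert fp.fractions["inter"] == 1.0


@pytest.fixture(scope="module")
def stab():
    cfg = SyntheticConfig(m=10, n=12, coupling=3.0, s_x=4, s_y=4,
                          missing_rate=0.05, seed=19)
    X, Y, _ = generate_coupled_panels(cfg)
    struct, func = generate_connectome_stacks(cfg, X, Y)
    return bootstrap_stability(struct, func, StabilityConfig(B=25, seed=3))


class TestProbabilityMap:
    def test_map_roundtrips_through_reader(self, stab, tmp_path):
        path = tmp_path / "probmap.tsv"
        cm = export_probability_map(stab, path=path)
        back = read_connectome(path, modality="fMRI")
        np.testing.assert_allclose(
            back.values[~back.missing], cm.values[~cm.missing], atol=1e-12
        )
        assert back.atlas.labels == cm.atlas.labels

    def test_map_symmetric_unit_interval(self, stab):
        cm = export_probability_map(stab)
        v = cm.values
        assert np.allclose(v, v.T, equal_nan=True)
        ok = ~np.isnan(v)
        assert np.all((v[ok] >= 0) & (v[ok] <= 1))

    def test_left_regions_listed_first(self, stab):
        cm = export_probability_map(stab)
        hemis = list(cm.atlas.hemisphere)
        assert hemis == sorted(hemis, key=lambda h: h != "left")

    def test_untested_edges_missing(self, stab):
        cm = export_probability_map(stab)
        idx = stab.edge_index_structural
        # edges dropped in every resample must be NaN in the exported map
        never = np.flatnonzero(stab.tested_structural == 0)
        relabel = {lab: i for i, lab in enumerate(cm.atlas.labels)}
        for e in never:
            i, j = idx.pairs[e]
            a = relabel[idx.atlas.labels[i]]
            b = relabel[idx.atlas.labels[j]]
            assert np.isnan(cm.values[a, b])

    def test_graph_export(self, stab, tmp_path):
        import networkx as nx

        cfg = StabilityConfig(B=25, seed=3)
        dec = classify_edges(stab, cfg)
        g = selected_edge_graph(dec, stab.edge_index_structural)
        assert g.number_of_edges() == dec.selected.size
        nx.write_graphml(g, tmp_path / "sel.graphml")
        assert (tmp_path / "sel.graphml").stat().st_size > 0


class TestPipeline:
    CONFIG = {
        "pairs": [["WFA", "alpha"], ["WICVF", "delta"]],
        "simulate": {"m": 10, "n": 12, "coupling": 3.0, "s_x": 4, "s_y": 4,
                     "missing_rate": 0.05, "seed": 5},
        "stability": {"B": 12, "alpha": 0.05, "seed": 5},
    }

    def test_simulate_grid_end_to_end(self, tmp_path):
        bundle = run_pipeline(self.CONFIG, output_dir=tmp_path)
        assert set(bundle["pairs"]) == {"WFA_alpha", "WICVF_delta"}
        for name, summary in bundle["pairs"].items():
            assert 0 < summary["p_chance"] < 1
            assert (tmp_path / f"probability_{name}.tsv").exists()
            assert (tmp_path / f"decision_{name}.tsv").exists()
            assert "fingerprint" in summary
        saved = json.loads((tmp_path / "bundle.json").read_text())
        assert saved == bundle

    def test_same_seed_identical_bundles(self, tmp_path):
        b1 = run_pipeline(self.CONFIG, output_dir=tmp_path / "a")
        b2 = run_pipeline(self.CONFIG, output_dir=tmp_path / "b")
        assert b1 == b2

    def test_file_mode_matches_simulate_stacks(self, tmp_path):
        from sfconn import write_connectome

        cfg = SyntheticConfig(m=9, n=10, coupling=3.0, s_x=3, s_y=3,
                              missing_rate=0.05, seed=2)
        X, Y, _ = generate_coupled_panels(cfg)
        struct, func = generate_connectome_stacks(cfg, X, Y)
        sdir, fdir = tmp_path / "s", tmp_path / "f"
        sdir.mkdir(), fdir.mkdir()
        spaths, fpaths = [], []
        for cm in struct:
            p = sdir / f"{cm.subject}.tsv"
            write_connectome(cm, p)
            spaths.append(str(p))
        for cm in func:
            p = fdir / f"{cm.subject}.tsv"
            write_connectome(cm, p)
            fpaths.append(str(p))
        config = {
            "pairs": [["WFA", "fMRI"]],
            "inputs": {"structural": {"WFA": spaths}, "functional": {"fMRI": fpaths}},
            "stability": {"B": 10, "seed": 4},
        }
        direct = bootstrap_stability(struct, func, StabilityConfig(B=10, seed=4))
        bundle = run_pipeline(config)
        assert bundle["pairs"]["WFA_fMRI"]["p_chance"] == pytest.approx(
            direct.p_chance, abs=1e-12
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="simulate.*inputs"):
            run_pipeline({"pairs": [["WFA", "fMRI"]]})


class TestCli:
    def test_simulate_then_stability_and_r2(self, tmp_path):
        from click.testing import CliRunner

        from sfconn.cli import main

        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(main, [
            "simulate", "--out", str(out), "--m", "9", "--n", "10",
            "--s-x", "3", "--s-y", "3", "--missing-rate", "0.05", "--seed", "3",
        ])
        assert r.exit_code == 0, r.output
        spaths = sorted((out / "structural").glob("*.tsv"))
        fpaths = sorted((out / "functional").glob("*.tsv"))
        assert len(spaths) == len(fpaths) == 9

        args = ["stability", "--b", "10", "--seed", "1",
                "--out", str(tmp_path / "res")]
        for p in spaths:
            args += ["--structural", str(p)]
        for p in fpaths:
            args += ["--functional", str(p)]
        r = runner.invoke(main, args)
        assert r.exit_code == 0, r.output
        assert (tmp_path / "res" / "bundle.json").exists()

        r = runner.invoke(main, [
            "pairwise-r2",
            "--index", f"WFA={out / 'structural'}",
            "--index", f"WMD={out / 'structural'}",
        ])
        assert r.exit_code == 0, r.output
        table = json.loads(r.output)
        assert table["r2"][0][1] == pytest.approx(1.0)  # same data twice

    def test_fit_scca_smoke(self, tmp_path):
        from click.testing import CliRunner

        from sfconn.cli import main

        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(main, [
            "simulate", "--out", str(out), "--m", "9", "--n", "10",
            "--s-x", "3", "--s-y", "3", "--missing-rate", "0.0", "--seed", "3",
        ])
        assert r.exit_code == 0, r.output
        args = []
        for p in sorted((out / "structural").glob("*.tsv")):
            args += ["--structural", str(p)]
        for p in sorted((out / "functional").glob("*.tsv")):
            args += ["--functional", str(p)]
        r = runner.invoke(main, ["fit-scca"] + args)
        assert r.exit_code == 0, r.output
        res = json.loads(r.output)
        assert 0 <= res["rho"] <= 1
        assert res["support_structural"] >= 1

    def test_build_connectomes_smoke(self, tmp_path):
        import pandas as pd
        from click.testing import CliRunner

        from sfconn.cli import main
        from sfconn.synthetic import generate_gaussian_timeseries, make_sparse_precision

        atlas = default_atlas(6)
        ts = generate_gaussian_timeseries(make_sparse_precision(6, 4, seed=1),
                                          T=400, seed=2)
        path = tmp_path / "sub01.tsv"
        pd.DataFrame(ts.data, columns=atlas.labels).to_csv(path, sep="\t", index=False)
        runner = CliRunner()
        r = runner.invoke(main, [
            "build-connectomes", str(path), "--out", str(tmp_path / "conn"),
            "--rate", "1.0",
        ])
        assert r.exit_code == 0, r.output
        cm = read_connectome(tmp_path / "conn" / "sub01.tsv", modality="fMRI")
        assert np.linalg.eigvalsh(cm.values).min() > 0
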
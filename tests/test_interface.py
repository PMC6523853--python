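"""TSV dialect round-trips, run configuration and the pipeline driver."""

import json

import numpy as np
import pandas as pd
import pytest

import apmsdiff as a
from apmsdiff.io import condition_map_from_flat_headers, write_quant_tsv
from apmsdiff.tables import make_columns


def _tiny_table():
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                      index=pd.Index(["P1", "P2"], name="accession"),
                      columns=make_columns({"A": 2}))
    return a.QuantTable(df, mode="raw_ibaq")


def test_quant_tsv_round_trip(tmp_path):
    path = tmp_path / "q.tsv"
    q = _tiny_table()
    write_quant_tsv(q, path)
    cmap = condition_map_from_flat_headers(path)
    q2 = a.read_quant_tsv(path, cmap)
    pd.testing.assert_frame_equal(q.values, q2.values)
    # write -> read -> write is byte-stable
    path2 = tmp_path / "q2.tsv"
    write_quant_tsv(q2, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_reverse_flagged_rows_dropped(tmp_path, caplog):
    import logging
    path = tmp_path / "pg.tsv"
    path.write_text("accession\tReverse\tA.1\tA.2\n"
                    "P1\t\t1.0\t2.0\n"
                    "REV_P9\t+\t5.0\t6.0\n")
    with caplog.at_level(logging.INFO, logger="apmsdiff.io"):
        q = a.read_quant_tsv(path, {"A.1": ("A", 1), "A.2": ("A", 2)})
    assert list(q.values.index) == ["P1"]
    assert any("dropped 1" in r.message for r in caplog.records)


def test_missing_accession_column_names_expected_header(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("protein\tA.1\nP1\t1.0\n")
    with pytest.raises(a.DataError, match="accession"):
        a.read_quant_tsv(path, {"A.1": ("A", 1)})


def test_duplicate_accessions_and_non_numeric_cells_rejected(tmp_path):
    dup = tmp_path / "dup.tsv"
    dup.write_text("accession\tA.1\nP1\t1.0\nP1\t2.0\n")
    with pytest.raises(a.DataError, match="P1"):
        a.read_quant_tsv(dup, {"A.1": ("A", 1)})
    nn = tmp_path / "nn.tsv"
    nn.write_text("accession\tA.1\nP1\toops\n")
    with pytest.raises(a.DataError, match="A.1"):
        a.read_quant_tsv(nn, {"A.1": ("A", 1)})


def test_run_config_defaults_match_published_constants():
    cfg = a.RunConfig()
    vcfg = a.VolcanoConfig()
    assert cfg.b_perm == vcfg.b_perm == 10_000
    assert cfg.p_threshold == vcfg.p_threshold == 0.025
    assert cfg.delta_threshold == vcfg.delta_threshold == 6.0
    assert cfg.classification_threshold == 5.0
    assert cfg.min_replicates == 2
    assert vcfg.p_threshold_log == pytest.approx(1.60, abs=0.005)


def test_run_config_yaml_round_trip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("route: ibaq_ratio\nb_perm: 50\ncluster_k_range: [3, 6]\n")
    cfg = a.RunConfig.from_yaml(path)
    assert cfg.route == "ibaq_ratio" and cfg.b_perm == 50
    assert cfg.cluster_k_range == (3, 6)
    bad = tmp_path / "bad.yaml"
    bad.write_text("no_such_key: 1\n")
    with pytest.raises(a.ConfigurationError):
        a.RunConfig.from_yaml(bad)


def test_pipeline_deterministic_given_seed(tmp_path):
    sim = a.SimConfig(n_conditions=2, n_background_binders=60,
                      n_specific_per_condition=6, n_shared_specific=4, seed=21)
    outs = []
    for sub in ("r1", "r2"):
        cfg = a.RunConfig(b_perm=100, seed=21, outdir=str(tmp_path / sub),
                          make_plots=False)
        a.run_pipeline(cfg, sim_config=sim)
        outs.append(tmp_path / sub)
    for name in ("manifest.json", "ibaq.tsv", "differential_bait1_vs_bait2.tsv",
                 "jaccard.tsv", "pca_scores.tsv", "clusters.tsv"):
        assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()


def test_pipeline_requires_background_condition():
    df = pd.DataFrame(np.ones((3, 6)),
                      index=pd.Index(["P1", "P2", "P3"], name="accession"),
                      columns=make_columns({"A": 3, "B": 3}))
    q = a.QuantTable(df, mode="raw_ibaq")
    with pytest.raises(a.ConfigurationError, match="background"):
        a.run_pipeline(a.RunConfig(make_plots=False), proteins=q)


def test_manifest_records_every_decision_flag(tmp_path):
    sim = a.SimConfig(n_conditions=2, n_background_binders=50,
                      n_specific_per_condition=5, n_shared_specific=0, seed=2)
    base = a.RunConfig(b_perm=50, seed=2, make_plots=False)
    changed = a.RunConfig(b_perm=50, seed=2, make_plots=False, zero_policy="drop")
    m1 = a.run_pipeline(base, sim_config=sim).manifest
    m2 = a.run_pipeline(changed, sim_config=sim).manifest
    assert m1["config"] != m2["config"]
    assert m1["config"]["zero_policy"] == "floor"
    assert m2["config"]["zero_policy"] == "drop"
    # every RunConfig field except the output sink appears in the manifest
    assert set(m1["config"]) == set(a.RunConfig().to_dict()) - {"outdir"}


def test_routes_agree_on_fully_observed_proteins():
    # the two processing routes express the same quantity through the 2^x
    # identity, so deltas coincide where nothing was floored or dropped
    sim = a.SimConfig(n_conditions=2, n_background_binders=80,
                      n_specific_per_condition=8, n_shared_specific=4,
                      dropout_rate=0.0, seed=9)
    res_h = a.run_pipeline(a.RunConfig(route="holistic", b_perm=20, seed=9,
                                       make_plots=False), sim_config=sim)
    res_r = a.run_pipeline(a.RunConfig(route="ibaq_ratio", b_perm=20, seed=9,
                                       make_plots=False), sim_config=sim)
    dh = res_h.differential[("bait1", "bait2")]["delta"]
    dr = res_r.differential[("bait1", "bait2")]["delta"]
    common = dh.index.intersection(dr.index)
    np.testing.assert_allclose(dh.loc[common], dr.loc[common], rtol=1e-9, atol=1e-9)


def test_pipeline_plot_and_output_files(tmp_path):
    sim = a.SimConfig(n_conditions=3, n_background_binders=40,
                      n_specific_per_condition=5, n_shared_specific=0, seed=4)
    cfg = a.RunConfig(b_perm=50, seed=4, outdir=str(tmp_path), make_plots=True)
    a.run_pipeline(cfg, sim_config=sim)
    for name in ("volcano_bait1_vs_bait2.png", "jaccard_heatmap.png", "pca_3d.png"):
        assert (tmp_path / name).stat().st_size > 0
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["config"]["b_perm"] == 50


def test_cli_simulate_and_run(tmp_path):
    from click.testing import CliRunner
    from apmsdiff.cli import main
    runner = CliRunner()
    simdir = tmp_path / "sim"
    r = runner.invoke(main, ["simulate", "--seed", "3", "--conditions", "2",
                             "--out", str(simdir)])
    assert r.exit_code == 0, r.output
    assert (simdir / "proteins.tsv").exists()
    cfgfile = tmp_path / "cfg.yaml"
    cfgfile.write_text("b_perm: 50\nmake_plots: false\n")
    r2 = runner.invoke(main, ["run", "--table", str(simdir / "proteins.tsv"),
                              "--config", str(cfgfile), "--seed", "3",
                              "--out", str(tmp_path / "out")])
    assert r2.exit_code == 0, r2.output
    assert (tmp_path / "out" / "manifest.json").exists()
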
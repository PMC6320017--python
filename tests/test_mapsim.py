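"""Simulator, classification, congruence report, file I/O and CLI."""

import json

import pytest
from click.testing import CliRunner

from bucketlcs import (
    BucketOrder,
    SimulationConfig,
    classify_markers,
    congruence_report,
    lcs_length,
    read_bucket_order,
    read_map_table,
    simulate_pair,
    write_bucket_order,
    write_map_table,
)
from bucketlcs.cli import main
from bucketlcs.report import LABELS

import pandas as pd


class TestSimulator:
    def test_protocol_shape(self):
        a, b = simulate_pair(SimulationConfig(n_markers=100, seed=5))
        assert len(a) == len(b) == 100
        assert a.n_buckets <= 10
        assert a.domain == b.domain

    def test_determinism(self):
        cfg = SimulationConfig(n_markers=1000, seed=42)
        a1, b1 = simulate_pair(cfg)
        a2, b2 = simulate_pair(cfg)
        assert a1 == a2 and b1 == b2
        assert a1.to_text() == a2.to_text() and b1.to_text() == b2.to_text()

    def test_zero_perturbation_is_identity(self):
        cfg = SimulationConfig(
            n_markers=200,
            bucket_swap_fraction=0.0,
            marker_move_fraction=0.0,
            seed=9,
        )
        a, b = simulate_pair(cfg)
        assert a == b
        assert lcs_length(a, b) == 200

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_markers=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_markers=10, n_buckets=11)
        with pytest.raises(ValueError):
            SimulationConfig(n_markers=10, bucket_swap_fraction=1.5)

    def test_perturbation_breaks_some_collinearity(self):
        for seed in (1, 2, 3):
            a, b = simulate_pair(SimulationConfig(n_markers=500, seed=seed))
            report = congruence_report(a, b)
            assert report["lcs_ratio"] < 1.0


class TestClassification:
    def test_worked_example(self, pi1, pi2):
        c = classify_markers(pi1, pi2, mode="lcis")
        assert c.group("in_lcs") == frozenset("abl")
        assert c.group("conflicting") == frozenset("cdefgh")
        assert c.group("only_map1") == frozenset("kij")
        assert c.group("only_map2") == frozenset("mqrnop")

    def test_identical_maps_all_in_lcs(self, pi1):
        c = classify_markers(pi1, pi1, mode="lcs")
        assert c.group("in_lcs") == pi1.domain

    def test_disjoint_maps(self):
        a = BucketOrder([["a"]])
        b = BucketOrder([["b"]])
        c = classify_markers(a, b, mode="lcs")
        assert not c.group("in_lcs") and not c.group("conflicting")

    def test_labels_partition_the_union(self, pi1, pi2):
        c = classify_markers(pi1, pi2, mode="lcs")
        assert set(c.labels) == pi1.domain | pi2.domain
        assert set(c.labels.values()) <= set(LABELS)

    def test_rejects_unknown_mode(self, pi1, pi2):
        with pytest.raises(ValueError):
            classify_markers(pi1, pi2, mode="nope")


class TestReport:
    def test_worked_example(self, pi1, pi2):
        r = congruence_report(pi1, pi2)
        assert r["lcs_length"] == 4
        assert r["lcis_length"] == 3
        assert r["n_shared"] == 9
        assert r["n_homogenized_buckets"] == 6

    def test_identical_maps(self, pi1):
        r = congruence_report(pi1, pi1)
        assert r["lcs_length"] == len(pi1)
        assert r["lcs_ratio"] == 1.0

    def test_ratio_bounds(self, pi1, pi2):
        r = congruence_report(pi1, pi2)
        assert 0.0 <= r["lcis_ratio"] <= r["lcs_ratio"] <= 1.0
        assert r["lcis_length"] <= r["lcs_length"] <= r["n_shared"]


class TestIO:
    def test_map_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {
                "marker": ["a", "b", "c"],
                "chromosome": ["1A", "1A", "1A"],
                "position": [0.0, 1.5, 1.5],
            }
        )
        p = tmp_path / "map.tsv"
        write_map_table(df, p)
        back = read_map_table(p)
        pd.testing.assert_frame_equal(back, df)

    def test_bucket_order_roundtrip(self, tmp_path, pi2):
        p = tmp_path / "order.txt"
        write_bucket_order(pi2, p)
        assert read_bucket_order(p) == pi2


class TestCli:
    def _write_maps(self, tmp_path, pi1, pi2):
        f1, f2 = tmp_path / "m1.txt", tmp_path / "m2.txt"
        write_bucket_order(pi1, f1)
        write_bucket_order(pi2, f2)
        return str(f1), str(f2)

    def test_compare(self, tmp_path, pi1, pi2):
        f1, f2 = self._write_maps(tmp_path, pi1, pi2)
        report = tmp_path / "report.json"
        classes = tmp_path / "classes.tsv"
        result = CliRunner().invoke(
            main,
            [
                "compare", "--map1", f1, "--map2", f2, "--format", "buckets",
                "--mode", "lcis", "--algo", "dp", "--count", "--enumerate",
                "5", "--out-report", str(report), "--out-classes",
                str(classes),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "lcis_length\t3" in result.output
        assert "lcis\ta,b,l" in result.output
        assert "n_optimal\t1" in result.output
        data = json.loads(report.read_text())
        assert data["lcs_length"] == 4
        table = pd.read_csv(classes, sep="\t")
        assert set(table.columns) == {"marker", "label"}

    def test_compare_tsv_input(self, tmp_path):
        df = pd.DataFrame(
            {"marker": ["a", "b", "c"], "position": [1.0, 1.0, 2.0]}
        )
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_map_table(df, f1)
        write_map_table(df, f2)
        result = CliRunner().invoke(
            main, ["compare", "--map1", str(f1), "--map2", str(f2)]
        )
        assert result.exit_code == 0, result.output
        assert "lcs_length\t3" in result.output

    def test_homogenize(self, tmp_path, pi1, pi2):
        f1, f2 = self._write_maps(tmp_path, pi1, pi2)
        o1, o2 = tmp_path / "h1.txt", tmp_path / "h2.txt"
        result = CliRunner().invoke(
            main,
            [
                "homogenize", "--map1", f1, "--map2", f2, "--format",
                "buckets", "--out1", str(o1), "--out2", str(o2),
            ],
        )
        assert result.exit_code == 0, result.output
        assert read_bucket_order(o1).buckets == (
            ("a",), ("b",), ("c",), ("l",), ("d", "e", "f"), ("g", "h"),
        )

    def test_simulate(self, tmp_path):
        o1, o2 = tmp_path / "s1.txt", tmp_path / "s2.txt"
        args = [
            "simulate", "--n", "100", "--seed", "3",
            "--out1", str(o1), "--out2", str(o2),
        ]
        result = CliRunner().invoke(main, args)
        assert result.exit_code == 0, result.output
        a = read_bucket_order(o1)
        b = read_bucket_order(o2)
        assert len(a) == len(b) == 100
        # re-running with the same seed reproduces the files
        first = o1.read_text()
        CliRunner().invoke(main, args)
        assert o1.read_text() == first

    def test_count_requires_dp(self, tmp_path, pi1, pi2):
        f1, f2 = self._write_maps(tmp_path, pi1, pi2)
        result = CliRunner().invoke(
            main,
            ["compare", "--map1", f1, "--map2", f2, "--format", "buckets",
             "--count"],
        )
        assert result.exit_code != 0
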
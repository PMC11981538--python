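import filecmp

import pytest

from trophoweb import (
    AnalysisConfig,
    FoodWebError,
    Perturbation,
    SyntheticWebSpec,
    compare_webs,
    environmental_changes,
    global_metrics,
    percent_change,
    run_full_analysis,
    symmetrize,
    trophic_levels,
)
from trophoweb.compare import classify_tl_shift, parse_bounded
from trophoweb.datasets import (
    load_aggregation_scheme,
    load_environment_table,
    load_functional_groups,
    load_global_metrics_table,
)
from trophoweb.synthetic import generate_niche_web


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (15.33, 19.28, 25.77),
            (1.10, 1.20, 9.09),
            (24.16, 25.69, 6.33),
            (35.19, 36.10, 2.59),
            (35.92, 37.00, 3.01),
            ("<1.00", 54.00, 5300.0),
            (7.5, 7.5, 0.0),
        ],
    )
    def test_examples(self, pre, post, expected):
        assert round(percent_change(pre, post), 2) == pytest.approx(expected)

    def test_bound_parsing(self):
        assert parse_bounded("<1.00") == 1.0
        assert parse_bounded(" 2.5 ") == 2.5

    def test_zero_baseline_rejected(self):
        with pytest.raises(FoodWebError):
            percent_change(0.0, 1.0)

    def test_environmental_table_recomputes_printed_changes(self):
        table = environmental_changes(load_environment_table())
        assert list(table["percent_change"]) == list(
            table["printed_percent_change"].astype(float)
        )


class TestPackagedTables:
    def test_global_metrics_table_shape(self):
        df = load_global_metrics_table()
        assert list(df.columns) == ["metric", "PRE", "POST"]
        assert len(df) == 6

    def test_functional_group_scheme_is_many_to_one(self):
        df = load_functional_groups()
        scheme = load_aggregation_scheme()
        assert len(scheme.mapping) == len(df)
        # the mullet complex merges four taxa into one group
        mullets = [t for t, g in scheme.mapping.items() if g == "Mugil spp."]
        assert len(mullets) == 4

    def test_period_schemes_reproduce_aggregated_node_counts(self):
        # 41 PRE taxa collapse onto exactly 23 functional groups, matching
        # the published raw and aggregated node counts for that period
        pre = load_aggregation_scheme("PRE")
        assert len(pre.mapping) == 41
        assert len(set(pre.mapping.values())) == 23
        post = load_aggregation_scheme("POST")
        assert len(set(post.mapping.values())) == 23

    def test_period_filtered_schemes(self):
        pre = load_aggregation_scheme("PRE")
        post = load_aggregation_scheme("POST")
        assert "Ruppia cirrhosa" in pre.mapping and "Ruppia cirrhosa" not in post.mapping
        assert "Diatom" in post.mapping and "Diatom" not in pre.mapping
        # groups present in both periods
        assert pre.mapping["Detritus"] == post.mapping["Detritus"] == "Detritus"


class TestCompareWebs:
    def test_identical_webs_all_no_change(self):
        web = generate_niche_web(SyntheticWebSpec(n_nodes=15, seed=3))
        gm = global_metrics(symmetrize(web))
        tl = trophic_levels(web)
        report = compare_webs(web, web, gm, gm, tl, tl)
        assert report.n_shared == web.n_nodes
        assert (report.shared_nodes["delta"] == 0).all()
        assert (report.shared_nodes["classification"] == "no change").all()

    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (2.50, 2.17, "decrease"),
            (3.39, 3.64, "increase"),
            (2.004, 2.001, "no change"),  # equal at 2 dp
        ],
    )
    def test_tl_shift_classification(self, pre, post, expected):
        assert classify_tl_shift(round(pre, 2), round(post, 2)) == expected

    def test_disturbed_pair_shared_nodes_subset(self):
        spec = SyntheticWebSpec(seed=9)
        base, pert = __import__("trophoweb").generate_disturbance_pair(
            spec, Perturbation(0.5, 0.2)
        )
        gm_a = global_metrics(symmetrize(base))
        gm_b = global_metrics(symmetrize(pert))
        report = compare_webs(base, pert, gm_a, gm_b,
                              trophic_levels(base), trophic_levels(pert))
        shared = set(report.shared_nodes["node"])
        assert shared <= set(base.nodes) & set(pert.nodes)


class TestRunFullAnalysis:
    def test_synthetic_pair_outputs_and_rerun_byte_identical(self, tmp_path):
        def config(out):
            return AnalysisConfig(
                synthetic=SyntheticWebSpec(n_nodes=18, seed=7),
                perturbation=Perturbation(0.5, 0.2),
                out_dir=out,
            )

        out1 = run_full_analysis(config(tmp_path / "run1"))
        out2 = run_full_analysis(config(tmp_path / "run2"))
        names = sorted(p.name for p in out1.iterdir())
        assert "pre_global_metrics.csv" in names
        assert "post_global_metrics.csv" in names
        assert "comparison_shared_nodes.csv" in names
        assert "comparison_report.txt" in names
        assert "run_log.txt" in names
        for name in names:
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name

    def test_single_web_run_omits_comparison(self, tmp_path):
        out = run_full_analysis(
            AnalysisConfig(
                synthetic=SyntheticWebSpec(n_nodes=15, seed=4),
                out_dir=tmp_path / "single",
            )
        )
        names = {p.name for p in out.iterdir()}
        assert "pre_global_metrics.csv" in names
        assert "pre_trophic_levels.csv" in names
        assert not any(n.startswith("comparison") for n in names)

    def test_file_inputs_roundtrip_through_pipeline(self, tmp_path):
        from trophoweb import write_web

        web = generate_niche_web(SyntheticWebSpec(n_nodes=15, seed=2))
        write_web(web, tmp_path / "e.csv", tmp_path / "a.csv")
        out = run_full_analysis(
            AnalysisConfig(
                edges=tmp_path / "e.csv",
                attrs=tmp_path / "a.csv",
                out_dir=tmp_path / "out",
            )
        )
        assert (out / "pre_node_metrics.csv").exists()

    def test_stage_errors_carry_stage_name(self, tmp_path):
        from trophoweb import NodeAttributes, FoodWeb, write_web

        # two disconnected dyads fail analysis-ready validation in stage 'pre'
        web = FoodWeb(
            [NodeAttributes(name=n, category="animal") for n in "abcd"],
            [("a", "b"), ("c", "d")],
        )
        write_web(web, tmp_path / "e.csv", tmp_path / "a.csv")
        with pytest.raises(FoodWebError, match="stage 'pre'"):
            run_full_analysis(
                AnalysisConfig(
                    edges=tmp_path / "e.csv",
                    attrs=tmp_path / "a.csv",
                    out_dir=tmp_path / "out",
                )
            )
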
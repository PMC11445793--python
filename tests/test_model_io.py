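"""Model/Results surface, file I/O, plotting and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dreamchart import (
    DreamEmotionModel,
    DreamReport,
    PipelineConfig,
    plot_chart,
    read_reports,
)
from dreamchart.cli import main
from dreamchart.io import read_externals
from dreamchart.synthetic import generate_cohort, toy_lexicon


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(n_reports=8, seed=15)


@pytest.fixture(scope="module")
def results(cohort):
    reports, _, _ = cohort
    return DreamEmotionModel(reports, toy_lexicon()).fit()


class TestModel:
    def test_duplicate_report_ids_rejected(self):
        reports = [DreamReport("a", "happy day"), DreamReport("a", "sad night")]
        with pytest.raises(ValueError, match="unique"):
            DreamEmotionModel(reports, toy_lexicon())

    def test_indicator_table_shape(self, results):
        ind = results.indicators
        assert list(ind.columns) == [
            "report_id", "total_peaks", "total_troughs", "pei", "nei", "oei",
            "emotion_gradient",
        ]
        assert len(ind) == 8

    def test_unscoreable_report_skipped_with_warning(self):
        reports = [DreamReport("ok", "posaampj " * 40), DreamReport("bad", "1234 5678")]
        with pytest.warns(UserWarning, match="skipping"):
            res = DreamEmotionModel(reports, toy_lexicon()).fit()
        assert res.report_ids == ["ok"]
        assert res.skipped[0][0] == "bad"

    def test_from_dataframe(self):
        frame = pd.DataFrame({"id": ["a", "b"], "text": ["posaampj " * 35, "negaampj " * 35]})
        res = DreamEmotionModel.from_dataframe(frame, toy_lexicon()).fit()
        assert res.report_ids == ["a", "b"]

    def test_summary_mentions_counts(self, results):
        text = results.summary()
        assert "reports analyzed: 8" in text
        assert "mean word count" in text

    def test_determinism(self, cohort):
        reports, _, _ = cohort
        a = DreamEmotionModel(reports, toy_lexicon()).fit().indicators
        b = DreamEmotionModel(reports, toy_lexicon()).fit().indicators
        assert a.equals(b)


class TestExportRoundTrip:
    def test_csv_outputs(self, results, tmp_path):
        paths = results.to_csv(tmp_path)
        for key in ("indicators", "charts", "segments", "trends", "config"):
            assert paths[key].exists()
        ind = pd.read_csv(paths["indicators"])
        assert len(ind) == 8

    def test_chart_csv_reimport_reproduces_indicators(self, results, tmp_path):
        """Segmenting a chart re-read from its CSV export yields identical
        intensities."""
        from dreamchart import DreamChart, compute_indicators, segment_chart

        paths = results.to_csv(tmp_path)
        charts = pd.read_csv(paths["charts"])
        ind = pd.read_csv(paths["indicators"]).set_index("report_id")
        for rid, group in charts.groupby("report_id"):
            chart = DreamChart(
                report_id=str(rid),
                x=group.x.to_numpy(),
                y=group.y.to_numpy(),
                n_windows=len(group),
                raw_length=len(group) + 29,
            )
            re_ind = compute_indicators(chart, segment_chart(chart))
            assert re_ind.pei == pytest.approx(ind.loc[rid, "pei"], abs=1e-9)
            assert re_ind.nei == pytest.approx(ind.loc[rid, "nei"], abs=1e-9)
            assert re_ind.total_peaks == ind.loc[rid, "total_peaks"]


class TestReadReports:
    def test_txt_directory(self, tmp_path):
        (tmp_path / "d1.txt").write_text("a happy dream")
        (tmp_path / "d2.txt").write_text("a scary dream")
        reports = read_reports(tmp_path)
        assert [r.report_id for r in reports] == ["d1", "d2"]

    def test_csv(self, tmp_path):
        path = tmp_path / "reports.csv"
        pd.DataFrame({"id": ["x"], "text": ["very happy"]}).to_csv(path, index=False)
        (report,) = read_reports(path)
        assert report.report_id == "x"

    def test_jsonl(self, tmp_path):
        path = tmp_path / "reports.jsonl"
        path.write_text('{"id": "j1", "text": "calm water"}\n{"id": "j2", "text": "dark hall"}\n')
        reports = read_reports(path)
        assert len(reports) == 2

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"name": ["x"], "body": ["y"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="columns"):
            read_reports(path)

    def test_externals_need_report_id(self, tmp_path):
        path = tmp_path / "ext.csv"
        pd.DataFrame({"id": ["x"], "rem": [20.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="report_id"):
            read_externals(path)


class TestPlotting:
    def test_shaded_regions_match_segments(self, results):
        import matplotlib.pyplot as plt

        rid = results.report_ids[0]
        a = results[rid]
        ax = plot_chart(a.chart, a.segmentation, a.trend)
        fills = [c for c in ax.collections]
        assert len(fills) == len(a.segmentation.segments)
        plt.close(ax.figure)

    def test_flat_chart_has_no_shading(self, tmp_path):
        import matplotlib.pyplot as plt

        from dreamchart import DreamChart, segment_chart

        chart = DreamChart("flat", np.arange(1, 11, dtype=float), np.zeros(10), 10, 39)
        ax = plot_chart(chart, segment_chart(chart), savepath=tmp_path / "flat.svg")
        assert len(ax.collections) == 0
        assert (tmp_path / "flat.svg").exists()
        plt.close(ax.figure)


class TestCli:
    def write_cohort(self, tmp_path):
        reports, ext, _ = generate_cohort(n_reports=5, seed=2)
        rpath = tmp_path / "reports.csv"
        pd.DataFrame([{"id": r.report_id, "text": r.text} for r in reports]).to_csv(
            rpath, index=False
        )
        epath = tmp_path / "externals.csv"
        ext.to_csv(epath, index=False)
        return rpath, epath

    def toy_lexicon_file(self, tmp_path):
        lex = toy_lexicon()
        path = tmp_path / "toy.tsv"
        path.write_text("".join(f"{t}\t{v}\t0.5\n" for t, v in lex.entries.items()))
        return path

    def test_indicators_command(self, tmp_path):
        rpath, _ = self.write_cohort(tmp_path)
        lpath = self.toy_lexicon_file(tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["indicators", str(rpath), "--lexicon", str(lpath),
             "--outdir", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        ind = pd.read_csv(tmp_path / "out" / "indicators.csv")
        assert len(ind) == 5

    def test_correlate_command(self, tmp_path):
        rpath, epath = self.write_cohort(tmp_path)
        lpath = self.toy_lexicon_file(tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["correlate", str(rpath), str(epath), "--lexicon", str(lpath),
             "--outdir", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "correlations.csv").exists()

    def test_simulate_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["simulate", "--n-reports", "4", "--seed", "1",
                   "--outdir", str(tmp_path / "sim")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sim" / "reports.csv").exists()
        assert (tmp_path / "sim" / "ground_truth.json").exists()

    def test_score_command(self, tmp_path):
        rpath, _ = self.write_cohort(tmp_path)
        lpath = self.toy_lexicon_file(tmp_path)
        out = tmp_path / "valences.csv"
        runner = CliRunner()
        result = runner.invoke(
            main, ["score", str(rpath), "--lexicon", str(lpath), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(out)
        assert {"report_id", "position", "token", "valence"} <= set(frame.columns)
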
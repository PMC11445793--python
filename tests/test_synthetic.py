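"""Synthetic report generator and its ground-truth guarantees."""

import numpy as np
import pytest

from dreamchart import DreamEmotionModel, analyze_report
from dreamchart.synthetic import (
    EmotionScript,
    ExternalSpec,
    Run,
    generate_cohort,
    generate_report,
    oracle_intensities,
    toy_lexicon,
)


class TestGenerateReport:
    def test_reproducibility_is_byte_identical(self):
        script = EmotionScript(
            plan=(Run("neutral", 35), Run("positive", 10, 0.5), Run("neutral", 35)),
            seed=42,
        )
        r1, t1 = generate_report(script)
        r2, t2 = generate_report(script)
        assert r1.text == r2.text
        assert np.array_equal(t1["values"], t2["values"])

    def test_neutral_script_is_all_zero(self):
        report, truth = generate_report(EmotionScript(plan=(Run("neutral", 50),)))
        a = analyze_report(report, toy_lexicon())
        assert np.all(a.series.values == 0.0)
        assert a.indicators.total_peaks == 0
        assert a.indicators.total_troughs == 0
        assert a.indicators.oei == 0.0
        assert a.indicators.emotion_gradient == 0.0

    def test_single_planted_peak_recovered(self):
        script = EmotionScript(
            plan=(Run("neutral", 35), Run("positive", 10, 0.5), Run("neutral", 35)),
            seed=7,
        )
        report, truth = generate_report(script)
        assert truth["n_peaks"] == 1 and truth["n_troughs"] == 0
        a = analyze_report(report, toy_lexicon())
        assert a.indicators.total_peaks == 1
        assert a.indicators.total_troughs == 0

    def test_mirrored_script_gives_mirrored_indicators(self):
        plan_pos = (Run("neutral", 32), Run("positive", 12, 0.6), Run("neutral", 32),
                    Run("negative", 12, 0.6), Run("neutral", 32))
        plan_neg = tuple(
            Run({"positive": "negative", "negative": "positive"}.get(r.kind, r.kind),
                r.length, r.amplitude)
            for r in plan_pos
        )
        a = analyze_report(generate_report(EmotionScript(plan_pos, seed=5))[0], toy_lexicon())
        b = analyze_report(generate_report(EmotionScript(plan_neg, seed=5))[0], toy_lexicon())
        assert a.indicators.pei == pytest.approx(abs(b.indicators.nei), abs=1e-9)
        assert abs(a.indicators.nei) == pytest.approx(b.indicators.pei, abs=1e-9)
        assert a.indicators.emotion_gradient == pytest.approx(
            -b.indicators.emotion_gradient, abs=1e-9
        )

    def test_unachievable_amplitude_is_error(self):
        with pytest.raises(ValueError, match="amplitude"):
            generate_report(EmotionScript(plan=(Run("positive", 5, 0.512),)))

    def test_ground_truth_matches_pipeline(self):
        """Pipeline results on a generated report equal the stored oracle
        series and chart exactly, and areas to 1e-9."""
        script = EmotionScript(
            plan=(Run("negative", 15, 0.4), Run("neutral", 40),
                  Run("positive", 20, 0.8), Run("neutral", 10)),
            seed=11,
        )
        report, truth = generate_report(script)
        a = analyze_report(report, toy_lexicon())
        assert list(a.series.tokens) == truth["tokens"]
        assert np.array_equal(a.series.values, truth["values"])
        assert np.allclose(a.chart.y, truth["chart_y"], atol=1e-12)
        assert a.indicators.total_peaks == truth["n_peaks"]
        assert a.indicators.total_troughs == truth["n_troughs"]
        pei, nei = oracle_intensities(truth["chart_y"])
        assert a.indicators.pei == pytest.approx(pei, abs=1e-9)
        assert a.indicators.nei == pytest.approx(nei, abs=1e-9)


class TestGenerateCohort:
    def test_shapes_and_reproducibility(self):
        reports, ext, truth = generate_cohort(n_reports=14, seed=3)
        again, ext2, _ = generate_cohort(n_reports=14, seed=3)
        assert len(reports) == 14
        assert ext.shape[0] == 14
        assert [r.text for r in reports] == [r.text for r in again]
        assert ext.equals(ext2)

    def test_word_counts_within_emulated_range(self):
        reports, _, truth = generate_cohort(n_reports=20, seed=9)
        counts = [len(t["tokens"]) for t in truth["reports"].values()]
        assert min(counts) >= 46 and max(counts) <= 202

    def test_min_cohort_size(self):
        with pytest.raises(ValueError):
            generate_cohort(n_reports=2)

    def test_degenerate_externals_model_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_cohort(
                n_reports=5,
                seed=0,
                externals_model={"flat": ExternalSpec("oei", slope=0.0, sigma=0.0)},
            )

    def test_noiseless_link_gives_perfect_correlation(self):
        reports, ext, truth = generate_cohort(
            n_reports=10,
            seed=4,
            externals_model={"mirror": ExternalSpec("oei", slope=2.0, sigma=0.0)},
        )
        res = DreamEmotionModel(reports, toy_lexicon()).fit()
        analysis = res.correlate(ext)
        row = analysis.results[
            (analysis.results.indicator == "oei") & (analysis.results.variable == "mirror")
        ]
        assert row.coefficient.iloc[0] == pytest.approx(1.0)

    def test_pipeline_matches_cohort_truth(self):
        reports, _, truth = generate_cohort(n_reports=8, seed=21)
        res = DreamEmotionModel(reports, toy_lexicon()).fit()
        pipeline = res.indicators.set_index("report_id")
        oracle = truth["indicators"].set_index("report_id")
        assert (pipeline["total_peaks"] == oracle["total_peaks"]).all()
        assert (pipeline["total_troughs"] == oracle["total_troughs"]).all()
        assert np.allclose(pipeline["pei"], oracle["pei"], atol=1e-9)
        assert np.allclose(pipeline["nei"], oracle["nei"], atol=1e-9)
        assert np.allclose(pipeline["oei"], oracle["oei"], atol=1e-9)
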
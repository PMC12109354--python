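import numpy as np
import pytest
from click.testing import CliRunner
from scipy import stats as spstats

from dtw100 import RunConfig, ValidationError, paired_t_test, summarize
from dtw100.stats_report import cli, main, run_pipeline, run_study
from dtw100.synthetic_data import write_study

SMALL_CFG = dict(rate=500.0, epoch_seconds=1.0, baseline_window_seconds=0.5)
SMALL_STUDY = dict(n_reference=3, n_subjects=2, n_trials=4, rate=500.0, epoch_seconds=1.0)


class TestSummarize:
    def test_textbook_values(self):
        assert summarize([1.0, 2.0, 3.0]) == (2.0, 1.0)

    def test_constant_input(self):
        mean, sd = summarize([4.5] * 6)
        assert (mean, sd) == (4.5, 0.0)

    def test_large_sample_recovers_parameters(self, rng):
        draws = rng.normal(50.0, 5.0, size=10_000)
        mean, sd = summarize(draws)
        assert abs(mean - 50.0) <= 0.2
        assert abs(sd - 5.0) <= 0.2

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            summarize([1.0])


class TestPairedTTest:
    def test_matches_closed_form_to_six_decimals(self):
        pre = [48.0, 50.0, 52.0, 47.0, 49.0]
        post = [60.0, 63.0, 59.0, 61.0, 62.0]
        diff = np.subtract(post, pre)
        t_expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * spstats.t.sf(abs(t_expected), df=4)
        comp = paired_t_test(pre, post)
        assert comp.t_statistic == pytest.approx(t_expected, abs=1e-6)
        assert comp.p_value == pytest.approx(p_expected, abs=1e-6)
        assert comp.n == 5
        assert comp.mean_increase == pytest.approx(diff.mean())

    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="zero variance"):
            comp = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert comp.t_statistic == 0.0
        assert comp.p_value == 1.0

    def test_constant_shift_degenerate(self):
        with pytest.warns(UserWarning, match="zero variance"):
            comp = paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert comp.p_value == 0.0
        assert comp.t_statistic == np.inf
        assert comp.mean_increase == 1.0

    def test_validation(self):
        with pytest.raises(ValidationError):
            paired_t_test([1.0, 2.0], [1.0])
        with pytest.raises(ValidationError):
            paired_t_test([1.0], [2.0])


class TestRunStudy:
    def test_bookkeeping_counts(self, small_cfg, small_study):
        ref, samples = small_study
        result = run_study(small_cfg, ref, samples)
        assert len(result.scorecards) == 2 * len(samples)  # both domains
        assert {c.domain for c in result.scorecards} == {"time", "frequency"}
        assert len(result.comparisons) == 2
        assert set(result.coefficients) == {"time", "frequency"}
        for comp in result.comparisons:
            assert comp.n == 2
            np.testing.assert_allclose(
                comp.mean_increase, np.mean(np.subtract(comp.post_scores, comp.pre_scores))
            )

    def test_sample_order_does_not_matter(self, small_cfg, small_study):
        ref, samples = small_study
        a = run_study(small_cfg, ref, samples)
        b = run_study(small_cfg, ref, list(reversed(samples)))
        assert a.scorecards == b.scorecards
        assert a.comparisons == b.comparisons

    def test_pinned_coefficient_is_used_everywhere(self, small_study):
        ref, samples = small_study
        cfg = RunConfig(coefficient_A=1e-3, **SMALL_CFG)
        result = run_study(cfg, ref, samples)
        assert result.coefficients == {"time": 1e-3, "frequency": 1e-3}
        assert all(c.coefficient_A == 1e-3 for c in result.scorecards)


class TestRunPipeline:
    def test_end_to_end_and_determinism(self, tmp_path):
        manifest = write_study(tmp_path / "study", seed=21, **SMALL_STUDY)
        cfg = RunConfig(**SMALL_CFG)
        out1, out2 = tmp_path / "out1", tmp_path / "out2"
        result = run_pipeline(cfg, manifest, out1)
        assert len(result.scorecards) == 2 * 2 * 2  # 2 subjects x 2 phases x 2 domains
        assert len(result.comparisons) == 2
        run_pipeline(cfg, manifest, out2)
        assert (out1 / "scores.csv").read_bytes() == (out2 / "scores.csv").read_bytes()
        report = (out1 / "report.txt").read_text()
        assert "time domain" in report and "frequency domain" in report

    def test_reference_only_manifest(self, tmp_path):
        manifest = write_study(tmp_path / "study", seed=21, **SMALL_STUDY)
        import yaml

        data = yaml.safe_load(manifest.read_text())
        data["subjects"] = []
        lean = manifest.parent / "ref_only.yaml"
        lean.write_text(yaml.safe_dump(data))
        result = run_pipeline(RunConfig(**SMALL_CFG), lean, tmp_path / "out")
        assert result.scorecards == []
        assert result.comparisons == []
        assert "reference only" in (tmp_path / "out" / "report.txt").read_text()

    def test_malformed_manifest_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("just a string")
        with pytest.raises(ValidationError):
            run_pipeline(RunConfig(**SMALL_CFG), bad, tmp_path / "out")


class TestCli:
    def test_simulate_score_compare_round_trip(self, tmp_path):
        runner = CliRunner()
        study = tmp_path / "study"
        res = runner.invoke(cli, [
            "simulate", "--out-dir", str(study), "--seed", "21",
            "--n-reference", "3", "--n-subjects", "2", "--n-trials", "4",
            "--rate", "500", "--epoch-seconds", "1",
        ])
        assert res.exit_code == 0, res.output
        assert (study / "manifest.yaml").exists()

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("rate: 500\nepoch_seconds: 1\nbaseline_window_seconds: 0.5\n")
        out = tmp_path / "out"
        res = runner.invoke(cli, [
            "report", "--manifest", str(study / "manifest.yaml"),
            "--config", str(cfg), "--out-dir", str(out),
        ])
        assert res.exit_code == 0, res.output
        assert "composite" in res.output

        res = runner.invoke(cli, ["compare", "--scores", str(out / "scores.csv")])
        assert res.exit_code == 0, res.output
        assert "time:" in res.output and "frequency:" in res.output

    def test_exit_codes(self, tmp_path):
        # usage error -> 2
        assert main(["score", "--out-dir", str(tmp_path)]) == 2
        # validation error -> 2
        bad = tmp_path / "cfg.yaml"
        bad.write_text("composite_weight: 7\n")
        study = tmp_path / "study"
        write_study(study, seed=1, **SMALL_STUDY)
        assert main([
            "score", "--manifest", str(study / "manifest.yaml"),
            "--config", str(bad), "--out-dir", str(tmp_path / "o"),
        ]) == 2
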
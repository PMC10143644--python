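import hashlib

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from redgepheno.stats_pipeline import (
    AnovaResult,
    DegenerateGroupsError,
    PipelineConfig,
    anova_one_way,
    hindex_stress_trial,
    phase_table,
    regress_oi_vs_hindex,
    run_pipeline,
)
from redgepheno.synthetic_scene import ExperimentDesign, SceneConfig, simulate_experiment


def sums_of_squares_f(groups):
    """Direct textbook oracle: F = (SSB/(k-1)) / (SSW/(N-k))."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_vals)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = scipy.stats.f.sf(f, k - 1, n - k)
    return f, p


class TestAnovaOneWay:
    def test_identical_groups_f_zero_p_one(self):
        res = anova_one_way([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_constant_equal_groups_degenerate(self):
        res = anova_one_way([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.degenerate
        assert np.isnan(res.f)

    def test_constant_separated_groups_p_zero_flagged(self):
        res = anova_one_way([[1.0, 1.0], [2.0, 2.0]])
        assert res.zero_within_variance
        assert res.p == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=6) for _ in range(2)]
            res = anova_one_way(groups)
            f, p = sums_of_squares_f(groups)
            assert res.f == pytest.approx(f, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-10)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(DegenerateGroupsError):
            anova_one_way([[1.0, 2.0]])
        with pytest.raises(DegenerateGroupsError):
            anova_one_way([[1.0], [2.0, 3.0]])
        with pytest.raises(DegenerateGroupsError):
            anova_one_way([[1.0, np.nan], [2.0, 3.0]])


def synthetic_records(effect_by_phase, n=6, seed=0, genotypes=("g1",)):
    """Records with a controlled stressed-vs-control H-index offset per phase."""
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in genotypes:
        for phase, effect in effect_by_phase.items():
            for treatment in ("control", "stressed"):
                shift = -effect if treatment == "stressed" else 0.0
                for rep in range(n):
                    rows.append(
                        {
                            "genotype": genotype,
                            "treatment": treatment,
                            "phase": phase,
                            "h_index": 0.009 + shift + rng.normal(0, 0.0006),
                            "psa": 200 + rng.normal(0, 10),
                            "hue": 110 + rng.normal(0, 3),
                            "si": np.clip(0.1 + rng.normal(0, 0.02), 0, 1),
                        }
                    )
    return pd.DataFrame(rows)


class TestPhaseTable:
    def test_full_grid_shape(self):
        records = synthetic_records(
            {p: 0.0 for p in ("I stress", "I recovery", "II stress", "II recovery")},
            genotypes=("g1", "g2", "g3", "g4"),
        )
        table = phase_table(records)
        assert len(table) == 4 * 4 * 4  # genotype × phase × index
        assert set(table.status) == {"ok"}

    def test_designed_effect_flagged_only_in_stress_phase(self):
        records = synthetic_records({"I stress": 0.004, "I recovery": 0.0}, seed=1)
        table = phase_table(records).set_index(["phase", "index"])
        assert table.loc[("I stress", "h_index"), "significant"].item()
        assert not table.loc[("I recovery", "h_index"), "significant"].item()

    def test_null_flag_rate_matches_alpha(self):
        """Type-I calibration: with no effect anywhere, the flag fraction
        over many seeds stays inside the binomial envelope of alpha."""
        flags = total = 0
        for seed in range(40):
            records = synthetic_records({"I stress": 0.0, "II stress": 0.0}, seed=seed)
            table = phase_table(records)
            flags += int(table.significant.sum())
            total += len(table)
        rate = flags / total  # total = 320 cells
        ci = 1.96 * np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) <= ci

    def test_missing_cell_reported(self):
        records = synthetic_records({"I stress": 0.0})
        records = records[
            ~((records.treatment == "stressed") & (records.phase == "I stress"))
        ]
        table = phase_table(records)
        assert table.status.str.startswith("missing").all()
        assert not table.significant.any()

    def test_bonferroni_tightens_threshold(self):
        records = synthetic_records({"I stress": 0.0008}, seed=3)
        plain = phase_table(records)
        strict = phase_table(records, bonferroni=True)
        assert strict.significant.sum() <= plain.significant.sum()


class TestRegression:
    def test_exact_line(self):
        df = pd.DataFrame({"h_index": [1.0, 2.0, 3.0, 4.0]})
        df["psa"] = 2 * df.h_index
        df["hue"] = -1.5 * df.h_index + 7
        df["si"] = 0.1 * df.h_index
        out = regress_oi_vs_hindex(df).set_index("oi")
        assert out.loc["psa", "slope"] == pytest.approx(2.0)
        assert out.loc["psa", "r_squared"] == pytest.approx(1.0)
        assert out.loc["hue", "slope"] == pytest.approx(-1.5)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame(
            {"h_index": [1.0] * 5, "psa": range(5), "hue": range(5), "si": range(5)}
        )
        with pytest.raises(ValueError, match="constant"):
            regress_oi_vs_hindex(df)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=30)
        y = 3.0 * x + rng.normal(size=30)
        df = pd.DataFrame({"h_index": x, "psa": y, "hue": y, "si": y})
        out = regress_oi_vs_hindex(df).set_index("oi")
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert out.loc["psa", "intercept"] == pytest.approx(beta[0], rel=1e-9)
        assert out.loc["psa", "slope"] == pytest.approx(beta[1], rel=1e-9)


class TestHindexStressTrial:
    def test_strong_effect_detected(self):
        res = hindex_stress_trial(0.3, seed=5)
        assert res.p < 0.05

    def test_returns_anova_result(self):
        assert isinstance(hindex_stress_trial(0.0, seed=1), AnovaResult)


@pytest.fixture(scope="module")
def tiny_experiment(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("exp")
    design = ExperimentDesign(
        genotypes=("770P", "Red Setter"),
        stress_effect=(0.45, 0.30),
        replicates=2,
        acquisitions=(
            ("2021-05-27", "baseline"),
            ("2021-06-02", "I stress"),
            ("2021-06-08", "I recovery"),
        ),
        seed=13,
    )
    config = SceneConfig(frame_rows=48, frame_cols=48, panel_roi=(0, 0, 8, 8), seed=13)
    simulate_experiment(design, config, outdir)
    return outdir


class TestRunPipeline:
    def test_smoke_all_outputs_emitted(self, tiny_experiment, tmp_path):
        cfg = PipelineConfig(panel_roi=(0, 0, 8, 8))
        result = run_pipeline(tiny_experiment / "manifest.csv", cfg, outdir=tmp_path / "r")
        assert not result["failures"]
        assert len(result["indices"]) == 2 * 2 * 2 * 3  # genotype×treatment×rep×date
        for name in ("indices.csv", "phase_table.csv", "regressions.csv",
                     "reduction.json", "vpd_daily.csv", "run.log"):
            assert (tmp_path / "r" / name).exists()

    def test_rerun_is_byte_identical(self, tiny_experiment, tmp_path):
        cfg = PipelineConfig(panel_roi=(0, 0, 8, 8))
        digests = []
        for run_dir in ("a", "b"):
            run_pipeline(tiny_experiment / "manifest.csv", cfg, outdir=tmp_path / run_dir)
            digest = {
                name: hashlib.sha256((tmp_path / run_dir / name).read_bytes()).hexdigest()
                for name in ("indices.csv", "phase_table.csv", "regressions.csv",
                             "reduction.json")
            }
            digests.append(digest)
        assert digests[0] == digests[1]

    def test_aggregate_reduction_exceeds_80pct(self, tiny_experiment, tmp_path):
        cfg = PipelineConfig(panel_roi=(0, 0, 8, 8))
        result = run_pipeline(tiny_experiment / "manifest.csv", cfg, outdir=tmp_path / "r")
        assert result["reduction"].reduction_pct >= 80.0

    def test_per_file_failure_surfaced(self, tiny_experiment, tmp_path):
        manifest = pd.read_csv(tiny_experiment / "manifest.csv")
        manifest.loc[0, "cube_path"] = "cubes/does_not_exist.bsq"
        broken = tmp_path / "broken_manifest.csv"
        manifest.to_csv(broken, index=False)
        # manifest paths resolve relative to the manifest location
        import shutil

        for sub in ("cubes", "rgb"):
            shutil.copytree(tiny_experiment / sub, tmp_path / sub)
        for f in ("weights.csv", "weather.csv"):
            shutil.copy(tiny_experiment / f, tmp_path / f)
        cfg = PipelineConfig(panel_roi=(0, 0, 8, 8))
        result = run_pipeline(broken, cfg, outdir=tmp_path / "r")
        assert len(result["failures"]) == 1
        assert len(result["indices"]) == len(manifest) - 1


class TestPipelineConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(percentile=95.0, panel_roi=(0, 0, 8, 8), alpha=0.01)
        path = tmp_path / "cfg.yaml"
        path.write_text(cfg.to_yaml())
        assert PipelineConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("percentil: 96\n")
        with pytest.raises(ValueError, match="unknown"):
            PipelineConfig.from_yaml(path)
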
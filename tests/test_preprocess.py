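import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from methrisk import preprocess as pp
from methrisk import synthdata as sd


class TestExclusionLedger:
    def test_epic_probe_and_sample_chain(self):
        led = pp.exclusion_ledger(
            485_577,
            332,
            [
                ("SNP probes", 65, 0),
                ("prior cancer", 0, 2),
                ("pair not on same chip", 0, 2),
                ("missing >20% of samples", 36_655, 0),
                ("missing >5% of CpGs", 0, 3),
                ("incomplete pair", 0, 1),
                ("non-specific probes", 40_108, 0),
            ],
        )
        assert led.probes_remaining == 408_749
        assert led.samples_remaining == 324

    def test_nowac_probe_and_sample_chain(self):
        led = pp.exclusion_ledger(
            485_577,
            384,
            [
                ("SNP probes", 65, 0),
                ("removed after batch adjustment", 224, 0),
                ("missing covariates", 0, 9),
                ("missing >20% of samples", 28_459, 0),
                ("missing >5% of CpGs", 0, 14),
                ("incomplete pairs", 0, 23),
                ("non-specific probes", 40_417, 0),
            ],
        )
        assert led.probes_remaining == 416_412
        assert led.samples_remaining == 338

    def test_over_removal_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pp.exclusion_ledger(10, 4, [("too many", 11, 0)])

    def test_ledger_reconciles_with_matrix(self):
        m = pd.DataFrame(np.full((5, 4), 0.5))
        led = pp.exclusion_ledger(8, 6, [("qc", 3, 2)])
        led.check_against(m)
        with pytest.raises(ValueError):
            led.check_against(m.iloc[1:])


class TestMissingnessFilters:
    @pytest.fixture()
    def matrix(self):
        m = pd.DataFrame(np.full((4, 10), 0.5), index=list("abcd"))
        m.iloc[0, :3] = np.nan  # 30% missing -> removed at 0.20
        m.iloc[1, :2] = np.nan  # 20% missing -> kept (not strictly greater)
        return m

    def test_probe_filter_strict_inequality(self, matrix):
        out, removed = pp.filter_probes_by_missingness(matrix, 0.20)
        assert removed == ["a"]
        assert list(out.index) == ["b", "c", "d"]

    def test_complete_matrix_identity(self):
        m = pd.DataFrame(np.full((3, 4), 0.2))
        out, removed = pp.filter_probes_by_missingness(m, 0.2)
        assert removed == [] and out.shape == m.shape

    def test_sample_filter(self):
        m = pd.DataFrame(np.full((100, 3), 0.5), columns=["x", "y", "z"])
        m.iloc[:6, 0] = np.nan  # 6% -> removed
        m.iloc[:5, 1] = np.nan  # 5% exactly -> kept
        out, removed = pp.filter_samples_by_missingness(m, 0.05)
        assert removed == ["x"]
        assert list(out.columns) == ["y", "z"]


def test_drop_incomplete_pairs():
    sheet = pd.DataFrame(
        {
            "pair_id": ["p1", "p1", "p2", "p2"],
            "status": ["case", "control", "case", "control"],
            "age_at_draw": [50] * 4,
            "followup": [5.0] * 4,
        },
        index=["a", "b", "c", "d"],
    )
    m = pd.DataFrame(np.full((3, 3), 0.5), columns=["a", "b", "c"])  # "d" was removed upstream
    out_m, out_sheet = pp.drop_incomplete_pairs(m, sheet)
    assert list(out_m.columns) == ["a", "b"]
    assert set(out_sheet["pair_id"]) == {"p1"}
    # all pairs complete -> identity
    m2 = pd.DataFrame(np.full((3, 4), 0.5), columns=list("abcd"))
    out2, _ = pp.drop_incomplete_pairs(m2, sheet)
    assert list(out2.columns) == list("abcd")


class TestKnnImpute:
    def test_duplicate_probe_imputation(self):
        m = pd.DataFrame(np.full((12, 5), 0.5), index=[f"p{i}" for i in range(12)])
        m.loc["p0"] = [0.1, 0.2, 0.3, 0.4, 0.5]
        m.loc["p1"] = [0.1, 0.2, 0.3, 0.4, np.nan]
        out = pp.knn_impute(m, k=1)
        assert out.loc["p1"].iloc[-1] == pytest.approx(0.5)  # copied from its duplicate p0
        assert not out.isna().to_numpy().any()

    def test_complete_matrix_identity(self):
        m = pd.DataFrame(np.random.default_rng(0).random((6, 4)))
        pd.testing.assert_frame_equal(pp.knn_impute(m, k=2), m)

    def test_imputed_within_neighbour_range(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.random((20, 6)))
        m.iloc[3, 2] = np.nan
        k = 3
        out = pp.knn_impute(m, k=k)
        # brute-force nearest-neighbour oracle on the 20-probe fixture
        target = m.iloc[3].to_numpy()
        dists = []
        for i in range(20):
            if i == 3:
                continue
            other = m.iloc[i].to_numpy()
            mask = ~np.isnan(target) & ~np.isnan(other)
            d = np.sqrt(np.sum((target[mask] - other[mask]) ** 2) * len(target) / mask.sum())
            dists.append((d, i))
        nearest = [i for _, i in sorted(dists)[:k]]
        neigh_vals = m.iloc[nearest, 2].dropna()
        assert neigh_vals.min() - 1e-12 <= out.iloc[3, 2] <= neigh_vals.max() + 1e-12
        assert out.iloc[3, 2] == pytest.approx(neigh_vals.mean())

    def test_too_few_complete_neighbours(self):
        m = pd.DataFrame(np.random.default_rng(2).random((4, 4)))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete neighbour"):
            pp.knn_impute(m, k=10)


class TestCombat:
    @pytest.fixture()
    def batched(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0.0, 1.0, (50, 40))
        Y[:, 20:] += 1.0  # injected batch offset δ = 1
        m = pd.DataFrame(Y, index=[f"p{i}" for i in range(50)], columns=[f"s{j}" for j in range(40)])
        return m, np.array(["A"] * 20 + ["B"] * 20)

    def test_single_batch_identity(self):
        m = pd.DataFrame(np.random.default_rng(4).normal(size=(10, 8)))
        out = pp.combat_adjust(m, ["A"] * 8)
        pd.testing.assert_frame_equal(out, m)

    def test_injected_offset_removed(self, batched):
        m, batch = batched
        adj = pp.combat_adjust(m, batch)
        before = (m.iloc[:, 20:].mean(axis=1) - m.iloc[:, :20].mean(axis=1)).mean()
        after = (adj.iloc[:, 20:].mean(axis=1) - adj.iloc[:, :20].mean(axis=1)).mean()
        assert abs(after) < 0.05 * abs(before)

    def test_pooled_mean_preserved(self, batched):
        m, batch = batched
        adj = pp.combat_adjust(m, batch)
        assert np.abs(adj.mean(axis=1) - m.mean(axis=1)).max() < 1e-6

    def test_singleton_batch_rejected(self):
        m = pd.DataFrame(np.random.default_rng(5).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="single sample"):
            pp.combat_adjust(m, ["A", "A", "A", "A", "B"])

    def test_matches_bioconductor_sva(self, batched, tmp_path):
        """Independent cross-check against sva::ComBat on the same fixture."""
        m, batch = batched
        adj = pp.combat_adjust(m, batch)
        m.to_csv(tmp_path / "in.csv")
        adj.to_csv(tmp_path / "py.csv")
        pd.Series(batch).to_csv(tmp_path / "batch.csv")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(sva))
            m <- as.matrix(read.csv("{tmp_path}/in.csv", row.names=1))
            batch <- read.csv("{tmp_path}/batch.csv", row.names=1)[,1]
            adj <- ComBat(dat=m, batch=batch)
            py <- as.matrix(read.csv("{tmp_path}/py.csv", row.names=1))
            a <- adj - rowMeans(adj); b <- py - rowMeans(py)
            cat(max(abs(a-b)))
            """
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        max_diff = float(out.stdout.strip().split()[-1])
        assert max_diff < 1e-4


class TestPeakCorrection:
    @pytest.fixture(scope="class")
    def bimodal(self):
        ann = sd.generate_annotation(4000, seed=21)
        cfg = sd.SimConfig(
            n_pairs=4, n_probes=4000, seed=22, missing_rate=0.0, effect_logor_per_sd=0.0
        )
        beta, _ = sd.generate_pairs(cfg, ann)
        return beta, ann["design_type"]

    def test_aligned_input_unchanged(self, bimodal):
        beta, design = bimodal
        out = pp.peak_correct_type2(beta, design)
        t1 = design == "I"
        pd.testing.assert_frame_equal(out.loc[t1], beta.loc[t1])  # type I untouched
        M_in = pp.beta_to_m(beta.clip(1e-6, 1 - 1e-6))
        M_out = pp.beta_to_m(out.clip(1e-6, 1 - 1e-6))
        # modes already matched: correction is close to identity
        assert np.abs(M_out - M_in).to_numpy().mean() < 0.2

    def test_compressed_type2_realigned(self, bimodal):
        beta, design = bimodal
        M = pp.beta_to_m(beta.clip(1e-6, 1 - 1e-6))
        t2 = (design == "II").to_numpy()
        M.iloc[t2, :] = M.iloc[t2, :] * 0.8  # compress type II modes
        distorted = pp.m_to_beta(M)
        fixed = pp.peak_correct_type2(distorted, design)
        Mf = pp.beta_to_m(fixed.clip(1e-6, 1 - 1e-6))
        for col in fixed.columns:
            m1 = Mf.loc[~t2, col].dropna().to_numpy()
            m2 = Mf.loc[t2, col].dropna().to_numpy()
            u1, h1 = pp._density_modes(m1, 0.5, 2.0)
            u2, h2 = pp._density_modes(m2, 0.5, 2.0)
            assert abs(u1 - u2) < 0.05 and abs(h1 - h2) < 0.05

    def test_idempotent(self, bimodal):
        beta, design = bimodal
        once = pp.peak_correct_type2(beta, design)
        twice = pp.peak_correct_type2(once, design)
        M1 = pp.beta_to_m(once.clip(1e-6, 1 - 1e-6))
        M2 = pp.beta_to_m(twice.clip(1e-6, 1 - 1e-6))
        assert np.abs(M2 - M1).to_numpy().max() < 1e-3 * np.abs(M1).to_numpy().max()

    def test_output_in_open_unit_interval(self, bimodal):
        beta, design = bimodal
        out = pp.peak_correct_type2(beta, design)
        vals = out.to_numpy()
        assert np.nanmin(vals) > 0 and np.nanmax(vals) < 1

    def test_unimodal_sample_errors_with_name(self):
        rng = np.random.default_rng(23)
        beta = pd.DataFrame(
            np.clip(rng.normal(0.5, 0.02, (500, 2)), 0.01, 0.99), columns=["ok?", "flat"]
        )
        design = pd.Series(["I"] * 250 + ["II"] * 250, index=beta.index)
        with pytest.raises(pp.ModeDetectionError, match="sample"):
            pp.peak_correct_type2(beta, design)


class TestBetaMConversion:
    @pytest.mark.parametrize("beta, m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert pp.beta_to_m(beta) == pytest.approx(m)

    def test_round_trip(self):
        b = np.linspace(0.01, 0.99, 53)
        assert np.abs(pp.m_to_beta(pp.beta_to_m(b)) - b).max() < 1e-12
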
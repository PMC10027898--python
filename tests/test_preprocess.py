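import numpy as np
import pandas as pd
import pytest

from pptpp import preprocess, simulate
from pptpp.preprocess import (
    DesignError,
    FilterRules,
    NormalizationError,
    correct_batch_effects,
    filter_proteins,
    normalize,
)

from conftest import make_long_rows, GRADIENT


class TestFilterProteins:
    def test_fixture_attribution(self, filter_fixture):
        table, expected = filter_fixture
        filtered, report = filter_proteins(table, FilterRules())
        assert set(filtered.protein_id) == {"P7"}
        assert report.n_kept == 1
        assert report.removed_by_rule == expected

    def test_single_peptide_removed(self):
        all_runs = [(t, r) for t in GRADIENT for r in (1, 2, 3)]
        table = pd.DataFrame(
            make_long_rows("P1", all_runs, qupm=1) + make_long_rows("P2", all_runs, qupm=2)
        )
        filtered, report = filter_proteins(table)
        assert set(filtered.protein_id) == {"P2"}
        assert report.removed_by_rule["min_unique_peptides"] == 1

    def test_four_temperatures_removed(self):
        runs = [(t, r) for t in GRADIENT[:4] for r in (1, 2, 3)]
        all_runs = [(t, r) for t in GRADIENT for r in (1, 2, 3)]
        table = pd.DataFrame(
            make_long_rows("P1", runs) + make_long_rows("P2", all_runs)
        )
        _, report = filter_proteins(table)
        assert report.removed_by_rule["min_temperatures"] == 1

    def test_idempotent(self, filter_fixture):
        table, _ = filter_fixture
        once, _ = filter_proteins(table)
        twice, report = filter_proteins(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )
        assert report.n_kept == report.n_input

    def test_unknown_low_temp_rejected(self, filter_fixture):
        table, _ = filter_fixture
        with pytest.raises(DesignError):
            filter_proteins(table, FilterRules(low_temps=(20.0, 25.0)))


class TestBatchCorrection:
    def _two_batch_table(self, offset=1.0):
        rows = []
        for batch, off in (("b1", 0.0), ("b2", offset)):
            rep = 1 if batch == "b1" else 2
            for i, pid in enumerate(["P1", "P2", "P3"]):
                for strain in ("clogger", "control"):
                    base = 10.0 + i + (0.5 if strain == "clogger" else 0.0)
                    rows.append(
                        {
                            "protein_id": pid,
                            "gene_name": pid,
                            "qupm": 2,
                            "strain": strain,
                            "time_min": 30,
                            "label": "light",
                            "temperature": 37.0,
                            "replicate": rep,
                            "batch": batch,
                            "signal_sum": 2.0 ** (base + off),
                        }
                    )
        return pd.DataFrame(rows)

    def test_single_batch_is_noop(self):
        table = self._two_batch_table()
        single = table[table.batch == "b1"].reset_index(drop=True)
        out = correct_batch_effects(single)
        pd.testing.assert_frame_equal(out, single)

    def test_constant_offset_removed(self):
        table = self._two_batch_table(offset=1.0)
        out = correct_batch_effects(table)
        means = np.log2(out.signal_sum).groupby(out.batch).mean()
        assert means["b1"] == pytest.approx(means["b2"], abs=1e-9)

    def test_confounded_design_rejected(self):
        table = self._two_batch_table()
        table["batch"] = table["strain"]
        with pytest.raises(DesignError, match="aliased"):
            correct_batch_effects(table)

    def test_batch_free_table_unchanged(self):
        cfg = simulate.SimConfig(
            n_proteins=10, noise_cv=0.0, batch_sd=0.0, detection_limit=0.0, seed=11
        )
        quant, _ = simulate.simulate_experiment(cfg)
        out = correct_batch_effects(quant)
        dev = np.abs(np.log2(out.signal_sum) - np.log2(quant.signal_sum))
        assert np.nanmax(dev) < 1e-9

    def test_simulated_offsets_removed_noise_free(self):
        base = dict(n_proteins=10, noise_cv=0.0, detection_limit=0.0, seed=12)
        with_batch, _ = simulate.simulate_experiment(
            simulate.SimConfig(batch_sd=0.5, **base)
        )
        clean, _ = simulate.simulate_experiment(simulate.SimConfig(batch_sd=0.0, **base))
        out = correct_batch_effects(with_batch)
        before = np.nanmedian(np.abs(np.log2(with_batch.signal_sum) - np.log2(clean.signal_sum)))
        after = np.nanmedian(np.abs(np.log2(out.signal_sum) - np.log2(clean.signal_sum)))
        assert after < before


class TestNormalize:
    def _scaled_pair(self, factor=2.0):
        rng = np.random.default_rng(0)
        values = 10.0 ** rng.uniform(3, 6, size=30)
        rows = []
        for rep, scale in ((1, 1.0), (2, factor)):
            for i, v in enumerate(values):
                rows.append(
                    {
                        "protein_id": f"P{i}",
                        "strain": "control",
                        "time_min": 30,
                        "label": "light",
                        "temperature": 37.0,
                        "replicate": rep,
                        "batch": "b",
                        "signal_sum": v * scale,
                    }
                )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("method, tol", [("median_log2", 1e-12), ("vst", 1e-6)])
    def test_global_factor_removed(self, method, tol):
        table = self._scaled_pair(2.0)
        out, coeffs = normalize(table, method=method)
        wide = out.pivot_table(index="protein_id", columns="replicate", values="value")
        assert np.max(np.abs(wide[1] - wide[2])) <= tol
        assert len(coeffs) == 2

    def test_already_normalized_is_fixed_point(self):
        table = self._scaled_pair(1.0)
        out, _ = normalize(table, method="median_log2")
        assert np.allclose(out["value"], np.log2(table["signal_sum"]), atol=1e-9)

    def test_glog_preserves_rank_order(self):
        table = self._scaled_pair(3.0)
        out, _ = normalize(table, method="vst")
        for _, sub in out.groupby("replicate"):
            order_raw = np.argsort(sub["signal_sum"].to_numpy())
            order_t = np.argsort(sub["value"].to_numpy())
            assert np.array_equal(order_raw, order_t)

    def test_single_sample_group_rejected(self):
        table = self._scaled_pair(1.0)
        single = table[table.replicate == 1]
        with pytest.raises(NormalizationError):
            normalize(single, method="median_log2")

    def test_replicate_scatter_not_inflated(self):
        cfg = simulate.SimConfig(n_proteins=60, noise_cv=0.05, batch_sd=0.4, seed=13)
        quant, _ = simulate.simulate_experiment(cfg)
        corrected = correct_batch_effects(quant)
        out, _ = normalize(corrected, method="vst")

        def pooled_rep_sd(df, col):
            wide = df.pivot_table(
                index=["protein_id", "strain", "time_min", "label", "temperature"],
                columns="replicate",
                values=col,
            )
            diffs = wide.to_numpy()[:, 1:] - wide.to_numpy()[:, :1]
            return np.nanstd(diffs)

        raw = quant.copy()
        raw["value"] = np.log2(raw["signal_sum"])
        assert pooled_rep_sd(out, "value") <= pooled_rep_sd(raw, "value")
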
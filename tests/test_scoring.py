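import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pptpp import preprocess, scoring, simulate
from pptpp.scoring import (
    ScoringError,
    abundance_score,
    compute_fold_changes,
    replicate_scores,
    stability_score,
    summarize_scores,
    z_scale_scores,
)

GRADIENT = np.array(simulate.DEFAULT_TEMPERATURES)
LOW = GRADIENT[:2]


def fc_row(values):
    return np.asarray(values, dtype=float)


class TestScores:
    def test_low_temperature_mean(self):
        fc = fc_row([0.8, 1.2] + [0.0] * 9)
        assert abundance_score(fc, GRADIENT, LOW) == pytest.approx(1.0)

    def test_zero_fold_changes_zero_scores(self):
        fc = fc_row([0.0] * 11)
        ab = abundance_score(fc, GRADIENT, LOW)
        assert ab == 0.0
        assert stability_score(fc, GRADIENT, LOW, ab) == 0.0

    def test_default_low_temperatures_are_the_two_coolest(self):
        assert tuple(LOW) == (37.0, 37.8)

    def test_constant_vector_is_pure_abundance(self):
        fc = fc_row([0.7] * 11)
        ab = abundance_score(fc, GRADIENT, LOW)
        assert ab == pytest.approx(0.7)
        assert stability_score(fc, GRADIENT, LOW, ab) == pytest.approx(0.0)

    @pytest.mark.parametrize("delta, expected", [(0.5, 4.5), (-0.5, -4.5)])
    def test_stabilization_sums_over_remaining_temperatures(self, delta, expected):
        fc = fc_row([0.0, 0.0] + [delta] * 9)
        ab = abundance_score(fc, GRADIENT, LOW)
        assert ab == 0.0
        assert stability_score(fc, GRADIENT, LOW, ab) == pytest.approx(expected)

    def test_missing_low_temperatures_undefine_the_score(self):
        fc = fc_row([np.nan, np.nan] + [0.5] * 9)
        assert np.isnan(abundance_score(fc, GRADIENT, LOW))

    @settings(deadline=None, max_examples=50)
    @given(
        delta=st.floats(-3, 3),
        base=st.lists(st.floats(-2, 2), min_size=11, max_size=11),
    )
    def test_translation_property(self, delta, base):
        fc = fc_row(base)
        ab0 = abundance_score(fc, GRADIENT, LOW)
        st0 = stability_score(fc, GRADIENT, LOW, ab0)
        ab1 = abundance_score(fc + delta, GRADIENT, LOW)
        st1 = stability_score(fc + delta, GRADIENT, LOW, ab1)
        assert ab1 == pytest.approx(ab0 + delta, abs=1e-9)
        assert st1 == pytest.approx(st0, abs=1e-7)


class TestFoldChanges:
    def _table_with_fc(self, ratio=2.0):
        """Three proteins built so per-sample medians are equal by
        construction; protein A carries clogger = ratio * control."""
        rows = []
        for rep in (1, 2):
            for temp in GRADIENT:
                for pid, ctl, clg in (
                    ("A", 4.0, 4.0 * ratio),
                    ("B", 4.0, 4.0 / ratio),
                    ("C", 4.0, 4.0),
                ):
                    for strain, sig in (("control", ctl), ("clogger", clg)):
                        rows.append(
                            {
                                "protein_id": pid,
                                "strain": strain,
                                "time_min": 90,
                                "label": "light",
                                "temperature": temp,
                                "replicate": rep,
                                "batch": "b",
                                "signal_sum": sig * 1000,
                            }
                        )
        return pd.DataFrame(rows)

    def test_identical_strains_give_zero(self):
        table = self._table_with_fc(ratio=1.0)
        norm, _ = preprocess.normalize(table, method="median_log2")
        fc = compute_fold_changes(norm)
        assert np.allclose(fc["log2fc"], 0.0, atol=1e-12)

    def test_doubled_clogger_gives_plus_one_through_median_pipeline(self):
        table = self._table_with_fc(ratio=2.0)
        norm, _ = preprocess.normalize(table, method="median_log2")
        fc = compute_fold_changes(norm)
        fc_a = fc[fc.protein_id == "A"]
        assert len(fc_a) == 2 * len(GRADIENT)
        assert np.allclose(fc_a["log2fc"], 1.0, atol=1e-9)

    def test_missing_side_masks_only_that_entry(self):
        table = self._table_with_fc()
        mask = (
            (table.protein_id == "A")
            & (table.strain == "control")
            & (table.temperature == GRADIENT[-1])
            & (table.replicate == 1)
        )
        table = table[~mask]
        norm, _ = preprocess.normalize(table, method="log2")
        fc = compute_fold_changes(norm)
        fc_a1 = fc[(fc.protein_id == "A") & (fc.replicate == 1)]
        assert len(fc_a1) == len(GRADIENT) - 1
        fc_a2 = fc[(fc.protein_id == "A") & (fc.replicate == 2)]
        assert len(fc_a2) == len(GRADIENT)


class TestZScaling:
    def _summary(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(20)] * 2,
                "label": ["light"] * 20 + ["heavy"] * 20,
                "time_min": 90,
                "abundance_score": rng.normal(0.2, 1.0, 40),
                "stability_score": rng.normal(-0.5, 2.0, 40),
            }
        )

    def test_zero_mean_unit_sd_within_label(self):
        out = z_scale_scores(self._summary())
        for _, sub in out.groupby("label"):
            assert sub["z_abundance"].mean() == pytest.approx(0.0, abs=1e-9)
            assert sub["z_abundance"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            assert sub["z_stability"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_rank_order_preserved(self):
        summary = self._summary()
        out = z_scale_scores(summary)
        light = out[out.label == "light"]
        assert np.array_equal(
            np.argsort(light["stability_score"]), np.argsort(light["z_stability"])
        )

    def test_degenerate_group_rejected(self):
        summary = self._summary()
        summary["abundance_score"] = 1.0
        with pytest.raises(ScoringError):
            z_scale_scores(summary)


class TestPipelineOracle:
    def test_scores_match_independent_recomputation(self, scoring_fixture):
        """Pipeline scores equal a single-pass hand recomputation, exactly."""
        fc = compute_fold_changes(scoring_fixture)
        per_rep = replicate_scores(fc)

        # independent oracle: plain loops over the normalized table
        low = (37.0, 37.8)
        for _, row in per_rep.iterrows():
            sub = scoring_fixture[
                (scoring_fixture.protein_id == row.protein_id)
                & (scoring_fixture.replicate == row.replicate)
            ]
            fcs = {}
            for temp in GRADIENT:
                clg = sub[(sub.temperature == temp) & (sub.strain == "clogger")]["value"]
                ctl = sub[(sub.temperature == temp) & (sub.strain == "control")]["value"]
                if len(clg) == 1 and len(ctl) == 1:
                    fcs[temp] = float(clg.iloc[0]) - float(ctl.iloc[0])
            low_vals = [fcs[t] for t in low if t in fcs]
            ab = sum(low_vals) / len(low_vals)
            stab = sum(v - ab for t, v in fcs.items() if t not in low)
            assert row.abundance_score == pytest.approx(ab, abs=1e-12)
            assert row.stability_score == pytest.approx(stab, abs=1e-12)
            assert row.n_temps_used == len(fcs)

    def test_decomposition_identity_on_complete_vectors(self, scoring_fixture):
        fc = compute_fold_changes(scoring_fixture)
        per_rep = replicate_scores(fc)
        complete = per_rep[per_rep.n_temps_used == len(GRADIENT)]
        assert len(complete) > 0
        for _, row in complete.iterrows():
            vec = fc[
                (fc.protein_id == row.protein_id) & (fc.replicate == row.replicate)
            ].set_index("temperature")["log2fc"]
            nonlow = vec[~vec.index.isin(LOW)]
            assert np.sum(nonlow - row.abundance_score) == pytest.approx(
                row.stability_score, abs=1e-12
            )


class TestSimulatorFaithfulness:
    @pytest.mark.parametrize("d_tm, positive", [(3.0, True), (-3.0, False)])
    def test_tm_shift_sign_drives_stability_score(self, d_tm, positive):
        eff = {
            "shift": simulate.EffectProfile("shift", d_tm_pre=d_tm, d_tm_post=d_tm)
        }
        cfg = simulate.SimConfig(
            n_proteins=200,
            group_fractions={"shift": 1.0},
            effects=eff,
            noise_cv=0.1,
            batch_sd=0.0,
            seed=77,
        )
        quant, _ = simulate.simulate_experiment(cfg)
        norm, _ = preprocess.normalize(quant, method="log2")
        summary = summarize_scores(replicate_scores(compute_fold_changes(norm)))
        mean_stab = summary["stability_score"].mean()
        assert (mean_stab > 0) == positive
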
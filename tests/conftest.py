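import numpy as np
import pandas as pd
import pytest

from pptpp import simulate


@pytest.fixture(scope="session")
def small_experiment():
    """A 20-protein default-parameter experiment with ground truth."""
    cfg = simulate.SimConfig(n_proteins=20, seed=42)
    quant, gt = simulate.simulate_experiment(cfg)
    return cfg, quant, gt


def make_long_rows(
    protein_id,
    temps_reps,
    qupm=3,
    label="light",
    strain="control",
    time_min=30,
    signal=1000.0,
):
    """Long-format rows for one protein observed at given (temp, rep) runs."""
    rows = []
    for temp, rep in temps_reps:
        rows.append(
            {
                "protein_id": protein_id,
                "gene_name": protein_id,
                "qupm": qupm,
                "strain": strain,
                "time_min": time_min,
                "label": label,
                "temperature": temp,
                "replicate": rep,
                "batch": f"T{temp:g}_r{rep}",
                "signal_sum": signal,
            }
        )
    return rows


GRADIENT = simulate.DEFAULT_TEMPERATURES


@pytest.fixture(scope="session")
def filter_fixture():
    """Seven hand-built proteins: six violating exactly one filter rule
    each (in the rule-attribution order), one clean survivor.

    Expected attribution: min_unique_peptides 2, min_runs_at_low_temp 2,
    min_temperatures 1, min_total_runs 1, kept 1.
    """
    all_runs = [(t, r) for t in GRADIENT for r in (1, 2, 3)]
    rows = []
    # P1, P2: single unique peptide
    rows += make_long_rows("P1", all_runs, qupm=1)
    rows += make_long_rows("P2", all_runs, qupm=1)
    # P3: only one replicate run at each of the two coolest temperatures
    runs_p3 = [(t, r) for t, r in all_runs if t > 38.0] + [(37.0, 1), (37.8, 1)]
    rows += make_long_rows("P3", runs_p3)
    # P6: fails the low-temperature rule AND the temperature count
    # (first-failing attribution -> min_runs_at_low_temp)
    rows += make_long_rows("P6", [(37.0, 1), (40.4, 1), (44.0, 1), (46.9, 1)])
    # P4: observed at only 4 temperatures (but 12 runs, low-temp fine)
    runs_p4 = [(t, r) for t in GRADIENT[:4] for r in (1, 2, 3)]
    rows += make_long_rows("P4", runs_p4)
    # P5: 6 temperatures, low-temp ok, but only 7 runs in total
    runs_p5 = [(37.0, 1), (37.0, 2), (37.8, 1), (40.4, 1), (44.0, 1), (46.9, 1), (49.8, 1)]
    rows += make_long_rows("P5", runs_p5)
    # P7: clean
    rows += make_long_rows("P7", all_runs)
    expected = {
        "min_unique_peptides": 2,
        "min_runs_at_low_temp": 2,
        "min_temperatures": 1,
        "min_total_runs": 1,
    }
    return pd.DataFrame(rows), expected


@pytest.fixture(scope="session")
def scoring_fixture():
    """Five proteins with a hand-checkable normalized value table.

    Log2-like values are constructed directly (as if normalized), with
    a few deliberately missing entries, one replicate pair per strain.
    """
    rng = np.random.default_rng(2024)
    temps = GRADIENT
    rows = []
    for i, pid in enumerate(["A", "B", "C", "D", "E"]):
        for rep in (1, 2):
            for it, temp in enumerate(temps):
                control = 10.0 + 0.3 * i + 0.01 * it
                fc = {"A": 0.0, "B": 1.0, "C": -0.5, "D": 0.25, "E": 0.8}[pid]
                curve = {"A": 0.0, "B": 0.0, "C": 0.3, "D": -0.2, "E": 0.1}[pid] * it
                clogger = control + fc + curve + 0.05 * rep
                for strain, value in (("control", control), ("clogger", clogger)):
                    if pid == "D" and temp == temps[-1] and strain == "control":
                        continue  # masked entry
                    rows.append(
                        {
                            "protein_id": pid,
                            "label": "light",
                            "time_min": 90,
                            "replicate": rep,
                            "temperature": temp,
                            "strain": strain,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)
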
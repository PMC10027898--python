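"""Reading, writing and merging of the pipeline's tabular formats.

The canonical in-memory form is a long (tidy) pandas DataFrame with one
row per (protein, strain, time, label, temperature, replicate)
measurement; IsobarQuant-style per-run ``protein.txt`` tables are an
I/O dialect only. Missing intensities are NaN in memory and "NA" on
disk; zero reporter-ion signals are treated as non-detections on
ingest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: columns addressing one measurement (the sample key)
SAMPLE_KEY = ["strain", "time_min", "label", "temperature", "replicate", "batch"]

#: canonical column order of the long quantification table
QUANT_COLUMNS = ["protein_id", "gene_name", "qupm"] + SAMPLE_KEY + ["signal_sum"]


class QuantFormatError(ValueError):
    """Malformed quantification table or metadata."""


def read_metadata(path) -> pd.DataFrame:
    """Read ``metadata.tsv`` mapping (run_id, channel) to sample keys."""
    meta = pd.read_csv(path, sep="\t")
    required = {"run_id", "channel"} | set(SAMPLE_KEY)
    missing = required - set(meta.columns)
    if missing:
        raise QuantFormatError(f"metadata missing columns: {sorted(missing)}")
    meta["channel"] = meta["channel"].astype(str)
    return meta


def read_quant_run(path, channel_map: pd.DataFrame) -> pd.DataFrame:
    """Read one IsobarQuant-style protein table into long format.

    Parameters
    ----------
    path : file path
        Tab-delimited table with columns ``protein_id``, ``gene_name``,
        ``qupm`` and one ``signal_sum_<channel>`` column per TMT channel.
    channel_map : DataFrame
        Rows with ``channel`` plus the sample-key columns, covering
        every signal_sum column in the file.

    Zero intensities are recorded missing (NaN). Duplicated protein IDs
    within one run and negative intensities raise
    :class:`QuantFormatError`.
    """
    wide = pd.read_csv(path, sep="\t")
    mandatory = ["protein_id", "gene_name", "qupm"]
    missing = [c for c in mandatory if c not in wide.columns]
    if missing:
        raise QuantFormatError(f"{path}: missing mandatory columns {missing}")
    sig_cols = [c for c in wide.columns if c.startswith("signal_sum_")]
    if not sig_cols:
        raise QuantFormatError(f"{path}: no signal_sum columns")
    if wide["protein_id"].duplicated().any():
        dups = wide.loc[wide["protein_id"].duplicated(), "protein_id"].tolist()
        raise QuantFormatError(f"{path}: duplicated protein ids {dups}")

    cmap = channel_map.copy()
    cmap["channel"] = cmap["channel"].astype(str)
    mapped = set("signal_sum_" + cmap["channel"])
    unmapped = sorted(set(sig_cols) - mapped)
    if unmapped:
        raise QuantFormatError(f"{path}: unmapped channel columns {unmapped}")

    long = wide.melt(
        id_vars=mandatory,
        value_vars=sig_cols,
        var_name="channel",
        value_name="signal_sum",
    )
    long["channel"] = long["channel"].str.removeprefix("signal_sum_")
    long["signal_sum"] = pd.to_numeric(long["signal_sum"])
    if (long["signal_sum"] < 0).any():
        raise QuantFormatError(f"{path}: negative intensities")
    long.loc[long["signal_sum"] == 0, "signal_sum"] = np.nan
    long = long.merge(cmap[["channel"] + SAMPLE_KEY], on="channel", how="left")
    return long[QUANT_COLUMNS]


def merge_runs(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-run long tables into one quantification table.

    Conflicting duplicate (protein, sample-key) measurements raise an
    error listing the offending keys. Adds ``n_identified_runs``:
    per (protein, label), the number of distinct (temperature,
    replicate) MS runs with at least one observed signal.
    """
    if not tables:
        raise QuantFormatError("no tables to merge")
    merged = pd.concat(tables, ignore_index=True)
    key = ["protein_id"] + SAMPLE_KEY
    dup = merged.duplicated(subset=key, keep=False)
    if dup.any():
        offending = merged.loc[dup, key].drop_duplicates().head(10)
        raise QuantFormatError(
            f"conflicting duplicate measurements for keys:\n{offending}"
        )
    merged = merged.sort_values(key, kind="mergesort").reset_index(drop=True)
    counts = identification_counts(merged)
    merged = merged.merge(counts[["protein_id", "label", "n_identified_runs"]],
                          on=["protein_id", "label"], how="left")
    return merged[QUANT_COLUMNS + ["n_identified_runs"]]


def identification_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per (protein, label) identification bookkeeping.

    Returns one row per (protein_id, label) with the number of distinct
    MS runs (temperature x replicate) and temperatures in which the
    protein was observed.
    """
    obs = table.dropna(subset=["signal_sum"])
    run_pairs = obs[["protein_id", "label", "temperature", "replicate"]].drop_duplicates()
    runs = (
        run_pairs.groupby(["protein_id", "label"])
        .size()
        .rename("n_identified_runs")
        .reset_index()
    )
    temp_pairs = obs[["protein_id", "label", "temperature"]].drop_duplicates()
    temps = (
        temp_pairs.groupby(["protein_id", "label"])
        .size()
        .rename("n_temperatures")
        .reset_index()
    )
    return runs.merge(temps, on=["protein_id", "label"])


def write_tidy(table: pd.DataFrame, path) -> Path:
    """Write a table as TSV with missing values serialized as "NA"."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_tidy(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tidy` ("NA" means missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def load_experiment_dir(directory) -> pd.DataFrame:
    """Load all ``protein_*.txt`` runs in a directory via its metadata.

    Convenience wrapper: reads ``metadata.tsv``, then each per-run file
    with its channel map, and merges.
    """
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    tables = []
    for run_id, cmap in meta.groupby("run_id"):
        path = directory / f"protein_{run_id}.txt"
        if not path.exists():
            raise QuantFormatError(f"run file missing: {path}")
        tables.append(read_quant_run(path, cmap))
    return merge_runs(tables)
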
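"""Plain-text readers and writers for the pipeline's tabular formats.

Beta matrices travel as TSV (rows = probes, columns = samples, 4 decimal
places, missing as NA); manifests and sample sheets as CSV; intensity
cohorts as long-format TSV; differential tables as TSV; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError


def write_beta_tsv(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA", index_label="probe_id")


def read_beta_tsv(path) -> pd.DataFrame:
    betas = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA"])
    values = betas.to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise DataError(f"beta values outside [0, 1] in {path}")
    if betas.index.has_duplicates:
        raise DataError(f"duplicate probe ids in {path}")
    return betas


def write_manifest_csv(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index_label="probe_id")


def read_manifest_csv(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, index_col="probe_id", keep_default_na=False)
    required = {"chrom", "pos", "gene", "region_category", "island_relation", "snp_flagged"}
    missing = required - set(manifest.columns)
    if missing:
        raise DataError(f"manifest {path} missing columns: {sorted(missing)}")
    if manifest.index.has_duplicates:
        raise DataError(f"duplicate probe ids in manifest {path}")
    manifest["pos"] = manifest["pos"].astype(int)
    manifest["snp_flagged"] = manifest["snp_flagged"].astype(str).str.lower().isin(
        ["true", "1", "yes"]
    )
    return manifest


def write_sample_sheet(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, index=False
    )


def read_sample_sheet(path) -> pd.Series:
    sheet = pd.read_csv(path)
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise DataError(f"sample sheet {path} needs sample_id and group columns")
    return pd.Series(
        sheet["group"].to_numpy(), index=sheet["sample_id"].to_numpy(), name="group"
    )


def write_intensity_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_intensity_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_diff_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g", index_label="unit_id")


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
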
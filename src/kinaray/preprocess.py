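"""Assemble slide quantifications into the analysis matrix.

Three rules, applied in a fixed order:

1. quality-flagged spots become missing values,
2. each slide is normalized by median-centering its observed log2 net
   intensities (the median spans all replicate blocks on the slide),
3. within each (substrate, cell type, time) condition, a single missing
   technical replicate is imputed with the mean of the available
   replicates; a substrate with more than one missing replicate in a
   condition is excluded from the analysis entirely.

Centering precedes imputation so that imputed values can never influence
a slide median.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "cell_type", "time_min", "replicate", "slide_id"]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample column (one replicate block on one slide)."""

    sample_id: str
    cell_type: str
    time_min: int
    replicate: int
    slide_id: str


@dataclass
class IntensityMatrix:
    """Substrates x samples log2 net intensities with sample metadata.

    ``values`` is a DataFrame indexed by substrate_id with one column per
    sample_id; missing values are NaN.  ``samples`` is a DataFrame with
    columns sample_id, cell_type, time_min, replicate, slide_id, in the
    same order as the value columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample sheet lacks columns: {missing_cols}")
        self.samples = self.samples.reset_index(drop=True)
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix columns do not match sample sheet order")
        triples = self.samples[["cell_type", "time_min", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("(cell_type, time_min, replicate) must be unique")

    @property
    def substrate_ids(self):
        return list(self.values.index)

    @property
    def n_substrates(self) -> int:
        return self.values.shape[0]

    def sample_meta(self) -> list[SampleMeta]:
        return [SampleMeta(**row) for row in
                self.samples[SAMPLE_COLUMNS].to_dict("records")]

    def condition_columns(self) -> dict:
        """Map (cell_type, time_min) -> sample_ids ordered by replicate."""
        out = {}
        for (cell, t), grp in self.samples.groupby(["cell_type", "time_min"],
                                                   sort=True):
            out[(cell, t)] = list(grp.sort_values("replicate")["sample_id"])
        return out

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "substrate_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, sample_sheet) -> "IntensityMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        samples = read_sample_sheet(sample_sheet)
        samples = samples.set_index("sample_id").loc[list(values.columns)].reset_index()
        return cls(values=values, samples=samples)


def read_sample_sheet(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns: {missing}")
    df["time_min"] = df["time_min"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df


def median_center(slide_values):
    """Subtract the median of the observed values; NaNs pass through.

    The median of an even number of values is the mean of the middle two.
    Raises if every value is missing.
    """
    arr = np.asarray(slide_values, dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise ValueError("cannot median-center an all-missing slide")
    return arr - np.median(observed)


def impute_replicates(triple):
    """Apply the replicate imputation / exclusion rule to one condition.

    Exactly one missing value is imputed with the mean of the available
    replicates; more than one missing triggers exclusion of the substrate.

    Returns
    -------
    (imputed, excluded)
        ``imputed`` is the completed array (unchanged values preserved);
        ``excluded`` is True when more than one replicate is missing, in
        which case ``imputed`` is returned as-is.
    """
    arr = np.asarray(triple, dtype=float)
    missing = np.isnan(arr)
    n_missing = int(missing.sum())
    if n_missing > 1:
        return arr, True
    if n_missing == 1:
        arr = arr.copy()
        arr[missing] = arr[~missing].mean()
    return arr, False


def _assemble_raw(quant_tables: dict, sample_sheet: pd.DataFrame,
                  control_ids=frozenset()):
    """Raw substrates x samples matrix from per-slide quant tables.

    Each quant table has columns substrate_id, block, log2_net, flags;
    block number is the technical replicate.  Flagged spots and
    nonpositive nets arrive as NaN log2_net or a nonempty flag string and
    become missing.  Control spots are dropped from the matrix.
    """
    samples = read_sample_sheet(sample_sheet)
    sheet_slides = set(samples["slide_id"])
    table_slides = set(quant_tables)
    if sheet_slides != table_slides:
        raise ValueError(
            f"sample sheet and quant tables disagree: sheet-only="
            f"{sorted(sheet_slides - table_slides)}, "
            f"tables-only={sorted(table_slides - sheet_slides)}"
        )

    ref_ids = None
    columns = {}
    for _, row in samples.iterrows():
        qt = quant_tables[row["slide_id"]]
        sub = qt[qt["block"] == row["replicate"]].copy()
        sub = sub[~sub["substrate_id"].isin(control_ids)]
        ids = list(sub["substrate_id"])
        if ref_ids is None:
            ref_ids = ids
        elif set(ids) != set(ref_ids):
            raise ValueError(
                f"substrate set of slide {row['slide_id']} block "
                f"{row['replicate']} differs from the first slide"
            )
        vals = sub.set_index("substrate_id")["log2_net"].reindex(ref_ids)
        flagged = sub.set_index("substrate_id")["flags"].reindex(ref_ids)
        flagged = flagged.fillna("").astype(str) != ""
        vals[flagged.values] = np.nan
        columns[row["sample_id"]] = vals.to_numpy(dtype=float)

    values = pd.DataFrame(columns, index=ref_ids)
    values.index.name = "substrate_id"
    return IntensityMatrix(values=values, samples=samples)


def build_matrix(quant_tables: dict, sample_sheet, control_ids=frozenset(),
                 exclusion_scope: str = "condition"):
    """QC-drop, median-center, impute and exclude; return matrix + report.

    Parameters
    ----------
    quant_tables
        Mapping slide_id -> quantification table (columns substrate_id,
        block, log2_net, flags).  May also be an :class:`IntensityMatrix`
        to start from a pre-assembled raw matrix.
    sample_sheet
        Path or DataFrame with sample_id, cell_type, time_min, replicate,
        slide_id (ignored when an IntensityMatrix is passed).
    exclusion_scope
        ``"condition"`` (default): a substrate is excluded when any single
        (cell type, time) condition has more than one missing replicate.
        ``"global_count"``: excluded when the substrate has more than one
        missing value across all samples; otherwise its single missing
        value is imputed within its condition.

    Returns
    -------
    (IntensityMatrix, report)
        The completed matrix (no missing values among retained
        substrates) and a dict with retained / excluded counts and ids.
    """
    if exclusion_scope not in ("condition", "global_count"):
        raise ValueError(f"unknown exclusion_scope: {exclusion_scope!r}")
    if isinstance(quant_tables, IntensityMatrix):
        raw = quant_tables
    else:
        raw = _assemble_raw(quant_tables, sample_sheet, control_ids)

    values = raw.values.copy()
    # per-slide median centering over observed values (all replicate blocks)
    for slide, grp in raw.samples.groupby("slide_id", sort=False):
        cols = list(grp["sample_id"])
        block = values[cols].to_numpy(dtype=float)
        values[cols] = median_center(block.ravel()).reshape(block.shape)

    cond_cols = raw.condition_columns()
    arr = values.to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(values.columns)}

    excluded = np.zeros(arr.shape[0], dtype=bool)
    if exclusion_scope == "global_count":
        excluded |= np.isnan(arr).sum(axis=1) > 1
    for cols in cond_cols.values():
        idx = [col_index[c] for c in cols]
        triple = arr[:, idx]
        miss = np.isnan(triple)
        n_miss = miss.sum(axis=1)
        if exclusion_scope == "condition":
            excluded |= n_miss > 1
        one = n_miss == 1
        if one.any():
            avail_mean = np.nanmean(np.where(miss, np.nan, triple)[one], axis=1)
            filled = triple[one]
            filled[miss[one]] = avail_mean
            triple[one] = filled
        arr[:, idx] = triple

    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    retained = out.loc[~excluded]
    report = {
        "n_input": int(arr.shape[0]),
        "n_retained": int((~excluded).sum()),
        "n_excluded": int(excluded.sum()),
        "excluded_ids": list(values.index[excluded]),
        "exclusion_scope": exclusion_scope,
        "n_missing_raw": int(raw.values.isna().to_numpy().sum()),
    }
    return IntensityMatrix(values=retained, samples=raw.samples), report


def write_exclusion_report(report: dict, path) -> None:
    import json

    Path(path).write_text(json.dumps(report, indent=2) + "\n")
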
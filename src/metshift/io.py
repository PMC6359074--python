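"""Data model, file I/O and preprocessing for metabolite abundance tables.

A study table is a samples x metabolites matrix of relative abundances
(arbitrary units, already normalized to an internal protein standard by the
measurement vendor). Values below the detection limit arrive as missing
cells; preprocessing imputes each metabolite's missing cells to its minimum
detected value and log-transforms, the standard treatment for left-censored
untargeted metabolomics data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}

MISSING_TOKENS = ("", "NA")


@dataclass
class MetaboliteAnnotation:
    """Per-metabolite record: display name, identification status, class label."""

    name: str
    id_status: Literal["known", "unknown"] = "known"
    class_label: str = ""
    external_ids: dict[str, str] = field(default_factory=dict)


@dataclass
class AbundanceTable:
    """Samples x metabolites relative-abundance matrix.

    ``values`` is a pandas DataFrame indexed by sample id with metabolite ids
    as columns; missing cells are NaN, never zero.
    """

    values: pd.DataFrame
    annotations: dict[str, MetaboliteAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index.astype(str).str.strip()
        cols = self.values.columns.astype(str).str.strip()
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate metabolite ids: {dups}")
        self.values = self.values.copy()
        self.values.index = idx
        self.values.columns = cols
        self.values.index.name = None
        self.values.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(sample_ids)], self.annotations)

    def subset_metabolites(self, metabolite_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.values[list(metabolite_ids)], self.annotations)


@dataclass
class SampleAnnotation:
    """Per-sample design record: diet arm, genotype, phenotype class, triglyceride."""

    sample_id: str
    diet: Literal["ND", "HFD"]
    genotype: str = ""
    reaction_norm: Literal["N_gt_HF", "zero", "N_lt_HF"] | None = None
    triglyceride: float | None = None

    def __post_init__(self) -> None:
        if self.diet not in ("ND", "HFD"):
            raise ValueError(f"diet must be ND or HFD, got {self.diet!r}")
        if self.reaction_norm not in (None, "N_gt_HF", "zero", "N_lt_HF"):
            raise ValueError(f"invalid reaction norm class {self.reaction_norm!r}")


@dataclass
class PreprocessReport:
    """What preprocessing did: which cells were imputed, which samples look aberrant."""

    imputed_cell_count: int = 0
    imputation_value_per_metabolite: dict[str, float] = field(default_factory=dict)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: dict[str, float] = field(default_factory=dict)
    outlier_scores: dict[str, float] = field(default_factory=dict)
    log_base: str = "e"


def read_abundance_table(
    path: str | Path,
    orientation: Literal["samples_in_rows", "metabolites_in_rows"] = "samples_in_rows",
    missing_tokens: Sequence[str] = MISSING_TOKENS,
) -> AbundanceTable:
    """Read a TSV/CSV abundance table (dialect sniffed from the extension).

    The first column holds sample ids (or metabolite ids when
    ``orientation="metabolites_in_rows"``). Missing cells — empty or one of
    ``missing_tokens`` — are kept as NaN, never coerced to zero. Duplicate
    ids and non-numeric cells raise ValueError naming the offender.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)[1:]]
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        # checked on the raw line: pandas silently renames duplicate columns
        raise ValueError(f"{path}: duplicate identifiers in header: {dup_cols}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(missing_tokens),
        keep_default_na=False, dtype=str,
    )
    if df.index.astype(str).duplicated().any():
        dups = sorted(set(df.index[df.index.astype(str).duplicated()]))
        raise ValueError(f"{path}: duplicate identifiers in index: {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            ) from None
    if orientation == "metabolites_in_rows":
        numeric = numeric.T
    return AbundanceTable(numeric)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.values.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


def read_metadata(path: str | Path) -> list[SampleAnnotation]:
    """Read a metadata TSV: sample_id, diet, genotype, reaction_norm, triglyceride."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "NA"], keep_default_na=False)
    required = {"sample_id", "diet"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata must contain columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        trig = d.get("triglyceride")
        rn = d.get("reaction_norm")
        out.append(
            SampleAnnotation(
                sample_id=str(d["sample_id"]).strip(),
                diet=str(d["diet"]).strip(),
                genotype=str(d.get("genotype") or ""),
                reaction_norm=None if pd.isna(rn) or rn is None else str(rn),
                triglyceride=None if trig is None or pd.isna(trig) else float(trig),
            )
        )
    return out


def write_metadata(meta: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "diet": m.diet,
            "genotype": m.genotype,
            "reaction_norm": m.reaction_norm if m.reaction_norm is not None else "NA",
            "triglyceride": m.triglyceride if m.triglyceride is not None else "NA",
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def impute_min_and_log(
    table: AbundanceTable, log_base: str = "e"
) -> tuple[AbundanceTable, PreprocessReport]:
    """Impute missing cells to each metabolite's minimum detected value, then log.

    A metabolite with no observed value at all, or any nonpositive observed
    value (log undefined), raises ValueError.
    """
    if log_base not in LOG_BASES:
        raise ValueError(f"log_base must be one of {sorted(LOG_BASES)}")
    vals = table.values
    all_missing = vals.columns[vals.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"metabolites with no observed value: {list(all_missing)}")
    if (vals <= 0).any().any():
        bad = vals.columns[(vals <= 0).any(axis=0)]
        raise ValueError(f"nonpositive observed abundances in: {list(bad)}")

    col_min = vals.min(axis=0, skipna=True)
    mask = vals.isna()
    filled = vals.fillna(col_min)
    logged = np.log(filled) / math.log(LOG_BASES[log_base])

    imputed_cells = [
        (vals.index[i], vals.columns[j]) for i, j in zip(*np.where(mask.values))
    ]
    report = PreprocessReport(
        imputed_cell_count=int(mask.values.sum()),
        imputation_value_per_metabolite={
            m: float(col_min[m]) for m in vals.columns[mask.any(axis=0)]
        },
        imputed_cells=imputed_cells,
        log_base=log_base,
    )
    return AbundanceTable(logged, table.annotations), report


def flag_outlier_samples(
    table: AbundanceTable, robust_z_cutoff: float = 5.0
) -> PreprocessReport:
    """Score each sample by the robust z of its median log abundance.

    The score is (sample median - median of sample medians) / (1.4826 * MAD),
    computed across samples; samples whose |score| exceeds the cutoff are
    flagged in ``removed_samples``. Nothing is removed here — dropping a
    flagged sample is an explicit caller action (``AbundanceTable.subset_samples``).
    """
    if table.n_samples < 4:
        raise ValueError("robust outlier scoring needs at least 4 samples")
    med = table.values.median(axis=1, skipna=True)
    center = med.median()
    mad = (med - center).abs().median()
    scale = 1.4826 * mad
    if scale == 0:
        # Majority of samples coincide: any deviation is infinitely many
        # MADs away; identical samples all score 0.
        dev = med - center
        scores = pd.Series(
            np.where(dev == 0, 0.0, np.inf * np.sign(dev)), index=med.index
        )
    else:
        scores = (med - center) / scale
    flagged = scores[scores.abs() > robust_z_cutoff]
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} sample(s) exceed robust-z cutoff {robust_z_cutoff}: "
            f"{dict(flagged.round(2))}",
            stacklevel=2,
        )
    return PreprocessReport(
        outlier_scores={str(k): float(v) for k, v in scores.items()},
        removed_samples={str(k): float(v) for k, v in flagged.items()},
    )
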
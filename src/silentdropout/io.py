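"""Plain-text readers and writers for the package's table schemas.

Cohort and score tables travel as CSV; count matrices as TSV with gene ids in
the first column and sample ids in the header; gene lengths and group labels
as 2-column TSVs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .simulate import COHORT_COLUMNS, SCORE_COLUMNS, CountMatrix

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_scores",
    "write_scores",
    "read_count_matrix",
    "write_count_matrix",
]


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} is missing columns {missing}")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, COHORT_COLUMNS, "cohort table")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SCORE_COLUMNS, "score table")
    return df


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_count_matrix(counts_path, lengths_path, groups_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(
        counts,
        lengths.reindex(counts.index),
        groups.reindex(counts.columns),
    )


def write_count_matrix(matrix: CountMatrix, out_dir, stem: str) -> None:
    out = Path(out_dir)
    matrix.counts.to_csv(out / f"{stem}_counts.tsv", sep="\t")
    matrix.gene_lengths.to_frame().to_csv(out / f"{stem}_gene_lengths.tsv", sep="\t")
    matrix.sample_groups.to_frame().to_csv(out / f"{stem}_groups.tsv", sep="\t")
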
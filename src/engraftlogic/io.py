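"""Plain-text I/O: tab-separated matrices, sample sheets and call tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from engraftlogic.matrix import ExpressionMatrix


def write_matrix(matrix: ExpressionMatrix, values_path, samples_path) -> None:
    matrix.values.rename_axis("feature_id").to_csv(values_path, sep="\t")
    matrix.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")


def read_matrix(values_path, samples_path, meta_columns=()) -> ExpressionMatrix:
    """Read a TSV intensity matrix + sample sheet.

    ``meta_columns`` names non-intensity columns of the matrix file (e.g.
    ``priority``, ``gene_id``) to split into ``feature_meta``.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    meta = None
    meta_columns = [c for c in meta_columns if c in values.columns]
    if meta_columns:
        meta = values[meta_columns].copy()
        values = values.drop(columns=meta_columns)
    return ExpressionMatrix(values=values, samples=samples, feature_meta=meta).validate()


def write_ground_truth(gt: pd.DataFrame, path) -> None:
    gt.to_csv(path, sep="\t")


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.rename_axis("feature_id").to_csv(path, sep="\t")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
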
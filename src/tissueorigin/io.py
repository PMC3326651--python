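"""Plain-text readers/writers for the package's file formats.

Expression matrices travel as tab-delimited text with probesets as
rows (first column the probeset id) and specimens as columns;
metadata and report tables as comma-delimited text with a header row;
models and standardization references as structured (JSON) text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classifier import ClassifierModel
from .standardize import StandardizationReference


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probeset_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_reference(path) -> StandardizationReference:
    return StandardizationReference.from_json(Path(path).read_text())


def write_reference(ref: StandardizationReference, path) -> None:
    Path(path).write_text(ref.to_json())


def read_model(path) -> ClassifierModel:
    return ClassifierModel.from_json(Path(path).read_text())


def write_model(model: ClassifierModel, path) -> None:
    Path(path).write_text(model.to_json())
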
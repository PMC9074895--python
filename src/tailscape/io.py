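"""Readers and writers for the pipeline's tabular interchange formats.

Everything is plain TSV (optionally gzipped), JSON, or YAML so that
intermediate results stay inspectable with standard command-line tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ghmm import GHMMParams

__all__ = [
    "write_traces",
    "read_traces",
    "write_params",
    "read_params",
    "read_norms",
    "write_table",
    "read_table",
]

_CHANNELS = ["A", "C", "G", "T"]


def write_traces(path, raw: np.ndarray, tag_ids) -> None:
    """Write an (n, cycles, 4) intensity stack as long-format gzipped TSV.

    Columns: tag_id, cycle (0-based), A, C, G, T.  Millions of rows are
    common, so the write goes through pyarrow's CSV writer.
    """
    import pyarrow as pa
    import pyarrow.csv as pacsv

    n, t_len, _ = raw.shape
    flat = np.ascontiguousarray(raw.reshape(n * t_len, 4))
    table = pa.table(
        {
            "tag_id": pa.array(np.repeat(np.asarray(tag_ids, dtype=object), t_len)),
            "cycle": pa.array(np.tile(np.arange(t_len), n)),
            **{c: flat[:, i] for i, c in enumerate(_CHANNELS)},
        }
    )
    compression = "gzip" if str(path).endswith(".gz") else None
    with pa.output_stream(str(path), compression=compression) as sink:
        pacsv.write_csv(table, sink, pacsv.WriteOptions(delimiter="\t"))


def read_traces(path):
    """Read traces written by :func:`write_traces`.

    Returns ``(raw, tag_ids)`` with traces ordered as in the file.  All
    tags must share one cycle count.
    """
    import pyarrow.csv as pacsv

    df = pacsv.read_csv(
        str(path), parse_options=pacsv.ParseOptions(delimiter="\t")
    ).to_pandas()
    tag_ids = df["tag_id"].unique()
    t_len = int(df["cycle"].max()) + 1
    if len(df) != len(tag_ids) * t_len:
        raise ValueError("traces have unequal cycle counts")
    raw = df[_CHANNELS].to_numpy(dtype=float).reshape(len(tag_ids), t_len, 4)
    return raw, tag_ids


def write_params(path, params: GHMMParams) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def read_params(path) -> GHMMParams:
    return GHMMParams.from_dict(json.loads(Path(path).read_text()))


def read_norms(path) -> np.ndarray:
    """Channel norms from JSON: either a list [A, C, G, T] or a mapping."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data[c] for c in _CHANNELS]
    return np.asarray(data, dtype=float)


def write_table(path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
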
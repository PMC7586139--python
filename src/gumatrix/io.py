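"""Reading and writing the delimited-text formats the CLI exchanges."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a numeric matrix from delimited text (CSV/TSV/whitespace).

    The delimiter is sniffed and a single header line is tolerated:
    if the first row is not fully numeric it is treated as column names.
    """
    df = pd.read_csv(
        path, sep=r"[\s,;]+", engine="python", header=None, comment="#"
    )
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return values


def load_labels(path: str | Path) -> np.ndarray:
    mat = load_matrix(path)
    if mat.shape[1] != 1:
        raise ValueError("labels file must contain a single column")
    return mat[:, 0].astype(int)


def save_matrix(arr: np.ndarray, path: str | Path, header: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if header is None:
        np.savetxt(path, np.asarray(arr), delimiter="\t")
    else:
        pd.DataFrame(np.asarray(arr), columns=header).to_csv(path, index=False)
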
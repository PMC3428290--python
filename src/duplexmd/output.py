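"""Tabular output: TSV with a header line and '#'-prefixed provenance comments.

Floats are fixed to 6 significant digits so re-running an identical
configuration reproduces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return f"{v:.6g}"
    return str(v)


def write_tsv(path: str | Path, df: pd.DataFrame, provenance: dict | None = None) -> Path:
    """Write a DataFrame as TSV; provenance key/value pairs become '#' comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k}: {v}" for k, v in (provenance or {}).items()]
    lines.append("\t".join(map(str, df.columns)))
    for row in df.itertuples(index=False):
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
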
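"""Reading and writing counts tables, coordinate tables and results.

Counts are genes x samples, as delimited text (first column = gene ids,
header = sample ids) or matrix-market triplets with sidecar row/column
name files.  Coordinates come from a delimited table keyed by sample id
with an ``x`` column (1-D) or ``x``/``y`` columns (2-D), plus optional
``label`` and ``scale_factor`` columns.  A reader for the
"genes x locations with 'x_y' headers" dialect of spatial counts exports
is also provided: sample ids of the form ``12.5x3.25`` are parsed directly
into 2-D coordinates.

Every results directory gets a machine-readable copy of the resolved
configuration with the package version, seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .gp import CountsDataset

__all__ = ["read_counts", "write_counts", "parse_xy_headers", "write_run_metadata"]


def _validate_counts(df: pd.DataFrame) -> np.ndarray:
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) \
        | (arr.astype(float) != np.round(arr.astype(float)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer or negative count at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {arr[i, j]!r}"
        )
    return arr.astype(np.int64)


def read_counts(path, coords_path=None, fmt: str = "delimited", sep=None) -> CountsDataset:
    """Load a genes x samples counts file, optionally joined to coordinates.

    ``fmt='delimited'`` expects gene ids in the first column and sample ids
    in the header; ``fmt='matrix_market'`` expects ``<path>`` plus sidecar
    ``<path>.rows`` / ``<path>.cols`` name files.  When ``coords_path`` is
    given, its sample ids must cover the counts columns exactly; mismatches
    are reported by id.  Without it, sample ids of the form ``<x>x<y>`` are
    parsed as 2-D coordinates and plain numeric ids as 1-D coordinates.
    """
    path = Path(path)
    if fmt == "delimited":
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    elif fmt == "matrix_market":
        mat = mmread(str(path))
        mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError("format must be 'delimited' or 'matrix_market'")
    counts = _validate_counts(df)
    sample_ids = [str(c) for c in df.columns]

    labels = None
    scale = None
    if coords_path is not None:
        cdf = pd.read_csv(coords_path, sep=sep, engine="python")
        key = cdf.columns[0]
        cdf[key] = cdf[key].astype(str)
        cdf = cdf.set_index(key)
        missing = [s for s in sample_ids if s not in cdf.index]
        if missing:
            raise ValueError(f"sample ids missing from coordinate table: {missing}")
        cdf = cdf.loc[sample_ids]
        if "y" in cdf.columns:
            coords = cdf[["x", "y"]].to_numpy(dtype=float)
        else:
            coords = cdf["x"].to_numpy(dtype=float)
        if "label" in cdf.columns:
            labels = cdf["label"].to_numpy()
        if "scale_factor" in cdf.columns:
            scale = cdf["scale_factor"].to_numpy(dtype=float)
    else:
        coords = parse_xy_headers(sample_ids)
    return CountsDataset(counts=counts, coords=coords,
                         gene_names=[str(g) for g in df.index],
                         sample_names=sample_ids, labels=labels,
                         scale_factors=scale)


def parse_xy_headers(sample_ids):
    """Parse ``'<x>x<y>'`` spatial headers (or plain numbers) to coordinates."""
    first = str(sample_ids[0])
    if "x" in first:
        out = []
        for s in sample_ids:
            a, b = str(s).split("x")
            out.append((float(a), float(b)))
        return np.asarray(out)
    return np.asarray([float(s) for s in sample_ids])


def write_counts(dataset: CountsDataset, path, fmt: str = "delimited") -> None:
    """Write counts as delimited text or matrix-market triplets (+ sidecars)."""
    path = Path(path)
    df = pd.DataFrame(dataset.counts, index=dataset.gene_names,
                      columns=dataset.sample_names)
    if fmt == "delimited":
        df.to_csv(path)
    elif fmt == "matrix_market":
        mmwrite(str(path), csr_matrix(dataset.counts))
        Path(str(path) + ".rows").write_text("\n".join(dataset.gene_names))
        Path(str(path) + ".cols").write_text("\n".join(dataset.sample_names))
    else:
        raise ValueError("format must be 'delimited' or 'matrix_market'")


def write_run_metadata(out_dir, config: dict) -> Path:
    """Persist the resolved config with package version, seed and hash."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(config)
    payload["package_version"] = __version__
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:12]
    path = out_dir / "config.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
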
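"""10x-compatible MatrixMarket persistence for count matrices.

The bundle layout follows Cell Ranger v3: ``matrix.mtx.gz`` (coordinate real,
1-based indices, column-major triplets), ``features.tsv.gz`` (feature id,
feature name, literal "Gene Expression") and ``barcodes.tsv.gz``.  Values are
written as reals because multi-feature molecules carry fractional weights.
Plain-text output (``gzip=False``) is available for inspection and tests.
All output is byte-deterministic: gzip members are written with a zero mtime
and no filename.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .quantifier import CountMatrix

__all__ = ["write_mtx", "read_mtx", "write_csv"]

_FEATURE_TYPE = "Gene Expression"


def _write_bytes(path: Path, payload: bytes, use_gzip: bool) -> None:
    if use_gzip:
        buf = io.BytesIO()
        with gzip.GzipFile(filename="", mode="wb", fileobj=buf, mtime=0) as gz:
            gz.write(payload)
        path.write_bytes(buf.getvalue())
    else:
        path.write_bytes(payload)


def write_mtx(m: CountMatrix, out_dir, use_gzip: bool = True) -> Path:
    """Write the matrix bundle to ``out_dir`` and return that directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if use_gzip else ""

    buf = io.BytesIO()
    scipy.io.mmwrite(buf, m.values.tocsc())  # CSC -> column-major triplets
    _write_bytes(out / f"matrix.mtx{suffix}", buf.getvalue(), use_gzip)

    features = "".join(
        f"{name}\t{name}\t{_FEATURE_TYPE}\n" for name in m.feature_names
    )
    _write_bytes(out / f"features.tsv{suffix}", features.encode(), use_gzip)
    barcodes = "".join(f"{bc}\n" for bc in m.barcodes)
    _write_bytes(out / f"barcodes.tsv{suffix}", barcodes.encode(), use_gzip)
    return out


def _find(out: Path, stem: str) -> Path:
    for name in (f"{stem}.gz", stem):
        p = out / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {out}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_mtx(bundle_dir) -> CountMatrix:
    """Load a bundle written by :func:`write_mtx` (round-trip inverse)."""
    out = Path(bundle_dir)
    mtx_path = _find(out, "matrix.mtx")
    try:
        opener = gzip.open if mtx_path.suffix == ".gz" else open
        with opener(mtx_path, "rb") as fh:
            X = scipy.io.mmread(fh)
    except Exception as err:
        raise ValueError(f"cannot read matrix file {mtx_path}: {err}") from err
    features = [line.split("\t")[1] for line in _read_lines(_find(out, "features.tsv"))]
    barcodes = _read_lines(_find(out, "barcodes.tsv"))
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes file contains duplicates")
    X = sp.csr_matrix(X)
    if X.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix dimensions {X.shape} do not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    return CountMatrix(features, barcodes, X)


def write_csv(m: CountMatrix, path) -> None:
    """Flat wide CSV (features as rows, barcodes as columns) for inspection."""
    pd.DataFrame(m.to_dense(), index=m.feature_names, columns=m.barcodes).to_csv(path)
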
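"""Readers and writers: 10x-style MatrixMarket directories, CSV tables, YAML config.

MTX dialect: the on-disk matrix is genes×cells (vendor orientation) with
1-based MatrixMarket indices, transposed to cells×genes on load.  The
features TSV has columns ``gene_id, gene_name, feature_type``; barcodes TSV
has one barcode per line.  Both may be gzipped.  Truth labels travel in a
sidecar ``cell_metadata.csv``; provenance (package version, seed, config
hash) goes into ``run_manifest.json`` and into ``#``-comment headers on the
package's own CSV outputs (the 10x trio stays header-free for
compatibility).
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from .matrix import LabeledExpressionMatrix

PathLike = Union[str, Path]


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_lines(seed: Optional[int] = None, config: Optional[dict] = None) -> list[str]:
    lines = [f"# ependymap version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


# ----------------------------------------------------------------------
# MTX directories
# ----------------------------------------------------------------------
def read_mtx_dir(path: PathLike) -> LabeledExpressionMatrix:
    """Load a triplet MatrixMarket directory (matrix.mtx + barcodes/features TSVs)."""
    dirpath = Path(path)
    mtx_path = _find(dirpath, "matrix.mtx")
    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    counts = sp.csr_matrix(mat.T)  # stored genes×cells; we work cells×genes

    bc_path = _find(dirpath, "barcodes.tsv")
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    ft_path = _find(dirpath, "features.tsv")
    with _open_maybe_gz(ft_path) as fh:
        features = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    gene_ids = [row[0] for row in features]

    if counts.shape[0] != len(barcodes):
        raise ValueError(
            f"{bc_path.name}: {len(barcodes)} barcodes but matrix has {counts.shape[0]} cells"
        )
    if counts.shape[1] != len(gene_ids):
        raise ValueError(
            f"{ft_path.name}: {len(gene_ids)} features but matrix has {counts.shape[1]} genes"
        )
    dupes = pd.Index(barcodes).duplicated()
    if dupes.any():
        line_no = int(np.flatnonzero(dupes)[0]) + 1
        raise ValueError(f"{bc_path.name}: duplicate barcode at line {line_no}")

    truth = facs = None
    meta_path = dirpath / "cell_metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, comment="#").set_index("cell_id")
        meta = meta.reindex(barcodes)
        if "truth_subtype" in meta.columns and meta["truth_subtype"].notna().any():
            truth = meta["truth_subtype"].to_numpy()
        if "facs_fraction" in meta.columns and meta["facs_fraction"].notna().any():
            facs = meta["facs_fraction"].to_numpy()

    return LabeledExpressionMatrix(
        counts=counts, cell_ids=barcodes, gene_ids=gene_ids,
        truth_subtype=truth, facs_fraction=facs,
    )


def write_mtx_dir(
    matrix: LabeledExpressionMatrix,
    path: PathLike,
    gzipped: bool = False,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> Path:
    """Write the 10x-style trio plus label sidecar and a provenance manifest."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(matrix.counts.T), field="integer")
    raw = buf.getvalue()
    with _open_maybe_gz(dirpath / f"matrix.mtx{suffix}", "wb") as fh:
        fh.write(raw)

    with _open_maybe_gz(dirpath / f"barcodes.tsv{suffix}", "wt") as fh:
        for bc in matrix.cell_ids:
            fh.write(f"{bc}\n")
    with _open_maybe_gz(dirpath / f"features.tsv{suffix}", "wt") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")

    meta = pd.DataFrame(index=matrix.cell_ids)
    if matrix.truth_subtype is not None:
        meta["truth_subtype"] = matrix.truth_subtype
    if matrix.facs_fraction is not None:
        meta["facs_fraction"] = matrix.facs_fraction
    if len(meta.columns):
        with open(dirpath / "cell_metadata.csv", "w") as fh:
            fh.write("\n".join(provenance_lines(seed, config)) + "\n")
            meta.rename_axis("cell_id").to_csv(fh)

    manifest = {
        "ependymap_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "shape_cells_genes": list(matrix.shape),
    }
    (dirpath / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return dirpath


# ----------------------------------------------------------------------
# CSV tables
# ----------------------------------------------------------------------
def write_table_csv(
    frame: pd.DataFrame,
    path: PathLike,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
    index: bool = False,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_lines(seed, config)) + "\n")
        frame.to_csv(fh, index=index, float_format="%.17g")
    return path


def read_table_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_composition_csv(composition, path: PathLike, **kw) -> Path:
    return write_table_csv(composition.table, path, **kw)


def read_composition_csv(path: PathLike):
    from .gating import CompositionTable

    frame = read_table_csv(path)
    remainder = frame["bin"].iloc[-1]
    total = None
    if "n_cells" in frame.columns and frame["n_cells"].notna().all():
        total = int(frame["n_cells"].sum())
    return CompositionTable(table=frame, remainder_name=remainder, total_cells=total)


def write_zstack_csv(counts, path: PathLike, **kw) -> Path:
    return write_table_csv(counts.table, path, **kw)


def read_zstack_csv(path: PathLike):
    from .zstack import ZStackCounts

    return ZStackCounts(read_table_csv(path))


# ----------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------
def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
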
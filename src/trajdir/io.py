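"""Readers and writers for ensembles, loadings and analysis results.

Two input dialects are supported for the attribute matrix: delimited text
(header row of feature ids, first column of cell ids) and Matrix Market
sparse files with sidecar row/column name files (``X.mtx`` +
``X.rows.txt`` + ``X.cols.txt``).  Pseudotime is a two-column table
(cell id, value) joined to the attribute matrix by id.  Results are
written as diff-able JSON plus flat TSV tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path as FilePath
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .analysis import BranchScan, CellEnsemble, TrajectoryResult
from .genes import GeneScoreTable, LoadingMatrix

logger = logging.getLogger("trajdir")

__all__ = [
    "read_ensemble",
    "write_ensemble",
    "read_loadings",
    "write_results",
    "read_results_radii",
]


def _read_delimited(path: FilePath) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else None
    if sep:
        df = pd.read_csv(path, index_col=0, sep=sep,
                         float_precision="round_trip")
    else:
        df = pd.read_csv(path, index_col=0, sep=None, engine="python")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        col = bad[0]
        row = df[pd.to_numeric(df[col], errors="coerce").isna()].index
        raise ValueError(
            f"non-numeric entries in {path} (e.g. cell "
            f"{row[0] if len(row) else '?'}, column {col})")
    return df


def _read_matrix_market(path: FilePath) -> pd.DataFrame:
    mat = mmread(str(path))
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    base = path.with_suffix("")
    rows_file = base.with_suffix(".rows.txt")
    cols_file = base.with_suffix(".cols.txt")
    for f in (rows_file, cols_file):
        if not f.exists():
            raise FileNotFoundError(
                f"Matrix Market sidecar name file missing: {f}")
    row_ids = rows_file.read_text().split()
    col_ids = cols_file.read_text().split()
    return pd.DataFrame(np.asarray(mat), index=row_ids, columns=col_ids)


def read_ensemble(attributes_path, pseudotime_path,
                  fmt: Optional[str] = None) -> CellEnsemble:
    """Load a cell x feature matrix and join its per-cell pseudotime.

    ``fmt`` is "delimited" or "matrix-market"; by default it is inferred
    from the attributes file extension (``.mtx`` -> Matrix Market).  Cells
    present in the attributes but missing a pseudotime value are dropped
    with a logged count; pseudotime rows for unknown cells are ignored
    with a warning.  No overlap at all is a fatal error.
    """
    attributes_path = FilePath(attributes_path)
    pseudotime_path = FilePath(pseudotime_path)
    if fmt is None:
        fmt = ("matrix-market"
               if attributes_path.suffix.lower() == ".mtx" else "delimited")
    if fmt == "delimited":
        attrs = _read_delimited(attributes_path)
    elif fmt == "matrix-market":
        attrs = _read_matrix_market(attributes_path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if pseudotime_path.suffix.lower() == ".csv":
        pt = pd.read_csv(pseudotime_path, float_precision="round_trip")
    else:
        pt = pd.read_csv(pseudotime_path, sep=None, engine="python")
    if pt.shape[1] < 2:
        raise ValueError(
            f"pseudotime file {pseudotime_path} needs two columns "
            "(cell id, value)")
    pt = pt.iloc[:, :2]
    pt.columns = ["cell_id", "pseudotime"]
    pt["cell_id"] = pt["cell_id"].astype(str)
    attrs.index = attrs.index.astype(str)

    unknown = set(pt["cell_id"]) - set(attrs.index)
    if unknown:
        logger.warning("ignoring %d pseudotime rows with unknown cell ids "
                       "(e.g. %s)", len(unknown), sorted(unknown)[0])
    pt = pt[pt["cell_id"].isin(attrs.index)]
    if pt.empty:
        raise ValueError(
            "no overlapping cell ids between attributes and pseudotime")
    missing = len(attrs.index) - pt["cell_id"].nunique()
    if missing:
        logger.info("dropping %d cells without a pseudotime value", missing)
    pt = pt.drop_duplicates("cell_id").set_index("cell_id")
    cells = [c for c in attrs.index if c in pt.index]
    attrs = attrs.loc[cells]
    return CellEnsemble(
        attributes=attrs.to_numpy(dtype=float),
        pseudotime=pt.loc[cells, "pseudotime"].to_numpy(dtype=float),
        cell_ids=list(attrs.index),
        feature_ids=list(attrs.columns),
    )


def write_ensemble(ensemble: CellEnsemble, attributes_path,
                   pseudotime_path, fmt: str = "delimited") -> None:
    """Write an ensemble in either input dialect (round-trippable)."""
    attributes_path = FilePath(attributes_path)
    cell_ids = ensemble.cell_ids or [str(i) for i in range(ensemble.n_cells)]
    feature_ids = (ensemble.feature_ids
                   or [f"f{j}" for j in range(ensemble.n_features)])
    if fmt == "delimited":
        df = pd.DataFrame(ensemble.attributes, index=cell_ids,
                          columns=feature_ids)
        df.to_csv(attributes_path, float_format="%.17g")
    elif fmt == "matrix-market":
        mmwrite(str(attributes_path), csr_matrix(ensemble.attributes))
        base = attributes_path.with_suffix("")
        base.with_suffix(".rows.txt").write_text(
            "\n".join(cell_ids) + "\n")
        base.with_suffix(".cols.txt").write_text(
            "\n".join(feature_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    pd.DataFrame({"cell_id": cell_ids,
                  "pseudotime": ensemble.pseudotime}
                 ).to_csv(pseudotime_path, index=False,
                          float_format="%.17g")


def read_loadings(path) -> LoadingMatrix:
    """Read a gene x component loading matrix from delimited text."""
    path = FilePath(path)
    df = _read_delimited(path)
    return LoadingMatrix(df.to_numpy(dtype=float),
                         [str(g) for g in df.index],
                         [str(c) for c in df.columns])


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(result: Optional[TrajectoryResult] = None,
                  scan: Optional[BranchScan] = None,
                  gene_table: Optional[GeneScoreTable] = None,
                  out_dir=".", config: Optional[dict] = None) -> dict:
    """Write results.json plus flat TSV tables; returns written paths.

    results.json carries every parameter and seed, the per-path radii and
    P-values, the aggregate P, and the per-path centers, at full double
    precision; it contains no timestamps so identical runs produce
    byte-identical files.
    """
    out_dir = FilePath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    payload: dict = {"version": _version(), "config": _jsonable(config or {})}
    if result is not None:
        payload["analysis"] = {
            "parameters": _jsonable(result.parameters),
            "aggregate_p": result.aggregate_p,
            "median_radius": result.median_radius,
            "sampled_radii": _jsonable(result.sampled_radii),
            "p_values": [t.p_value for t in result.per_path_tests],
            "centers": _jsonable(result.centers),
            "mean_center": _jsonable(result.mean_center),
            "n_null_total": int(result.pooled_null_radii.size),
            "null_radius_median":
                float(np.median(result.pooled_null_radii)),
        }
        radii = out_dir / "radii.tsv"
        pd.DataFrame({
            "path_index": np.arange(result.sampled_radii.size),
            "radius": result.sampled_radii,
            "p_value": [t.p_value for t in result.per_path_tests],
        }).to_csv(radii, sep="\t", index=False)
        written["radii"] = radii
    if scan is not None:
        payload["scan"] = {
            "start_fractions": _jsonable(scan.start_fractions),
            "start_values": _jsonable(scan.start_values),
            "median_radii": _jsonable(scan.median_radii),
            "aggregate_ps": _jsonable(scan.aggregate_ps),
            "neg_log10_ps": _jsonable(scan.neg_log10_ps),
            "skipped": _jsonable(scan.skipped),
        }
        ok = ~np.isnan(scan.aggregate_ps)
        scan_path = out_dir / "scan.tsv"
        pd.DataFrame({
            "start_value": scan.start_values[ok],
            "median_radius": scan.median_radii[ok],
            "aggregate_p": scan.aggregate_ps[ok],
            "neg_log10_p": scan.neg_log10_ps[ok],
        }).to_csv(scan_path, sep="\t", index=False)
        written["scan"] = scan_path
    if gene_table is not None:
        gs = out_dir / "gene_scores.tsv"
        gene_table.table.to_csv(gs, sep="\t", index=False)
        written["gene_scores"] = gs
    results_json = out_dir / "results.json"
    with open(results_json, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written["results"] = results_json
    return written


def read_results_radii(path) -> dict:
    """Load the analysis block of a results.json written by write_results."""
    with open(path) as fh:
        payload = json.load(fh)
    if "analysis" not in payload:
        raise ValueError(f"{path} contains no analysis block")
    return payload["analysis"]


def _version() -> str:
    from . import __version__
    return __version__
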
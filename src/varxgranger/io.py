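"""Readers and writers for delimited time series, configs, and results.

Time series travel as headered CSV/TSV (one row per sample); missing
values may be written as an empty field, ``NaN``, ``nan`` or ``NA``.
Fitted filters serialize to the JSON schema of
:class:`~varxgranger.core_model.VARXFilters`; a Granger result is
written as a directory bundle of a JSON summary plus headered CSV
matrices and an edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import MultiSeries, VARXFilters
from .estimation import FitConfig
from .granger_inference import GrangerResult

__all__ = [
    "read_config",
    "read_timeseries",
    "write_timeseries",
    "load_filters",
    "save_filters",
    "save_result_bundle",
]

_NA_MARKERS = ["", "NaN", "nan", "NA"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_config(path) -> dict:
    """Load a JSON or YAML fit configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def fit_config_from(cfg: dict) -> FitConfig:
    return FitConfig(n_a=int(cfg.get("n_a", 0)), n_b=int(cfg.get("n_b", 0)),
                     gamma=float(cfg.get("gamma", 0.0)),
                     n_basis=(int(cfg["n_basis"])
                              if cfg.get("n_basis") is not None else None))


def read_timeseries(path, config: dict) -> MultiSeries:
    """Read a delimited series, selecting and ordering columns per config.

    ``config`` needs ``endogenous`` (list of column names) and may give
    ``exogenous`` and ``segments`` (segment start indices).  Column
    order follows the config, not the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_MARKERS,
                         keep_default_na=True, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    endo = list(config.get("endogenous") or [])
    exo = list(config.get("exogenous") or [])
    if not endo:
        raise ValueError("config must list at least one endogenous variable")
    missing = [c for c in endo + exo if c not in df.columns]
    if missing:
        raise ValueError(f"unknown variable(s) {missing}; file has columns "
                         f"{list(df.columns)}")
    return MultiSeries(
        Y=df[endo].to_numpy(dtype=float),
        X=df[exo].to_numpy(dtype=float) if exo else None,
        names_y=endo, names_x=exo,
        segment_starts=list(config.get("segments") or [0]))


def write_timeseries(path, data: MultiSeries) -> None:
    """Write Y and X side by side with a header row; missing -> NaN."""
    path = Path(path)
    df = pd.DataFrame(np.hstack([data.Y, data.X]),
                      columns=list(data.names_y) + list(data.names_x))
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="NaN")


def load_filters(path) -> VARXFilters:
    return VARXFilters.from_json(Path(path).read_text())


def save_filters(path, filters: VARXFilters) -> None:
    Path(path).write_text(filters.to_json())


def _matrix_csv(path, M, row_names, col_names) -> None:
    pd.DataFrame(M, index=row_names, columns=col_names).to_csv(path)


def save_result_bundle(outdir, result: GrangerResult, provenance: dict) -> Path:
    """Write a Granger result as a directory bundle.

    Contents: summary.json (config, seed, T_used, N, per-channel
    variances), filters.json, headered CSV matrices (A_pval, B_pval,
    A_R2, B_R2, A_deviance, B_deviance), and edges.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ny, nx = list(result.names_y), list(result.names_x)
    summary = {
        "config": {"n_a": result.config.n_a, "n_b": result.config.n_b,
                   "gamma": result.config.gamma,
                   "n_basis": result.config.n_basis,
                   "bias_correction": result.config.debias},
        "T_used": result.T_used, "T_effective": result.T_effective,
        "N": result.N,
        "sigma2": dict(zip(ny, result.sigma2_full.tolist())),
        **provenance,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    save_filters(outdir / "filters.json", result.filters)
    for stem, M, cols in (
            ("A_pval", result.A_pval, ny), ("A_R2", result.A_R2, ny),
            ("A_deviance", result.A_deviance, ny),
            ("B_pval", result.B_pval, nx), ("B_R2", result.B_R2, nx),
            ("B_deviance", result.B_deviance, nx)):
        if M.shape[1]:
            _matrix_csv(outdir / f"{stem}.csv", M, ny, cols)
    result.edges(alpha=provenance.get("alpha")).to_csv(
        outdir / "edges.csv", index=False)
    return outdir
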
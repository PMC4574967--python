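"""Readers, writers and pipeline configuration.

Interchange dialect: tab-separated values with a header row and ``.`` for
missing values.  Every writer here round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .rnaseq import CountMatrix
from .simulate import META_COLUMNS, SimulationParams, default_panel

__all__ = [
    "PipelineConfig",
    "load_config",
    "MalformedTableError",
    "read_cell_table",
    "write_cell_table",
    "read_count_matrix",
    "write_count_matrix",
    "write_table",
    "read_table",
    "write_manifest",
]

NA = "."


class MalformedTableError(ValueError):
    """Raised with the offending file and column when a TSV fails validation."""


@dataclass
class PipelineConfig:
    """Seed, simulation conditions and analysis thresholds for the pipeline."""

    seed: int = 0
    # simulation
    genotypes: tuple[str, ...] = ("wildtype", "stra8_null", "dazl_null",
                                  "kit_null", "stra8_het")
    ages: tuple[float, ...] = (11.5, 12.5, 13.5, 14.0, 14.5, 15.0, 15.5, 16.5)
    cells_per_ovary: int = 300
    n_replicates: int = 3
    dispersion_phi: float = 0.15
    bulk_dispersion_phi: float = 0.04
    ra_sigma: float = 0.4
    wave_anterior_onset: float = 13.0
    wave_span: float = 2.0
    # analysis thresholds
    fpkm_min: float = 5.0
    fc_min: float = 2.0
    q_max: float = 0.01
    alpha: float = 0.05
    k: int = 5
    n_windows: int = 100
    window_frac: float = 0.2
    reference_gene: str = "Stra8"
    include_list: tuple[str, ...] = ("Rec8",)
    # stage toggles
    run_bulk: bool = True
    run_cells: bool = True

    def __post_init__(self) -> None:
        for name in ("fpkm_min", "fc_min", "q_max", "alpha", "window_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            gene_panel=default_panel(),
            wave_anterior_onset=self.wave_anterior_onset,
            wave_span=self.wave_span,
            dispersion_phi=self.dispersion_phi,
            bulk_dispersion_phi=self.bulk_dispersion_phi,
            ra_sigma=self.ra_sigma,
            cells_per_ovary=self.cells_per_ovary,
            ages=tuple(self.ages),
            genotypes=tuple(self.genotypes),
        )


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides (e.g. from CLI flags) win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("genotypes", "ages", "include_list"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cols = META_COLUMNS + [c for c in cells.columns if c not in META_COLUMNS]
    cells[cols].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", na_values=[NA])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedTableError(f"{path}: cannot parse TSV ({exc})") from exc
    if table.empty:
        raise MalformedTableError(f"{path}: empty cell table")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise MalformedTableError(
            f"{path}: missing required columns {missing} (line 1)")
    genes = [c for c in table.columns if c not in META_COLUMNS]
    for col in ("ap_position", "volume"):
        bad = table.index[table[col].isna()]
        if len(bad):
            raise MalformedTableError(
                f"{path}: line {bad[0] + 2}, column {col!r}: missing value")
    if ((table["ap_position"] < 0) | (table["ap_position"] > 1)).any():
        raise MalformedTableError(f"{path}: column 'ap_position' outside [0, 1]")
    if (table["volume"] <= 0).any():
        raise MalformedTableError(f"{path}: column 'volume' must be positive")
    for g in genes:
        vals = table[g]
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise MalformedTableError(
                f"{path}: column {g!r}: counts must be non-negative integers")
        table[g] = vals.astype(int)
    return table


def write_count_matrix(cm: CountMatrix, outdir: str | Path, prefix: str = "bulk") -> dict:
    """Write counts, sample sheet and gene lengths as three TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "samples": outdir / f"{prefix}_samples.tsv",
        "gene_lengths": outdir / f"{prefix}_gene_lengths.tsv",
    }
    cm.counts.to_csv(paths["counts"], sep="\t", na_rep=NA)
    meta = cm.sample_meta.copy()
    meta["library_size"] = cm.library_sizes
    meta.to_csv(paths["samples"], sep="\t", na_rep=NA)
    cm.gene_lengths.rename("length_bp").to_csv(paths["gene_lengths"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def read_count_matrix(
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path,
) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, na_values=[NA])
    if counts.empty:
        raise MalformedTableError(f"{counts_path}: empty count matrix")
    if counts.isna().any().any() or (counts < 0).any().any():
        raise MalformedTableError(
            f"{counts_path}: counts must be non-negative integers")
    meta = pd.read_csv(samples_path, sep="\t", index_col=0, na_values=[NA])
    for col in ("tissue", "genotype", "age"):
        if col not in meta.columns:
            raise MalformedTableError(
                f"{samples_path}: missing required column {col!r}")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length_bp"]
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise MalformedTableError(
            f"{lengths_path}: no length for genes {sorted(missing)[:5]}")
    libs = meta["library_size"] if "library_size" in meta.columns else None
    return CountMatrix(counts=counts.astype(int), sample_meta=meta,
                       gene_lengths=lengths, library_sizes=libs)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep=NA)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], index_col=index_col)


def write_manifest(path: str | Path, config: PipelineConfig, files: list[str]) -> None:
    """JSON provenance record: parameters, seed and every emitted file."""
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "files": sorted(str(f) for f in files),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
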
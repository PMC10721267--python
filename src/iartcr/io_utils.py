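"""Readers/writers, configuration and input validation shared by all stages.

All tabular outputs are plain CSV/TSV with a commented header carrying the
tool version, seed and config hash so any result file is traceable to the
run that produced it. Count matrices are accepted as dense CSV or
MatrixMarket (.mtx with genes/cells sidecars).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .simulate import SimConfig

__all__ = [
    "write_table",
    "read_table",
    "read_counts",
    "write_counts_mtx",
    "config_hash",
    "PipelineConfig",
    "validate_inputs",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None, sep: str = ",") -> None:
    """Write a table with '# key: value' provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a table written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep=sep, comment="#")


def read_counts(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Read a cells x genes count matrix from dense CSV or MatrixMarket.

    For ``.mtx`` input the genes/cells sidecar files (one name per line)
    are required and the matrix is cells x genes.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes and cells sidecar files")
        mat = scipy.io.mmread(path)
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        dense = scipy.sparse.coo_matrix(mat).toarray()
        return pd.DataFrame(dense, index=pd.Index(cells, name="cell_id"), columns=genes)
    df = pd.read_csv(path, comment="#", index_col=0)
    df.index.name = "cell_id"
    return df


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.csr_matrix(counts.to_numpy()))
    (prefix.parent / (prefix.name + ".genes.txt")).write_text("\n".join(counts.columns) + "\n")
    (prefix.parent / (prefix.name + ".cells.txt")).write_text(
        "\n".join(map(str, counts.index)) + "\n"
    )


@dataclass
class PipelineConfig:
    """Paths and stage parameters for the umbrella pipeline.

    With no external inputs the pipeline simulates a cohort first; any
    stage's inputs can instead be supplied externally, and stages without
    inputs are skipped.
    """

    out_dir: str = "iartcr_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    simulate: bool = True
    run_repertoire: bool = True
    run_phenotyping: bool = True
    run_expression: bool = True
    run_outcome: bool = True
    use_truth_clusters: bool = True
    airr_path: str | None = None
    counts_path: str | None = None
    cells_path: str | None = None
    flow_path: str | None = None
    cpeptide_path: str | None = None
    arms_path: str | None = None
    db_path: str | None = None
    strict_vj: bool = False
    shrink_decay: bool = False
    n_permutations: int = 10_000
    de_alpha: float = 0.1
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_REQUIRED = {
    "airr": ["cell_id", "participant_id", "locus", "v_call", "j_call", "junction", "junction_aa", "productive"],
    "cells": ["cell_id", "participant_id", "cluster"],
    "cpeptide": ["participant_id", "month", "auc"],
    "arms": ["participant_id", "arm"],
}


def validate_inputs(
    airr: pd.DataFrame | None = None,
    cells: pd.DataFrame | None = None,
    flow: pd.DataFrame | None = None,
    cpeptide: pd.DataFrame | None = None,
    arms: pd.DataFrame | None = None,
) -> list[str]:
    """Schema and cross-table key checks; returns a list of problems."""
    problems: list[str] = []
    tables = {"airr": airr, "cells": cells, "cpeptide": cpeptide, "arms": arms}
    for name, df in tables.items():
        if df is None:
            continue
        for col in _REQUIRED[name]:
            if col not in df.columns:
                problems.append(f"{name}: missing required column {col!r}")
    if cpeptide is not None and "auc" in cpeptide.columns:
        if pd.to_numeric(cpeptide["auc"], errors="coerce").isna().any():
            problems.append("cpeptide: non-numeric values in 'auc'")
    if flow is not None and flow.select_dtypes(exclude="number").shape[1] == flow.shape[1]:
        problems.append("flow: no numeric marker columns found")
    if arms is not None and "participant_id" in arms.columns:
        known = set(arms["participant_id"])
        for name, df in (("cells", cells), ("cpeptide", cpeptide), ("airr", airr)):
            if df is not None and "participant_id" in df.columns:
                unknown = sorted(set(df["participant_id"]) - known)
                if unknown:
                    problems.append(
                        f"{name}: participants not present in the arm table: {unknown}"
                    )
    return problems
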
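"""Readers and writers for every on-disk format the pipeline touches.

All tables are TSV, UTF-8, '.' decimal separator.  Reals round-trip within
1e-9.  Malformed inputs are rejected with messages naming the offending
line, sample or field.

Formats
-------
expression   first column feature id (probe_id or gene), one column per sample
phenotype    columns: sample_id, group in {control, treated}
probe map    columns: probe_id, gene_symbol (many probes per gene allowed)
GMT          set_id <tab> description <tab> member genes...
hierarchy    columns: child_id, parent_id (Reactome relations dialect)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .enrichment import PathwayCatalog
from .preprocess import CohortDataset, ExpressionMatrix, looks_raw


def _require(path: str | Path) -> Path:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"missing input file: {path}")
    return path


def read_expression(path: str | Path, scale: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV.  ``scale=None`` applies the heuristic:
    a maximum above 50 marks raw (linear) intensities."""
    path = _require(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: malformed header — no sample columns found")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature identifier {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample identifier {dup!r}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    matrix = ExpressionMatrix(frame, scale=scale or "log2")
    if scale is None and looks_raw(matrix):
        matrix = ExpressionMatrix(frame, scale="raw")
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.data.copy()
    if frame.index.name is None:
        frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_phenotype(path: str | Path) -> dict[str, str]:
    """Read a phenotype TSV into a sample -> group mapping."""
    path = _require(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise ValueError(f"{path}: malformed header — missing column {col!r}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicated sample identifier {dup!r}")
    bad = set(frame["group"]) - {"control", "treated"}
    if bad:
        raise ValueError(f"{path}: unknown group label(s) {sorted(bad)}")
    return dict(zip(frame["sample_id"], frame["group"]))


def write_phenotype(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def load_cohort(
    expr_path: str | Path,
    pheno_path: str | Path,
    cohort_id: str | None = None,
    scale: str | None = None,
) -> CohortDataset:
    """Read and cross-validate one cohort's expression + phenotype pair."""
    matrix = read_expression(expr_path, scale=scale)
    groups = read_phenotype(pheno_path)
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValueError(
            f"{pheno_path}: sample {missing[0]!r} from {expr_path} has no phenotype row"
        )
    cid = cohort_id or Path(expr_path).stem.replace("_expression", "")
    return CohortDataset(matrix=matrix, groups=groups, cohort_id=cid)


def read_probe_map(path: str | Path) -> dict[str, str]:
    path = _require(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in frame.columns:
            raise ValueError(f"{path}: malformed header — missing column {col!r}")
    if frame["probe_id"].duplicated().any():
        dup = frame.loc[frame["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: probe {dup!r} mapped more than once")
    return dict(zip(frame["probe_id"], frame["gene_symbol"]))


def write_probe_map(probe_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_map), "gene_symbol": list(probe_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> PathwayCatalog:
    """Read gene sets from the standard GMT dialect (id, description, members)."""
    path = _require(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                    "need set_id, description and at least one member"
                )
            sid, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set id {sid!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: set {sid!r} has no members")
            sets[sid] = (desc, frozenset(members))
    return PathwayCatalog(sets=sets)


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for sid, (desc, members) in catalog.sets.items():
            handle.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def read_hierarchy(path: str | Path) -> list[tuple[str, str]]:
    path = _require(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("child_id", "parent_id"):
        if col not in frame.columns:
            raise ValueError(f"{path}: malformed header — missing column {col!r}")
    return list(zip(frame["child_id"], frame["parent_id"]))


def write_hierarchy(edges: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["child_id", "parent_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    path = _require(path)
    with open(path, encoding="utf-8") as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.writelines(f"{g}\n" for g in genes)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(_require(path), sep="\t", index_col=index_col)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(_require(path), encoding="utf-8") as handle:
        return json.load(handle)
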
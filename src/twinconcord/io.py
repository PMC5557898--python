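"""Readers and writers for the plain-text formats the pipeline uses.

Everything is TSV with documented headers; outputs carry comment
headers recording the tool version, config hash and seed, which the
readers skip.  A GEO series-matrix reader is included for deposited
expression tables (tab-delimited, "!"-prefixed metadata, table fenced
by series_matrix_table_begin/end); the sample->pair mapping always
comes from a sidecar TSV because series-matrix metadata does not encode
pairing machine-readably.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import __version__
from .concordance import TwinPairRecord, frame_from_pairs, pairs_from_frame
from .expression import PairedExpressionMatrix
from .simulate import GeneratorConfig
from .tracing import TracedBlastocyst

logger = logging.getLogger(__name__)

__all__ = [
    "config_hash",
    "output_header",
    "write_config_yaml",
    "read_config_yaml",
    "write_lineage_tsv",
    "read_lineage_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "read_series_matrix",
    "write_pair_map_tsv",
    "read_pair_map_tsv",
    "write_tracing_tsv",
    "read_tracing_tsv",
    "write_outcomes_tsv",
    "read_outcomes_tsv",
    "write_ranked_list",
    "read_ranked_list",
]


def config_hash(config: GeneratorConfig | dict) -> str:
    """Short stable hash of a configuration (first 12 hex digits of SHA-256)."""
    d = config.to_dict() if isinstance(config, GeneratorConfig) else dict(config)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(seed: int | None = None, cfg_hash: str | None = None) -> str:
    """Comment header stamped on every output file."""
    lines = [f"# twinconcord v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash={cfg_hash}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path: str | Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def write_config_yaml(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# twinconcord v{__version__}\n")
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config_yaml(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return GeneratorConfig.from_dict(d)


def write_lineage_tsv(
    pairs: list[TwinPairRecord], path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    """Long-format pair table: pair_id zygosity member te epi pend condition."""
    _write_frame(frame_from_pairs(pairs), path, output_header(seed, cfg_hash))


def read_lineage_tsv(path: str | Path) -> list[TwinPairRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return pairs_from_frame(df)


def write_pair_map_tsv(
    pair_map: pd.Series,
    path: str | Path,
    group: pd.Series | None = None,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Two-column sample_id/pair_id map (plus optional group column)."""
    df = pd.DataFrame({"sample_id": pair_map.index, "pair_id": pair_map.values})
    if group is not None:
        all_samples = group.index
        df = pd.DataFrame(
            {
                "sample_id": all_samples,
                "pair_id": [pair_map.get(s, "") for s in all_samples],
                "group": group.values,
            }
        )
    _write_frame(df, path, output_header(seed, cfg_hash))


def read_pair_map_tsv(path: str | Path) -> tuple[pd.Series, pd.Series | None]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if not {"sample_id", "pair_id"} <= set(df.columns):
        raise ValueError("pair map needs columns sample_id and pair_id")
    paired = df[df["pair_id"] != ""]
    pair_map = pd.Series(paired["pair_id"].values, index=paired["sample_id"].values)
    group = None
    if "group" in df.columns:
        group = pd.Series(df["group"].values, index=df["sample_id"].values)
    return pair_map, group


def write_expression_tsv(
    matrix: PairedExpressionMatrix,
    matrix_path: str | Path,
    pair_map_path: str | Path | None = None,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Genes x samples TSV (first column ``gene``) plus sidecar pair map."""
    df = matrix.values.copy()
    df.index.name = "gene"
    _write_frame(df, matrix_path, output_header(seed, cfg_hash), index=True)
    if pair_map_path is not None:
        write_pair_map_tsv(matrix.pair_map, pair_map_path, matrix.group, seed, cfg_hash)


def _aggregate_duplicates(
    values: pd.DataFrame, rule: Literal["max_variance", "mean"]
) -> pd.DataFrame:
    dup_mask = values.index.duplicated(keep=False)
    if not dup_mask.any():
        return values
    n_dup = int(values.index[dup_mask].nunique())
    logger.warning("aggregating %d duplicated gene symbol(s) by rule %r", n_dup, rule)
    if rule == "mean":
        return values.groupby(level=0, sort=False).mean()
    if rule == "max_variance":
        variances = values.var(axis=1).to_numpy()
        keep = (
            pd.DataFrame({"gene": values.index, "var": variances, "row": range(len(values))})
            .sort_values(["gene", "var", "row"], ascending=[True, False, True])
            .drop_duplicates("gene")["row"]
            .sort_values()
        )
        return values.iloc[keep.to_numpy()]
    raise ValueError(f"unknown duplicate-aggregation rule: {rule!r}")


def _build_matrix(
    values: pd.DataFrame,
    pair_map_path: str | Path | None,
    scale: Literal["linear", "log2"],
    duplicate_rule: Literal["max_variance", "mean"],
) -> PairedExpressionMatrix:
    values = _aggregate_duplicates(values, duplicate_rule)
    if pair_map_path is not None:
        pair_map, group = read_pair_map_tsv(pair_map_path)
    else:
        pair_map, group = pd.Series(dtype=object), None
    missing = set(pair_map.index) - set(values.columns)
    if missing:
        raise ValueError(f"pair map references samples absent from the matrix: {sorted(missing)}")
    counts = pair_map.value_counts()
    singletons = counts[counts != 2]
    if not singletons.empty:
        raise ValueError(
            "pairs without exactly two samples: "
            + ", ".join(f"{p} (n={c})" for p, c in singletons.items())
        )
    return PairedExpressionMatrix(values=values, pair_map=pair_map, group=group, scale=scale)


def read_expression_tsv(
    matrix_path: str | Path,
    pair_map_path: str | Path | None = None,
    scale: Literal["linear", "log2"] = "linear",
    duplicate_rule: Literal["max_variance", "mean"] = "max_variance",
) -> PairedExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbols)."""
    df = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return _build_matrix(df, pair_map_path, scale, duplicate_rule)


def read_series_matrix(
    path: str | Path,
    pair_map_path: str | Path | None = None,
    scale: Literal["linear", "log2"] = "log2",
    duplicate_rule: Literal["max_variance", "mean"] = "max_variance",
) -> PairedExpressionMatrix:
    """Read a GEO series-matrix expression table.

    Tolerates "!"-prefixed metadata lines and quoted identifiers; only
    the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is parsed.  Deposited RMA tables are
    log2-scale, hence the default.
    """
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.lower().startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table and stripped:
                table_lines.append(line)
    if not table_lines:
        raise ValueError(f"no series_matrix table found in {path}")
    df = pd.read_csv(_io.StringIO("".join(table_lines)), sep="\t", quotechar='"', index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return _build_matrix(df, pair_map_path, scale, duplicate_rule)


def write_tracing_tsv(
    records: list[TracedBlastocyst],
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Columns: embryo_id, epi_green, epi_red, total_cells, cohort."""
    df = pd.DataFrame(
        {
            "embryo_id": [r.embryo_id for r in records],
            "epi_green": [r.epi_a for r in records],
            "epi_red": [r.epi_b for r in records],
            "total_cells": [r.total_cells if r.total_cells is not None else "" for r in records],
            "cohort": [r.cohort if r.cohort is not None else "" for r in records],
        }
    )
    _write_frame(df, path, output_header(seed, cfg_hash))


def read_tracing_tsv(path: str | Path) -> list[TracedBlastocyst]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        total = row.get("total_cells")
        total = int(total) if pd.notna(total) and total != "" else None
        cohort = row.get("cohort")
        cohort = str(cohort) if pd.notna(cohort) and cohort != "" else None
        records.append(
            TracedBlastocyst(
                embryo_id=str(row["embryo_id"]),
                epi_a=int(row["epi_green"]),
                epi_b=int(row["epi_red"]),
                total_cells=total,
                cohort=cohort,
            )
        )
    return records


def write_outcomes_tsv(
    outcomes: pd.DataFrame, path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    """Columns: pair_id, member, stage."""
    _write_frame(outcomes, path, output_header(seed, cfg_hash))


def read_outcomes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"pair_id", "member", "stage"} <= set(df.columns):
        raise ValueError("outcome table needs columns pair_id, member, stage")
    return df


def write_ranked_list(ranked: pd.DataFrame, path: str | Path) -> None:
    """Two-column (gene, score) ranked list for GSEA/GOrilla-style tools."""
    ranked.to_csv(path, sep="\t", index=False, header=False)


def read_ranked_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
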
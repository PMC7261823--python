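"""Typed readers and writers for every table the pipeline consumes or emits.

All tabular formats are delimiter-separated text with a header row,
UTF-8, '.' decimal, floats at 9 significant digits; lines starting with
'#' are metadata comments (the pipeline stamps a config hash there).
Readers validate the declared schema and raise structured errors naming
the offending file and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .quant import TMT_CHANNELS, ProteinRatioMatrix

FLOAT_FMT = "%.9g"

PSM_COLUMNS = ["psm_id", "gene", "unique", "set_id"] + TMT_CHANNELS
PLATE_COLUMNS = ["plate_id", "well", "compound", "arm", "conc_molar", "signal", "control"]
CHIP_COLUMNS = ["gene", "experiment_id"]


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _write(df: pd.DataFrame, path: str | Path, sep: str, index: bool = False,
           config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=sep, index=index, float_format=FLOAT_FMT, lineterminator="\n")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, PSM_COLUMNS, path)
    if df["psm_id"].duplicated().any():
        dups = df.loc[df["psm_id"].duplicated(), "psm_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate psm_id values {dups}")
    df["unique"] = df["unique"].astype(bool)
    return df[PSM_COLUMNS]


def write_psm_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write(df[PSM_COLUMNS], path, "\t", config_hash=config_hash)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["gene"], path)
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()[:5]
        raise ValueError(f"{path}: duplicate gene rows {dups}")
    out = df.set_index("gene")
    bad = [c for c in out.columns if not np.issubdtype(out[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric count column(s) {bad}")
    return out


def write_count_matrix(counts: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write(counts.rename_axis("gene").reset_index(), path, "\t", config_hash=config_hash)


def read_plate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=",", comment="#")
    _require_columns(df, PLATE_COLUMNS, path)
    bad = sorted(set(df["control"]) - {"none", "neg", "pos"})
    if bad:
        raise ValueError(f"{path}: invalid control flag(s) {bad}; expected none/neg/pos")
    return df[PLATE_COLUMNS]


def write_plate_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write(df[PLATE_COLUMNS], path, ",", config_hash=config_hash)


def read_chip_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, CHIP_COLUMNS, path)
    return df[CHIP_COLUMNS].drop_duplicates()


def write_chip_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write(df[CHIP_COLUMNS], path, "\t", config_hash=config_hash)


def read_annotation(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, columns, path)
    return df[columns]


def write_annotation(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write(df, path, "\t", config_hash=config_hash)


def read_gene_list(path: str | Path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes...

    Raises on lines with fewer than three fields, naming the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >=3")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description] + sorted(sets[name])) + "\n")


def read_ratio_matrix(path: str | Path) -> ProteinRatioMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["gene", "n_psms"], path)
    df = df.set_index("gene")
    n_psms = df.pop("n_psms")
    return ProteinRatioMatrix(values=df, n_psms=n_psms)


def write_ratio_matrix(matrix: ProteinRatioMatrix, path: str | Path,
                       config_hash: str | None = None) -> None:
    out = matrix.values.copy()
    out["n_psms"] = matrix.n_psms
    _write(out.rename_axis("gene").reset_index(), path, "\t", config_hash=config_hash)


def read_dea(path: str | Path) -> pd.DataFrame:
    from .dea import DEA_COLUMNS

    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, DEA_COLUMNS, path)
    df["significant"] = df["significant"].astype(bool)
    return df[DEA_COLUMNS]


def write_dea(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write(df, path, "\t", config_hash=config_hash)


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Generic result-table writer (TSV)."""
    _write(df, path, "\t", config_hash=config_hash)
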
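"""Readers and writers for the package's plain-text formats.

Dialects:

* predictions TSV — header ``mirna<TAB>gene<TAB>score`` (an optional
  ``rank`` column is accepted for pre-ranked lists);
* labels TSV — header ``mirna<TAB>gene``, one validated pair per row;
* GMT — one pathway per line: id, description, then member gene ids;
* alias map TSV — header ``alias<TAB>canonical``;
* source config — JSON or YAML with a ``sources`` list of
  ``{name, path, direction}`` entries;
* metrics/reports — JSON with sorted keys.

Readers validate headers and report offending line numbers so scores and
labels can never be silently misaligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import SourceList

__all__ = [
    "Pathway",
    "read_predictions",
    "write_predictions",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_alias_map",
    "read_source_config",
    "load_sources",
    "write_metrics",
    "read_metrics",
]


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    genes: tuple[str, ...]


def _read_table(path, required, optional=()):
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[: len(required)] != list(required):
        raise FormatError(
            f"{path}: expected header starting with {list(required)}, found {cols}"
        )
    return df


def read_predictions(path) -> pd.DataFrame:
    """Read a predictions TSV (mirna, gene, score[, rank])."""
    path = Path(path)
    df = _read_table(path, ("mirna", "gene", "score"), optional=("rank",))
    try:
        df["score"] = df["score"].astype(float)
    except ValueError:
        bad = pd.to_numeric(df["score"], errors="coerce").isna()
        line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: non-numeric score on line {line}") from None
    if not np.all(np.isfinite(df["score"])):
        line = int(np.flatnonzero(~np.isfinite(df["score"]))[0]) + 2
        raise FormatError(f"{path}: non-finite score on line {line}")
    dup = df.duplicated(["mirna", "gene"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise FormatError(f"{path}: duplicate (mirna, gene) row on line {line}")
    if "rank" in df.columns:
        df["rank"] = df["rank"].astype(float)
    return df


def write_predictions(df: pd.DataFrame, path) -> Path:
    """Write a scored table; floats use a fixed 10-significant-digit format."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_labels(path) -> pd.DataFrame:
    """Read a validated-pair TSV (mirna, gene)."""
    path = Path(path)
    df = _read_table(path, ("mirna", "gene"))
    dup = df.duplicated(["mirna", "gene"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise FormatError(f"{path}: duplicate validated pair on line {line}")
    return df[["mirna", "gene"]]


def write_labels(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[["mirna", "gene"]].to_csv(path, sep="\t", index=False)
    return path


def read_gmt(path) -> list[Pathway]:
    """Read a GMT gene-set file: id, description, then member genes."""
    path = Path(path)
    pathways: list[Pathway] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            pid, name, genes = parts[0], parts[1], tuple(g for g in parts[2:] if g)
            if pid in seen:
                raise FormatError(f"{path}: duplicate pathway id {pid!r} on line {lineno}")
            seen.add(pid)
            pathways.append(Pathway(pathway_id=pid, name=name, genes=genes))
    return pathways


def write_gmt(pathways: list[Pathway], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *p.genes]) + "\n")
    return path


def read_alias_map(path, kind: str):
    """Read a two-column alias -> canonical TSV into an :class:`AliasMap`."""
    from .annotation import AliasMap

    path = Path(path)
    df = _read_table(path, ("alias", "canonical"))
    return AliasMap.from_pairs(zip(df["alias"], df["canonical"]), kind=kind)


def read_source_config(path) -> list[dict]:
    """Read a JSON/YAML sources config; paths resolve relative to the file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "sources" not in data:
        raise FormatError(f"{path}: config must contain a 'sources' list")
    entries = []
    for entry in data["sources"]:
        if not {"name", "path", "direction"} <= set(entry):
            raise FormatError(f"{path}: each source needs name, path, direction")
        resolved = dict(entry)
        resolved["path"] = str((path.parent / entry["path"]).resolve())
        entries.append(resolved)
    return entries


def load_sources(config_path) -> list[SourceList]:
    """Load every source declared in a config into SourceList objects."""
    out = []
    for entry in read_source_config(config_path):
        df = read_predictions(entry["path"])
        out.append(SourceList(name=entry["name"], entries=df, direction=entry["direction"]))
    return out


def write_metrics(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_metrics(path) -> dict:
    return json.loads(Path(path).read_text())
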
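"""File formats: TSV matrices, labels, GMT gene sets, pathway/truth JSON,
YAML configuration.

All tabular artifacts are tab-separated with a header row and an id column;
missing categorical values are written as the literal "NA".  Numeric text is
written with 6 significant digits, which round-trips at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import SpectrumSet


def write_matrix(matrix: pd.DataFrame, path, index_name: str = "id") -> None:
    df = pd.DataFrame(matrix)
    df = df.copy()
    df.index.name = df.index.name or index_name
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix with an id column; errors name the offending line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        ncol = header.count("\t") + 1
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and line.count("\t") + 1 != ncol:
                raise ValueError(f"{path}:{lineno}: ragged row")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        lineno = int(np.nonzero(df.index == dup)[0][1]) + 2
        raise ValueError(f"{path}:{lineno}: duplicate id {dup!r}")
    return df


def write_spectra(spectra: SpectrumSet, path) -> None:
    """Spectra TSV: first column sample_id, header = ppm values at 4 decimals."""
    df = pd.DataFrame(
        spectra.intensities,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{x:.4f}" for x in spectra.ppm],
    )
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_spectra(path) -> SpectrumSet:
    df = read_matrix(path)
    ppm = np.array([float(c) for c in df.columns])
    return SpectrumSet(ppm, df.to_numpy(dtype=float), [str(s) for s in df.index])


def write_labels(labels: pd.DataFrame | pd.Series, path) -> None:
    df = pd.DataFrame(labels)
    df.index.name = df.index.name or "sample_id"
    df.fillna("NA").to_csv(path, sep="\t")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: set_name TAB description TAB members...; duplicate members are
    collapsed with a warning."""
    import warnings

    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, _desc, *members = fields
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) != len([m for m in members if m]):
                warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} collapsed")
            sets[name] = unique
    return sets


def write_pathways(pathways: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(pathways, fh, indent=1)


def read_pathways(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


__all__ = [
    "read_matrix", "write_matrix",
    "read_spectra", "write_spectra",
    "read_labels", "write_labels",
    "read_gmt", "write_gmt",
    "read_pathways", "write_pathways",
    "read_json", "write_json",
    "read_yaml", "write_yaml",
]
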
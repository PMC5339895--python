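"""Tabular I/O for catalogs, level matrices, FPKM tables and mixtures.

Every TSV written by the pipeline starts with ``#``-prefixed header
comments carrying the tool version, seed and a parameter digest; all
readers here skip such lines. Catalog positions are 1-based in files and
converted at this boundary only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .synthetic import site_key


def params_digest(params: dict) -> str:
    """Short stable digest of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_comment(seed: int | None, params: dict | None = None) -> str:
    digest = params_digest(params or {})
    return f"# editomix v{__version__} seed={seed} params={digest}\n"


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None, params: dict | None = None, index: bool = True) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header_comment(seed, params))
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a site-catalog TSV (chrom, pos 1-based, strand, gene, conserved)."""
    cat = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "strand", "gene", "conserved"}
    missing = required - set(cat.columns)
    if missing:
        raise ValueError(f"catalog {path} lacks columns: {sorted(missing)}")
    bad = ~cat["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"catalog {path}: invalid strand values at rows {list(cat.index[bad])}")
    cat.index = [site_key(r.chrom, r.pos, r.strand) for r in cat.itertuples()]
    cat.index.name = "site"
    dup = cat.index.duplicated()
    if dup.any():
        cat = cat[~dup]
    return cat


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read a long FPKM TSV (gene, sample, value) into (gene x sample)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "sample", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"FPKM table {path} needs columns {sorted(required)}")
    return df.pivot_table(index="gene", columns="sample", values="value")


def read_mixture_yaml(path: str | Path) -> dict[str, dict[str, float]]:
    """Read named mixtures from YAML: {name: {cell_type: fraction}}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"mixture file {path} must map names to fraction maps")
    return {str(k): {str(c): float(f) for c, f in v.items()} for k, v in data.items()}
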
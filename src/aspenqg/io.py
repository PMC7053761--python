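"""CSV readers and writers for phenotype, pedigree, clone-map and score tables.

All formats are plain CSV with a header.  Output files carry ``# key=value``
metadata comment lines (seed, config hash) that the readers skip.  The score
reader accepts the deposited-supplement dialect in which a variable-
description preamble precedes the header row; the preamble length is
auto-detected by locating the first line containing the mapped key columns.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .pedigree import CloneMap, Pedigree, build_pedigree
from .phenology import trial_doy_table


class SchemaError(ValueError):
    """A required column is missing; the message lists the candidates found."""


def config_hash(config: Mapping) -> str:
    js = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha1(js.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: Optional[Mapping] = None) -> None:
    """Write a CSV with ``# key=value`` metadata lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_phenotypes(path, mapping: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read a phenotype table (one row per tree) and normalise column names.

    ``mapping`` maps canonical names (``tree, family, rep, block, plot,
    genotype`` and trait names) to the file's column names.  Raises
    :class:`SchemaError` naming the available columns when a mapped column
    is absent or the file is empty.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"{path}: empty file") from e
    if df.empty and len(df.columns) == 0:
        raise SchemaError(f"{path}: no columns found")
    mapping = dict(mapping or {})
    rename = {v: k for k, v in mapping.items()}
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; available: {list(df.columns)}")
    return df.rename(columns=rename)


def read_pedigree(path) -> Tuple[Pedigree, List[Tuple[str, object, object]]]:
    """Read ``id,sire,dam`` CSV (0/empty = unknown) into a validated pedigree."""
    df = read_phenotypes(path)
    for c in ("id", "sire", "dam"):
        if c not in df.columns:
            raise SchemaError(f"{path}: pedigree needs columns id,sire,dam; "
                              f"found {list(df.columns)}")
    records = [
        (r.id, None if pd.isna(r.sire) else r.sire, None if pd.isna(r.dam) else r.dam)
        for r in df.itertuples()
    ]
    return build_pedigree(records), records


def read_clone_map(path) -> CloneMap:
    """Read ``tree_id,genotype_id`` CSV into a :class:`CloneMap`."""
    df = read_phenotypes(path)
    cols = list(df.columns)
    tree_c = "tree_id" if "tree_id" in cols else cols[0]
    geno_c = "genotype_id" if "genotype_id" in cols else cols[1]
    return CloneMap(dict(zip(df[tree_c].astype(str), df[geno_c].astype(str))))


def read_scores(
    path,
    mapping: Optional[Mapping[str, str]] = None,
    max_preamble: int = 50,
) -> pd.DataFrame:
    """Read a repeated-scores CSV, skipping any description preamble.

    The header row is detected as the first line (within ``max_preamble``
    lines) whose comma-split fields contain all mapped key columns
    (default ``trial, tree, trait``).  Date columns are named ``d<DoY>``.
    """
    mapping = dict(mapping or {})
    keys = [mapping.get(k, k) for k in ("trial", "tree", "trait")]
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    header_row = None
    for i, line in enumerate(lines[:max_preamble]):
        fields = [f.strip().strip('"') for f in line.rstrip("\n").split(",")]
        if all(k in fields for k in keys):
            header_row = i
            break
    if header_row is None:
        raise SchemaError(f"{path}: no header containing {keys} in the first "
                          f"{max_preamble} lines")
    df = pd.read_csv(_io.StringIO("".join(lines[header_row:])))
    rename = {v: k for k, v in mapping.items()}
    return df.rename(columns=rename)


def phenotypes_with_doy(
    phenotypes: pd.DataFrame,
    scores: pd.DataFrame,
    tree_col: str = "tree",
) -> pd.DataFrame:
    """Attach per-tree ``<trait>_doy`` columns derived from a score table."""
    tidy = trial_doy_table(scores, tree_col=tree_col)
    out = phenotypes.copy()
    for trait, sub in tidy.groupby("trait"):
        col = sub.set_index(tree_col)["doy"]
        out[f"{trait}_doy"] = out[tree_col].map(col)
    return out


def write_dataset(ds, outdir, seed: Optional[int] = None) -> Dict[str, Path]:
    """Write a simulated :class:`~aspenqg.synthetic_data.TrialDataset` to CSVs."""
    outdir = Path(outdir)
    meta = {"trial": ds.trial}
    if seed is not None:
        meta["seed"] = seed
    meta["config_hash"] = config_hash({"trial": ds.trial, "seed": seed})
    paths = {}
    ped = pd.DataFrame(
        [(i, s or 0, d or 0) for i, s, d in ds.pedigree_records],
        columns=["id", "sire", "dam"])
    paths["pedigree"] = outdir / f"trial{ds.trial}_pedigree.csv"
    write_csv(ped, paths["pedigree"], meta)
    cm = pd.DataFrame(
        sorted(ds.clone_map.tree_to_genotype.items()),
        columns=["tree_id", "genotype_id"])
    paths["clone_map"] = outdir / f"trial{ds.trial}_clonemap.csv"
    write_csv(cm, paths["clone_map"], meta)
    paths["phenotypes"] = outdir / f"trial{ds.trial}_phenotypes.csv"
    write_csv(ds.phenotypes, paths["phenotypes"], meta)
    if len(ds.scores):
        paths["scores"] = outdir / f"trial{ds.trial}_scores.csv"
        write_csv(ds.scores, paths["scores"], meta)
    return paths
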
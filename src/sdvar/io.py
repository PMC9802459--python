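"""Readers and writers for the formats the analyses exchange.

Counts travel as TSV (genes x samples with a header row of sample ids) or
MatrixMarket coordinate files with ``.genes.txt`` / ``.samples.txt`` id
sidecars; gene sets as standard GMT (name, description, tab-separated
members); per-sample metadata and result tables as TSV. Every result-writing
call drops a JSON provenance sidecar (config, seed, package version) next to
its outputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_results",
]


def _check_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()[:5]
        raise ValueError(f"{source}: duplicate gene ids, e.g. {dup}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{source}: non-numeric cells present")
    bad = ~np.isfinite(arr) | (arr != np.floor(arr)) | (arr < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{source}: invalid count at gene {df.index[i]!r}, sample "
            f"{df.columns[j]!r}: {arr[i, j]!r} (counts must be nonnegative integers)"
        )
    return df.astype(np.int64)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Load a genes x samples integer count matrix from TSV or MatrixMarket."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        genes = Path(str(path) + ".genes.txt").read_text().split()
        samples = Path(str(path) + ".samples.txt").read_text().split()
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene"
    return _check_counts(df, str(path))


def write_counts(counts: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write counts as TSV or as MatrixMarket plus id sidecars."""
    path = Path(path)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(counts.to_numpy()))
        Path(str(path) + ".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(str(path) + ".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file; duplicate members deduplicated with a warning."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT lines need name, description and >= 1 member")
        name, members = fields[0], fields[2:]
        members = [m for m in members if m]
        uniq = list(dict.fromkeys(members))
        if len(uniq) < len(members):
            warnings.warn(f"{path}:{ln}: duplicate members in set {name!r} deduplicated")
        if not uniq:
            warnings.warn(f"{path}:{ln}: set {name!r} is empty; retained")
        sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(members) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    force: bool = False,
) -> list[Path]:
    """Write result tables as TSV (floats at 6 significant digits) plus a
    provenance JSON sidecar recording config, seed and package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        target = out_dir / f"{name}.tsv"
        if target.exists() and not force:
            raise FileExistsError(f"{target} exists; pass force=True / --force to overwrite")
        df.to_csv(target, sep="\t", float_format="%.6g")
        written.append(target)
    prov = {
        "config": config or {},
        "seed": seed,
        "version": __version__,
        "tables": {name: int(len(df)) for name, df in tables.items()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str) + "\n")
    return written
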
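"""Readers and writers for 10x-style Matrix Market directories and GMT files."""

from __future__ import annotations

import gzip
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CountMatrix

__all__ = [
    "read_tenx_mtx",
    "write_tenx_directory",
    "read_gmt",
    "write_gmt",
    "GeneSetCollection",
]


class GeneSetCollection:
    """Named gene sets restricted to a gene universe.

    Sets are stored as-is; :meth:`restrict` intersects them with a universe and
    warns about (and drops) sets left empty.
    """

    def __init__(self, sets: dict, universe=None):
        self.sets = {name: list(genes) for name, genes in sets.items()}
        self.universe = set(universe) if universe is not None else None

    def restrict(self, universe) -> "GeneSetCollection":
        universe = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in universe]
            if not inter:
                warnings.warn(f"gene set {name!r} empty after universe intersection; dropped")
                continue
            kept[name] = inter
        return GeneSetCollection(kept, universe)

    def __getitem__(self, name):
        return self.sets[name]

    def __contains__(self, name):
        return name in self.sets

    def __len__(self):
        return len(self.sets)

    def names(self):
        return sorted(self.sets)


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(directory: Path, stem: str) -> Path:
    """Locate ``stem`` with any of the common 10x suffixes."""
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {directory}")


def read_tenx_mtx(path, donor: str | None = None) -> CountMatrix:
    """Read one 10x-style directory (matrix.mtx + features.tsv + barcodes.tsv).

    Plain or gzipped files are accepted.  Duplicate gene IDs are
    disambiguated deterministically with a ``.1``, ``.2``, ... suffix.
    If ``donor`` is None the directory name is used as the donor label.
    """
    path = Path(path)
    mtx = _find_file(path, "matrix.mtx")
    feat = _find_file(path, "features.tsv")
    bc = _find_file(path, "barcodes.tsv")
    with _open_maybe_gz(mtx, "rb") as fh:
        counts = sp.csr_matrix(scipy.io.mmread(fh))
    genes = [line.split("\t")[0].strip() for line in _read_lines(feat)]
    barcodes = [line.strip() for line in _read_lines(bc)]
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but features.tsv has {len(genes)} genes"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} columns but barcodes.tsv has {len(barcodes)} barcodes"
        )
    genes = _dedupe(genes)
    label = donor if donor is not None else path.name
    return CountMatrix(counts, np.array(genes, dtype=object),
                       np.array(barcodes, dtype=object),
                       np.array([label] * len(barcodes), dtype=object))


def _read_lines(path: Path):
    with _open_maybe_gz(path) as fh:
        return [ln for ln in fh if ln.strip()]


def _dedupe(names):
    seen: dict = {}
    out = []
    dup = False
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
            dup = True
        else:
            seen[n] = 0
            out.append(n)
    if dup:
        warnings.warn("duplicate gene IDs disambiguated with numeric suffixes")
    return out


def read_tenx_multi(root) -> CountMatrix:
    """Read every per-donor subdirectory under ``root`` and concatenate cells.

    Gene universes must match across donors.  Barcodes are prefixed with the
    donor label to keep them unique.
    """
    root = Path(root)
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not subdirs:
        raise FileNotFoundError(f"no donor subdirectories under {root}")
    parts = [read_tenx_mtx(d) for d in subdirs]
    genes = parts[0].gene_ids
    for p in parts[1:]:
        if not np.array_equal(p.gene_ids, genes):
            raise ValueError("gene universes differ across donor directories")
    counts = sp.hstack([p.counts for p in parts], format="csr")
    barcodes = np.concatenate(
        [np.array([b if str(b).startswith(f"{p.donor[0]}:") else f"{p.donor[0]}:{b}"
                   for b in p.barcodes], dtype=object) for p in parts]
    )
    donor = np.concatenate([p.donor for p in parts])
    return CountMatrix(counts, genes, barcodes, donor)


def write_tenx_directory(counts: CountMatrix, path, overwrite: bool = False) -> None:
    """Write one 10x-style subdirectory per donor under ``path``.

    Each subdirectory holds ``matrix.mtx``, ``features.tsv`` and
    ``barcodes.tsv`` (integer Matrix Market triplet; round-trips exactly
    through :func:`read_tenx_mtx`).  Refuses a non-empty target unless
    ``overwrite`` is set.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("refusing to write an empty count matrix")
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists and is not empty (pass overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)
    for d in sorted(set(counts.donor)):
        sub = path / str(d)
        sub.mkdir(exist_ok=True)
        mask = counts.donor == d
        mat = sp.coo_matrix(counts.counts[:, mask]).astype(int)
        with open(sub / "matrix.mtx", "wb") as fh:
            scipy.io.mmwrite(fh, mat, field="integer")
        with open(sub / "features.tsv", "w") as fh:
            for g in counts.gene_ids:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(sub / "barcodes.tsv", "w") as fh:
            for b in counts.barcodes[mask]:
                fh.write(f"{b}\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Empty lines are skipped; a duplicated set name is an error.
    """
    sets: dict = {}
    with _open_maybe_gz(Path(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets)


def write_gmt(sets: dict, path, description: str = "tonsilflow") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gene_list(path) -> list:
    """One-gene-per-line TSV/text list (first column if tab-separated)."""
    out = []
    with _open_maybe_gz(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(line.split("\t")[0])
    return out


def write_tsv(df: pd.DataFrame, path, comment: str | None = None, index=True) -> None:
    """Write a TSV with an optional ``#`` header comment (e.g. config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)
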
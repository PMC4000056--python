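"""Readers and writers for the file formats the tool speaks.

Expression matrices are genes x samples on disk, either plain tab-delimited
(first column gene ids, header row sample ids) or GCT 1.2.  Gene-set
libraries use the GMT convention (name, description, members...).  Ranked
gene lists are two-column tab-delimited files, most significant first.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TwoClassDesign
from .enrich import GeneSetLibrary
from .errors import CharDirWarning, InputError
from .evaluate import ExperimentRanking

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_design",
    "read_ranking",
]


def read_expression(path: "str | Path", dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples matrix from a tsv or GCT 1.2 file."""
    path = Path(path)
    if dialect not in ("tsv", "gct"):
        raise InputError(f"unknown dialect: {dialect!r}")
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"empty file: {path}")
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise InputError(f"unsupported GCT version line: {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise InputError("malformed GCT dimensions line")
            df = pd.read_csv(fh, sep="\t", index_col=0, comment=None)
        df = df.drop(columns=[c for c in df.columns if c.lower() == "description"])
        declared = int(dims[0]), int(dims[1])
        if df.shape != declared:
            raise InputError(
                f"GCT declares {declared} but contains {df.shape}"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return _frame_to_matrix(df, path)


def _frame_to_matrix(df: pd.DataFrame, path: Path) -> ExpressionMatrix:
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise InputError(f"{path}: duplicate gene ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise InputError(
            f"{path}: non-numeric or missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_expression(
    matrix: ExpressionMatrix, path: "str | Path", header_lines: "list[str] | None" = None
) -> None:
    """Write a matrix as tab-delimited genes x samples, optional # header block."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_gmt(path: "str | Path") -> GeneSetLibrary:
    """Read a GMT gene-set library (name, description, members...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    f"at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"set {name!r} lists duplicated members; counted once",
                    CharDirWarning,
                    stacklevel=2,
                )
            if not deduped:
                raise InputError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = deduped
            descriptions[name] = desc
    if not sets:
        raise InputError(f"{path}: no gene sets found")
    return GeneSetLibrary(sets=sets, descriptions=descriptions)


def write_gmt(library: GeneSetLibrary, path: "str | Path") -> None:
    with open(path, "w") as fh:
        for name, members in library:
            desc = (library.descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_design(path: "str | Path") -> TwoClassDesign:
    """Read a two-column design file: sample_id <tab> {control|perturbed}."""
    path = Path(path)
    control: list[str] = []
    perturbed: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise InputError(f"{path}:{lineno}: expected 'sample_id class'")
            sample, cls = fields
            if cls in ("control", "ctrl", "0"):
                control.append(sample)
            elif cls in ("perturbed", "case", "treatment", "1"):
                perturbed.append(sample)
            else:
                raise InputError(f"{path}:{lineno}: unknown class {cls!r}")
    return TwoClassDesign(control_ids=control, perturbed_ids=perturbed)


def read_ranking(path: "str | Path", experiment_id: "str | None" = None) -> ExperimentRanking:
    """Read a ranked gene list: gene_id [tab score], most significant first.

    Any method's output can be evaluated this way; only the order is used.
    """
    path = Path(path)
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            genes.append(line.split()[0])
    if not genes:
        raise InputError(f"{path}: empty ranking")
    return ExperimentRanking(experiment_id or path.stem, genes)
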
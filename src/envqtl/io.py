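"""Plain-text I/O: TSV matrices, BED marker maps, JSON reports.

Coordinate convention: BED files are 0-based half-open (point markers are
width-1 intervals); everything in memory is 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MultiEnvPhenotypes, CheckeredMask


class ParseError(ValueError):
    pass


def read_matrix(path, kind: str = "numeric") -> pd.DataFrame:
    """Read a TSV matrix with a header row and an id column.

    Raises :class:`ParseError` with a line number on ragged rows or
    duplicated ids; empty cells become NaN.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            nfields = line.rstrip("\n").count("\t") + 1
            if nfields != ncol:
                raise ParseError(f"{path}:{lineno}: expected {ncol} fields, got {nfields}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ParseError(f"{path}: duplicate column ids")
    if kind == "numeric":
        df = df.astype(float)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def write_marker_bed(marker_map: pd.DataFrame, path) -> None:
    """Point markers as width-1 BED intervals (0-based half-open)."""
    out = pd.DataFrame({
        "chrom": marker_map["chrom"],
        "start": marker_map["pos"] - 1,
        "end": marker_map["pos"],
        "name": marker_map.index,
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_marker_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"])
    if ((bed["end"] - bed["start"]) != 1).any():
        raise ParseError(f"{path}: point markers must be width-1 intervals")
    mm = pd.DataFrame({"chrom": bed["chrom"].to_numpy(),
                       "pos": (bed["start"] + 1).to_numpy()},
                      index=pd.Index(bed["name"], name="marker"))
    return mm


def write_genotypes(genotypes: GenotypeMatrix, tsv_path, bed_path) -> None:
    write_matrix(genotypes.alleles, tsv_path)
    write_marker_bed(genotypes.marker_map, bed_path)


def read_genotypes(tsv_path, bed_path) -> GenotypeMatrix:
    alleles = read_matrix(tsv_path).astype(np.int8)
    marker_map = read_marker_bed(bed_path)
    if list(alleles.columns) != list(marker_map.index):
        raise ParseError("genotype columns and marker map disagree")
    return GenotypeMatrix(alleles, marker_map)


def write_phenotypes(phen: MultiEnvPhenotypes, outdir) -> None:
    outdir = Path(outdir)
    write_matrix(phen.growth, outdir / "growth.tsv")
    for env, mat in phen.expression.items():
        write_matrix(mat, outdir / f"expression_{env}.tsv")


def read_phenotypes(outdir, environments: list[str]) -> MultiEnvPhenotypes:
    outdir = Path(outdir)
    growth = read_matrix(outdir / "growth.tsv")
    expression = {env: read_matrix(outdir / f"expression_{env}.tsv")
                  for env in environments}
    profiled = {
        env: list(mat.index[~mat.isna().all(axis=1)]) for env, mat in expression.items()
    }
    return MultiEnvPhenotypes(growth=growth, expression=expression,
                              mask=CheckeredMask(profiled))


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
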
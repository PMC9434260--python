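"""Readers and writers for the pipeline's file formats.

- R/qtl-style "csv" cross files: header row of phenotype + marker names,
  a chromosome row, a cM row, then one row per individual.
- BED-like region files: 0-based half-open on disk, converted to the
  1-based closed convention used in memory (bit-exact inverse on write).
- chrom.sizes (two columns), expression matrix + probe annotation CSV,
  per-individual outline coordinate CSV.

All readers reject structurally invalid input; all writers are
deterministic for fixed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import GenomicInterval
from .cross import CrossData, GeneticMap


@dataclass
class CrossFileDialect:
    """How genotype codes and column roles are spelled in a cross file."""

    genotype_codes: dict = field(default_factory=lambda: {"AA": "RR", "AB": "RW", "BB": "WW"})
    missing: str = "-"
    phenotype_columns: tuple = ()
    covariate_columns: tuple = ()
    categorical_covariates: tuple = ("batch", "family", "structure")

    def __post_init__(self) -> None:
        vals = list(self.genotype_codes.values())
        if sorted(vals) != ["RR", "RW", "WW"]:
            raise ValueError("genotype_codes must map one token to each of RR, RW, WW")


def read_cross_csv(path, dialect: CrossFileDialect) -> CrossData:
    """Read an R/qtl-style CSV cross file.

    Unknown genotype tokens become missing calls (with a counted
    warning); non-monotone cM positions are re-sorted with a warning
    naming the chromosome.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    header = list(raw.columns)
    chrom_row = raw.iloc[0]
    cm_row = raw.iloc[1]
    body = raw.iloc[2:].reset_index(drop=True)
    ind_cols = [c for c in header if chrom_row[c].strip() == ""]
    marker_cols = [c for c in header if chrom_row[c].strip() != ""]
    if not marker_cols:
        raise ValueError("no marker columns found (empty chromosome row)")
    if len(set(marker_cols)) != len(marker_cols):
        raise ValueError("duplicated marker names in header")
    clash = set(marker_cols) & set(ind_cols)
    if clash:
        raise ValueError(f"columns used as both phenotype and marker: {sorted(clash)}")

    map_df = pd.DataFrame({
        "marker": marker_cols,
        "chrom": [chrom_row[c].strip() for c in marker_cols],
        "cM": [float(cm_row[c]) for c in marker_cols],
    })
    order = []
    for chrom, sub in map_df.groupby("chrom", sort=False):
        pos = sub["cM"].to_numpy()
        idx = sub.index.to_numpy()
        if not np.all(np.diff(pos) > 0):
            warnings.warn(f"non-monotone cM positions on chromosome {chrom}; re-sorting")
            idx = idx[np.argsort(pos, kind="stable")]
        order.extend(idx)
    map_df = map_df.loc[order].reset_index(drop=True)
    gmap = GeneticMap(map_df)

    geno_raw = body[map_df["marker"]]
    lut = dict(dialect.genotype_codes)
    vals = geno_raw.to_numpy()
    data = np.full(geno_raw.shape, np.nan, dtype=object)
    for tok, code in lut.items():
        data[vals == tok] = code
    missing_tok = (vals == dialect.missing) | (vals == "")
    unknown = int(np.sum(~np.isin(vals, list(lut)) & ~missing_tok))
    if unknown:
        warnings.warn(f"{unknown} unknown genotype tokens treated as missing")
    index = pd.Index([f"ind{i + 1}" for i in range(len(body))])
    genotypes = pd.DataFrame(data, columns=list(map_df["marker"]), index=index)

    phen_cols = [c for c in dialect.phenotype_columns if c in ind_cols]
    cov_cols = [c for c in dialect.covariate_columns if c in ind_cols]
    if not dialect.phenotype_columns and not dialect.covariate_columns:
        phen_cols = ind_cols
    def _numeric(cols):
        out = {}
        for c in cols:
            col = body[c].replace({dialect.missing: np.nan, "": np.nan})
            try:
                out[c] = pd.to_numeric(col)
            except (ValueError, TypeError):
                out[c] = col
        df = pd.DataFrame(out) if cols else pd.DataFrame(index=range(len(body)))
        df.index = index
        return df
    phen = _numeric(phen_cols)
    cov = _numeric(cov_cols)
    for c in cov.columns:
        if c in dialect.categorical_covariates:
            cov[c] = cov[c].astype("category")
    return CrossData(gmap=gmap, genotypes=genotypes, phenotypes=phen, covariates=cov)


def write_cross_csv(cross: CrossData, path, dialect: CrossFileDialect) -> None:
    """Write CrossData in the R/qtl CSV layout (phenotypes then markers)."""
    inv = {v: k for k, v in dialect.genotype_codes.items()}
    ind_cols = list(cross.phenotypes.columns) + [
        c for c in cross.covariates.columns if c not in cross.phenotypes.columns]
    markers = cross.gmap.marker_names
    header = ind_cols + markers
    chrom_row = [""] * len(ind_cols) + [str(c) for c in cross.gmap.table["chrom"]]
    cm_row = [""] * len(ind_cols) + [f"{v:g}" for v in cross.gmap.table["cM"]]
    geno = cross.genotypes.to_numpy(object)
    lines = [",".join(header), ",".join(chrom_row), ",".join(cm_row)]
    for i in range(cross.n_individuals):
        vals = []
        for c in ind_cols:
            src = cross.phenotypes if c in cross.phenotypes.columns else cross.covariates
            v = src[c].iloc[i]
            vals.append(dialect.missing if pd.isna(v) else f"{v:g}" if isinstance(v, (int, float, np.floating, np.integer)) else str(v))
        for j in range(len(markers)):
            g = geno[i, j]
            vals.append(inv[g] if isinstance(g, str) else dialect.missing)
        lines.append(",".join(vals))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Regions


def read_regions_bed(path) -> list:
    """BED 3+1 -> closed 1-based GenomicIntervals on the bp axis."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            if start > end:
                raise ValueError(f"start > end on BED line {lineno}")
            label = parts[3] if len(parts) > 3 else ""
            intervals.append(GenomicInterval(chrom=parts[0], start=start + 1,
                                             end=end, axis="bp", label=label))
    return intervals


def write_regions_bed(intervals, path) -> None:
    """Closed 1-based intervals -> 0-based half-open BED (inverse of read)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{int(iv.start) - 1}\t{int(iv.end)}\t{iv.label}\n")


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(float)))


def write_chrom_sizes(genome: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{int(length)}\n")


# ---------------------------------------------------------------------------
# Expression / outlines


def read_expression_csv(path) -> pd.DataFrame:
    """Probes x individuals matrix; first column = probe id."""
    return pd.read_csv(path, index_col=0)


def write_expression_csv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, index_label="probe")


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"probe": str, "chrom": str})
    missing = {"probe", "chrom", "cM"} - set(df.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns {sorted(missing)}")
    return df


def write_outlines_csv(outlines, path, ids=None) -> None:
    """Long-format x,y coordinates with an individual id column."""
    frames = []
    for i, o in enumerate(outlines):
        oid = ids[i] if ids is not None else f"ind{i + 1}"
        frames.append(pd.DataFrame({"individual": oid,
                                    "x": o.points[:, 0], "y": o.points[:, 1]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_outlines_csv(path) -> dict:
    """Inverse of :func:`write_outlines_csv`: id -> Outline."""
    from .morphometrics import Outline

    df = pd.read_csv(path)
    out = {}
    for oid, sub in df.groupby("individual", sort=False):
        out[oid] = Outline(sub[["x", "y"]].to_numpy(float))
    return out
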
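"""Core containers: genetic map, cross data, genotype probabilities.

Genotypes are coded ``RR`` / ``RW`` / ``WW`` (Red Junglefowl vs. White
Leghorn founder alleles); missing calls are ``NaN``.  Additive dosage is
``x_a = P(WW) - P(RR)`` (so RR = -1, RW = 0, WW = +1) and the dominance
indicator is ``x_d = P(RW)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CODES = ("RR", "RW", "WW")


@dataclass
class GeneticMap:
    """Marker map: one row per marker with chromosome, cM and bp position.

    ``table`` columns: ``marker``, ``chrom``, ``cM`` and optionally ``bp``.
    Positions must be strictly increasing within each chromosome and
    marker names unique genome-wide.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicated marker names: {sorted(set(dups))}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["cM"].to_numpy(float)
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"cM positions not strictly increasing on {chrom}")
        self.table = self.table.reset_index(drop=True)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_names(self) -> list:
        return list(self.table["marker"])

    def chrom_table(self, chrom) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        return sub

    def positions(self, chrom) -> np.ndarray:
        return self.chrom_table(chrom)["cM"].to_numpy(float)

    def chrom_length(self, chrom) -> float:
        return float(self.positions(chrom)[-1])

    def nearest_marker(self, chrom, cm: float) -> pd.Series:
        """Marker closest in cM; ties broken toward the lower position."""
        sub = self.chrom_table(chrom)
        dist = np.abs(sub["cM"].to_numpy(float) - cm)
        return sub.iloc[int(np.argmin(dist))]  # argmin takes first == lower pos

    def __len__(self) -> int:
        return self.n_markers


@dataclass
class CrossData:
    """An intercross: map + genotype calls + phenotypes + covariates.

    ``genotypes``: individuals x markers DataFrame of ``RR/RW/WW`` strings
    (NaN for missing), columns in map order.  ``phenotypes`` and
    ``covariates``: per-individual columns sharing the genotype index.
    """

    gmap: GeneticMap
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.genotypes.columns) != self.gmap.marker_names:
            raise ValueError("genotype columns must match map markers in order")
        n = len(self.genotypes)
        for name, df in (("phenotypes", self.phenotypes), ("covariates", self.covariates)):
            if len(df) not in (0, n):
                raise ValueError(f"{name} row count {len(df)} != {n} individuals")
        valid = set(GENOTYPE_CODES)
        vals = self.genotypes.to_numpy(object).ravel()
        bad = {v for v in vals if isinstance(v, str) and v not in valid}
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def individual_ids(self) -> pd.Index:
        return self.genotypes.index

    def genotype_codes_int(self) -> np.ndarray:
        """Genotypes as integers RR=0, RW=1, WW=2, missing=-1."""
        mapping = {c: i for i, c in enumerate(GENOTYPE_CODES)}
        arr = np.full(self.genotypes.shape, -1, dtype=np.int8)
        vals = self.genotypes.to_numpy(object)
        for code, i in mapping.items():
            arr[vals == code] = i
        return arr


@dataclass
class GenotypeProbabilities:
    """Per-position genotype probabilities and HK dosages.

    For each chromosome: evaluation positions (cM), names (marker name or
    pseudomarker label), and a ``(n_positions, n_individuals, 3)``
    probability array over (RR, RW, WW).
    """

    chrom_positions: dict
    chrom_names: dict
    chrom_probs: dict

    def dosages(self, chrom) -> np.ndarray:
        """``(n_positions, n_individuals, 2)`` array of (x_a, x_d)."""
        p = self.chrom_probs[chrom]
        return np.stack([p[..., 2] - p[..., 0], p[..., 1]], axis=-1)

    @property
    def chromosomes(self) -> list:
        return list(self.chrom_positions)

    def all_positions(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for name, cm in zip(self.chrom_names[chrom], self.chrom_positions[chrom]):
                rows.append((chrom, name, cm))
        return pd.DataFrame(rows, columns=["chrom", "name", "cM"])
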
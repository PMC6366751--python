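"""Core data containers shared across the mapping pipeline.

Genotypes are encoded throughout as ``0.0`` (homozygous, both alleles from
the backcross parent), ``1.0`` (heterozygous, one allele from each parental
species) and ``NaN`` (missing).  Only these two genotype states segregate in
a first-generation backcross, which is what keeps the hidden Markov model
and all downstream likelihoods two-state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM = 0.0  # homozygous for the recurrent (backcross) parent allele
HET = 1.0  # heterozygous

__all__ = [
    "HOM",
    "HET",
    "LinkageMap",
    "GenotypeProbabilities",
    "validate_phenotypes",
    "courted_mask",
]


@dataclass(frozen=True)
class LinkageMap:
    """Ordered marker map: one row per marker with chromosome and cM position.

    ``table`` columns: ``marker`` (str), ``chrom`` (str), ``pos_cm`` (float).
    Markers must appear grouped by chromosome with non-decreasing positions.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"marker", "chrom", "pos_cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"linkage map needs columns {sorted(required)}")
        pos = self.table["pos_cm"].to_numpy(dtype=float)
        if not np.all(np.isfinite(pos)) or np.any(pos < 0):
            raise ValueError("marker positions must be finite and >= 0")
        if self.table["marker"].duplicated().any():
            dup = self.table["marker"][self.table["marker"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        for chrom, grp in self.table.groupby("chrom", sort=False):
            p = grp["pos_cm"].to_numpy(dtype=float)
            if np.any(np.diff(p) < 0):
                raise ValueError(f"marker positions on {chrom} are not sorted")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub

    def length(self, chrom: str) -> float:
        return float(self.chrom_table(chrom)["pos_cm"].max())


@dataclass
class GenotypeProbabilities:
    """Posterior P(het) on an evaluation grid for a set of individuals.

    ``grid`` columns: ``chrom``, ``pos_cm``, ``is_marker`` (bool).
    ``p_het`` has shape ``(n_individuals, n_grid_points)``.
    """

    ids: np.ndarray
    grid: pd.DataFrame
    p_het: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.p_het = np.asarray(self.p_het, dtype=float)
        if self.p_het.shape != (len(self.ids), len(self.grid)):
            raise ValueError("p_het shape does not match ids x grid")
        if np.any((self.p_het < -1e-9) | (self.p_het > 1 + 1e-9)):
            raise ValueError("P(het) outside [0, 1]")
        self.p_het = np.clip(self.p_het, 0.0, 1.0)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def p_hom(self) -> np.ndarray:
        return 1.0 - self.p_het

    def columns_for(self, chrom: str) -> np.ndarray:
        idx = np.flatnonzero(self.grid["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not on grid")
        return idx

    def index_of(self, chrom: str, pos_cm: float, atol: float = 1e-6) -> int:
        cols = self.columns_for(chrom)
        pos = self.grid["pos_cm"].to_numpy()[cols]
        j = int(np.argmin(np.abs(pos - pos_cm)))
        if abs(pos[j] - pos_cm) > atol:
            raise KeyError(f"no grid point at {chrom}@{pos_cm} cM (nearest {pos[j]})")
        return int(cols[j])

    def p_het_at(self, chrom: str, pos_cm: float) -> np.ndarray:
        return self.p_het[:, self.index_of(chrom, pos_cm)]

    def calls_at(self, chrom: str, pos_cm: float) -> np.ndarray:
        """Maximum-posterior genotype call (0=hom, 1=het) at a grid point."""
        return (self.p_het_at(chrom, pos_cm) > 0.5).astype(float)

    def subset(self, keep: np.ndarray) -> "GenotypeProbabilities":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeProbabilities(self.ids[keep], self.grid, self.p_het[keep])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (individual, chrom, pos_cm, p_het)."""
        n_id, n_pos = self.p_het.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(self.ids, n_pos),
                "chrom": np.tile(self.grid["chrom"].to_numpy(), n_id),
                "pos_cm": np.tile(self.grid["pos_cm"].to_numpy(), n_id),
                "p_het": self.p_het.ravel(),
            }
        )


PHENO_COLUMNS = ["id", "minutes_mel", "minutes_cyd", "n_trials"]


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a courtship phenotype table.

    Columns: ``id``, ``minutes_mel`` (courtship minutes directed toward the
    melpomene-type female), ``minutes_cyd``, ``n_trials``.  Counts must be
    non-negative integers; duplicated ids are rejected.
    """
    missing = set(PHENO_COLUMNS) - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    if pheno.empty:
        raise ValueError("phenotype table is empty")
    if pheno["id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    for col in ("minutes_mel", "minutes_cyd", "n_trials"):
        vals = pheno[col].to_numpy()
        if np.any(pd.isna(vals)) or np.any(np.asarray(vals, dtype=float) < 0):
            raise ValueError(f"column {col} must be non-negative and complete")
    return pheno


def courted_mask(pheno: pd.DataFrame) -> np.ndarray:
    """True for males that performed at least one courtship minute.

    Males with zero total courtship carry no information about the courtship
    proportion and are excluded from proportion scans.
    """
    total = pheno["minutes_mel"].to_numpy() + pheno["minutes_cyd"].to_numpy()
    return np.asarray(total, dtype=float) > 0
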
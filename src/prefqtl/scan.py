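"""Genome scans for preference QTLs on courtship-proportion phenotypes.

At every grid position the binomial mixed model

    minutes_mel_i of n_i  ~  intercept + P(het)_i + u_i

is compared to the null model without the genotype-probability covariate;
LOD = (lnL_full - lnL_null) / ln 10.  Regressing on the posterior genotype
probability rather than on hard calls is the mixed-model analogue of
Haley-Knott regression; the per-individual random intercept u_i absorbs
overdispersion relative to the binomial.  Genome-wide significance comes
from permuting whole phenotype rows across individuals.  A rank-based
(Kruskal-Wallis-type) scan generalizing the Wilcoxon rank-sum statistic to
genotype probabilities is available as a distribution-free cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import GenotypeProbabilities, courted_mask, validate_phenotypes
from .glmm import fit_binomial_mixed

__all__ = [
    "ScanResult",
    "PermutationResult",
    "scan_glmm",
    "scan_nonparametric",
    "scan_subset",
    "permutation_threshold",
]

LN10 = np.log(10.0)


@dataclass
class ScanResult:
    """Per-position LOD profile.

    ``table`` columns: chrom, pos_cm, lod, converged.
    """

    table: pd.DataFrame
    n_used: int
    model: str
    excluded_ids: list = field(default_factory=list)

    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def peak(self, chrom: str | None = None) -> tuple:
        """(chrom, pos_cm, lod) of the maximum; ties break to the lowest cM."""
        tab = self.table if chrom is None else self.table[self.table["chrom"] == chrom]
        if tab.empty:
            raise KeyError(f"chromosome {chrom!r} not in scan")
        lod = tab["lod"].to_numpy()
        best = np.flatnonzero(lod >= lod.max() - 1e-12)
        row = tab.iloc[int(best[np.argmin(tab["pos_cm"].to_numpy()[best])])]
        return str(row["chrom"]), float(row["pos_cm"]), float(row["lod"])

    def max_lod_by_chrom(self) -> pd.Series:
        return self.table.groupby("chrom", sort=False)["lod"].max()


@dataclass
class PermutationResult:
    """Null distribution of genome-wide maximum LOD under row permutation."""

    max_lod_by_chrom: pd.DataFrame  # one row per permutation, one column per chrom
    seed: int
    n_permutations: int

    @property
    def max_lods(self) -> np.ndarray:
        return self.max_lod_by_chrom.to_numpy().max(axis=1)

    def threshold(self, alpha: float = 0.05, chromosomes=None) -> float:
        """(1 - alpha) quantile of the per-permutation maximum LOD."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        tab = self.max_lod_by_chrom
        if chromosomes is not None:
            tab = tab[list(chromosomes)]
        return float(np.quantile(tab.to_numpy().max(axis=1), 1.0 - alpha))

    def pvalue(self, lod: float, chromosomes=None) -> float:
        """Genome-wide permutation P of an observed LOD."""
        tab = self.max_lod_by_chrom
        if chromosomes is not None:
            tab = tab[list(chromosomes)]
        m = tab.to_numpy().max(axis=1)
        return float((np.sum(m >= lod) + 1) / (len(m) + 1))


def _align(probs: GenotypeProbabilities, pheno: pd.DataFrame):
    """Intersect phenotype and genotype individuals; drop zero-courtship males."""
    pheno = validate_phenotypes(pheno)
    pheno = pheno.set_index("id")
    common = [i for i in probs.ids if i in pheno.index]
    if not common:
        raise ValueError("no individuals shared between phenotypes and genotypes")
    keep_probs = probs.subset(np.isin(probs.ids, common))
    ph = pheno.loc[list(keep_probs.ids)].reset_index()
    courted = courted_mask(ph)
    excluded = list(ph.loc[~courted, "id"])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} males with zero courtship minutes",
            stacklevel=3,
        )
    ph = ph[courted].reset_index(drop=True)
    keep_probs = keep_probs.subset(courted)
    y = ph["minutes_mel"].to_numpy(dtype=float)
    n = y + ph["minutes_cyd"].to_numpy(dtype=float)
    return keep_probs, ph, y, n, excluded


def _glmm_lods(p_het: np.ndarray, y: np.ndarray, n: np.ndarray, sigma, nodes, max_batch):
    """LOD profile for covariate columns ``p_het`` (n_ind x n_pos)."""
    n_ind, n_pos = p_het.shape
    null = fit_binomial_mixed(y, n, np.ones((n_ind, 1)), sigma=sigma, nodes=nodes)
    ll_null = float(null["loglik"])

    informative = p_het.std(axis=0) > 1e-8
    lod = np.zeros(n_pos)
    converged = np.ones(n_pos, dtype=bool)
    if not informative.all():
        warnings.warn(
            f"{int((~informative).sum())} positions have a constant genotype "
            "covariate; their LOD is reported as 0",
            stacklevel=3,
        )
    cols = np.flatnonzero(informative)
    if cols.size:
        X = np.empty((cols.size, n_ind, 2))
        X[:, :, 0] = 1.0
        X[:, :, 1] = p_het[:, cols].T
        full = fit_binomial_mixed(
            np.broadcast_to(y, (cols.size, n_ind)),
            np.broadcast_to(n, (cols.size, n_ind)),
            X,
            sigma=sigma,
            nodes=nodes,
            max_batch=max_batch,
        )
        lod[cols] = np.maximum(full["loglik"] - ll_null, 0.0) / LN10
        converged[cols] = full["converged"]
    return lod, converged


def scan_glmm(
    probs: GenotypeProbabilities,
    pheno: pd.DataFrame,
    sigma: float | None = None,
    nodes: int = 25,
    max_batch: int = 256,
) -> ScanResult:
    """Binomial mixed-model genome scan.

    ``sigma=None`` (default) estimates the random-intercept SD by maximum
    likelihood at every position; ``sigma=0`` pins the variance to zero,
    reducing the scan to a plain binomial-GLM Haley-Knott-style scan.
    """
    keep, ph, y, n, excluded = _align(probs, pheno)
    lod, conv = _glmm_lods(keep.p_het, y, n, sigma, nodes, max_batch)
    table = keep.grid[["chrom", "pos_cm"]].copy()
    table["lod"] = lod
    table["converged"] = conv
    return ScanResult(table, n_used=len(y), model="glmm", excluded_ids=excluded)


def scan_nonparametric(probs: GenotypeProbabilities, pheno: pd.DataFrame) -> ScanResult:
    """Rank-based genome scan of the courtship proportion.

    The phenotype is each male's courtship proportion minutes_mel / total,
    converted to midranks.  At each position the linear rank statistic
    T = sum_i P(het)_i R_i is standardized by its exact permutation mean and
    variance given the weights; Z^2 / (2 ln 10) is reported on the LOD
    scale.  With fully informative genotypes (P(het) in {0, 1}) this is the
    tie-corrected Wilcoxon rank-sum (equivalently two-group Kruskal-Wallis)
    statistic.
    """
    keep, ph, y, n, excluded = _align(probs, pheno)
    ranks = rankdata(y / n)  # midranks for ties
    n_ind = len(ranks)
    rc = ranks - ranks.mean()
    w = keep.p_het
    wc = w - w.mean(axis=0, keepdims=True)
    t_stat = wc.T @ rc  # (n_pos,)
    var = (wc**2).sum(axis=0) * (rc**2).sum() / (n_ind - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z2 = np.where(var > 1e-12, t_stat**2 / var, 0.0)
    table = keep.grid[["chrom", "pos_cm"]].copy()
    table["lod"] = z2 / (2.0 * LN10)
    table["converged"] = True
    return ScanResult(table, n_used=n_ind, model="np", excluded_ids=excluded)


def scan_subset(
    probs: GenotypeProbabilities,
    pheno: pd.DataFrame,
    locus: tuple,
    genotype: float,
    **kw,
) -> ScanResult:
    """Genome scan restricted to males whose maximum-probability call at
    ``locus = (chrom, pos_cm)`` equals ``genotype`` (0 hom / 1 het)."""
    calls = probs.calls_at(*locus)
    keep = calls == float(genotype)
    if not keep.any():
        raise ValueError(f"no individuals with genotype {genotype} at {locus}")
    return scan_glmm(probs.subset(keep), pheno, **kw)


def permutation_threshold(
    probs: GenotypeProbabilities,
    pheno: pd.DataFrame,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    sigma: float | None = None,
    nodes: int = 25,
    max_batch: int = 256,
) -> PermutationResult:
    """Genome-wide significance threshold by whole-row phenotype permutation.

    Each permutation shuffles complete phenotype rows (minutes toward each
    female type and trial count stay together) across individuals, rescans
    the genome, and records the maximum LOD per chromosome.  The permutation
    unit is the individual, which respects the per-male random-intercept
    grouping of the scan model.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    keep, ph, y, n, _ = _align(probs, pheno)
    rng = np.random.default_rng(seed)
    chroms = keep.grid["chrom"].to_numpy()
    chrom_names = list(dict.fromkeys(chroms))
    rows = np.empty((n_permutations, len(chrom_names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_permutations):
            perm = rng.permutation(len(y))
            lod, _ = _glmm_lods(keep.p_het, y[perm], n[perm], sigma, nodes, max_batch)
            rows[b] = [lod[chroms == c].max() for c in chrom_names]
    return PermutationResult(
        pd.DataFrame(rows, columns=chrom_names), seed=seed, n_permutations=n_permutations
    )
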
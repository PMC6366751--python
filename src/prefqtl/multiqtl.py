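"""Joint multi-QTL models, penalized LOD scores, support intervals and
effect sizes on the percent-of-parental-difference scale.

The joint model regresses the courtship-minute response on the genotype
probabilities at the detected QTL peaks (random intercept per male always
retained).  The fully saturated model with all pairwise interactions is
simplified stepwise by likelihood-ratio tests; the retained model gamma is
scored by the penalized LOD

    pLODa(gamma) = LOD(gamma) - T * |gamma|,

where T is the genome-wide permutation threshold and |gamma| the number of
QTLs.  Per-QTL support is summarized by the change in pLODa when each QTL
is eliminated in turn and by the drop-one likelihood-ratio statistic
2*dlnL with its chi-square P value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeProbabilities
from .glmm import fit_single
from .scan import LN10, ScanResult, _align

__all__ = [
    "QTLModel",
    "EffectEstimate",
    "penalized_lod",
    "fit_multiqtl",
    "support_interval",
    "effect_size",
    "compare_groups",
    "per_cue_effects",
]


def penalized_lod(lod: float, n_qtl: int, threshold: float) -> float:
    """pLODa(gamma) = LOD(gamma) - T * |gamma|."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    return lod - threshold * n_qtl


@dataclass
class QTLModel:
    """A fitted multi-QTL binomial mixed model."""

    loci: list  # [(chrom, pos_cm), ...]
    interactions: list  # [(i, j), ...] retained pairwise interactions
    beta: np.ndarray
    sigma: float
    term_names: list
    loglik: float
    loglik_null: float
    threshold: float
    drop_tests: pd.DataFrame  # per-QTL: lod_drop, delta_plod, two_delta_lnl, p
    n_used: int

    @property
    def lod(self) -> float:
        return (self.loglik - self.loglik_null) / LN10

    @property
    def plod(self) -> float:
        return penalized_lod(self.lod, len(self.loci), self.threshold)


def _design(p_cols: np.ndarray, interactions) -> tuple[np.ndarray, list]:
    n_ind, n_loci = p_cols.shape
    cols = [np.ones(n_ind)]
    names = ["intercept"]
    for j in range(n_loci):
        cols.append(p_cols[:, j])
        names.append(f"q{j + 1}")
    for i, j in interactions:
        cols.append(p_cols[:, i] * p_cols[:, j])
        names.append(f"q{i + 1}:q{j + 1}")
    return np.column_stack(cols), names


def fit_multiqtl(
    probs: GenotypeProbabilities,
    pheno: pd.DataFrame,
    loci,
    threshold: float,
    alpha_simplify: float = 0.05,
) -> QTLModel:
    """Fit the saturated multi-QTL model and simplify it stepwise.

    ``loci`` is a list of (chrom, pos_cm) peak positions.  All pairwise
    interactions are tested first jointly and then singly (least significant
    eliminated while P > ``alpha_simplify``); main effects of all supplied
    QTLs are retained so the model can report their drop statistics.
    """
    loci = [(str(c), float(p)) for c, p in loci]
    if len(set(loci)) != len(loci):
        raise ValueError("duplicate QTL positions")
    keep, ph, y, n, _ = _align(probs, pheno)
    p_cols = np.column_stack([keep.p_het_at(c, p) for c, p in loci])

    def fit(interactions, columns=None):
        cols = columns if columns is not None else np.arange(p_cols.shape[1])
        X, names = _design(p_cols[:, cols], interactions)
        return fit_single(y, n, X), names

    null = fit_single(y, n, np.ones((len(y), 1)))

    pairs = list(itertools.combinations(range(len(loci)), 2))
    interactions = list(pairs)
    if pairs:
        saturated, _ = fit(interactions)
        mains_only, _ = fit([])
        stat = 2.0 * (saturated.loglik - mains_only.loglik)
        p_joint = stats.chi2.sf(max(stat, 0.0), df=len(pairs))
        if p_joint > alpha_simplify:
            interactions = []
        else:
            # backward elimination of single interactions
            current = saturated
            while interactions:
                tests = []
                for k, pair in enumerate(interactions):
                    reduced, _ = fit([q for q in interactions if q != pair])
                    s = 2.0 * (current.loglik - reduced.loglik)
                    tests.append((stats.chi2.sf(max(s, 0.0), df=1), pair, reduced))
                p_worst, pair_worst, reduced_worst = max(tests, key=lambda t: t[0])
                if p_worst <= alpha_simplify:
                    break
                interactions = [q for q in interactions if q != pair_worst]
                current = reduced_worst

    final, names = fit(interactions)
    lod_full = (final.loglik - null.loglik) / LN10
    plod_full = penalized_lod(lod_full, len(loci), threshold)

    rows = []
    for j, (chrom, pos) in enumerate(loci):
        cols = [k for k in range(len(loci)) if k != j]
        sub_inter = [
            (cols.index(a), cols.index(b)) for a, b in interactions if j not in (a, b)
        ]
        reduced, _ = fit(sub_inter, columns=np.array(cols, dtype=int))
        lod_red = (reduced.loglik - null.loglik) / LN10
        plod_red = penalized_lod(lod_red, len(loci) - 1, threshold)
        two_dlnl = max(2.0 * (final.loglik - reduced.loglik), 0.0)
        df = 1 + sum(1 for a, b in interactions if j in (a, b))
        rows.append(
            {
                "chrom": chrom,
                "pos_cm": pos,
                "delta_plod": plod_red - plod_full,
                "two_delta_lnl": two_dlnl,
                "df": df,
                "p": stats.chi2.sf(two_dlnl, df=df),
            }
        )

    return QTLModel(
        loci=loci,
        interactions=interactions,
        beta=final.beta,
        sigma=final.sigma,
        term_names=names,
        loglik=final.loglik,
        loglik_null=null.loglik,
        threshold=threshold,
        drop_tests=pd.DataFrame(rows),
        n_used=len(y),
    )


def support_interval(
    scan: ScanResult, chrom: str, drop: float = 1.5
) -> tuple[float, float]:
    """Smallest contiguous interval around the peak with LOD >= peak - drop.

    Endpoints are grid positions, clipped to the chromosome bounds.  A flat
    profile returns the whole chromosome with a warning.
    """
    if drop < 0:
        raise ValueError("drop must be >= 0")
    tab = scan.table[scan.table["chrom"] == chrom]
    if tab.empty:
        raise KeyError(f"chromosome {chrom!r} not in scan")
    pos = tab["pos_cm"].to_numpy()
    lod = tab["lod"].to_numpy()
    if not np.isfinite(lod).all():
        raise ValueError("non-finite LOD values")
    if lod.max() - lod.min() < 1e-12:
        warnings.warn(f"flat LOD profile on {chrom}; returning whole chromosome")
        return float(pos.min()), float(pos.max())
    peak_candidates = np.flatnonzero(lod >= lod.max() - 1e-12)
    peak = int(peak_candidates[np.argmin(pos[peak_candidates])])
    inside = lod >= lod[peak] - drop
    lo = peak
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(pos) - 1 and inside[hi + 1]:
        hi += 1
    return float(pos[lo]), float(pos[hi])


@dataclass
class EffectEstimate:
    """QTL effect as class means and percent of the parental difference."""

    locus: tuple
    mean_hom: float
    mean_het: float
    ci_hom: tuple
    ci_het: tuple
    percent_of_parental_difference: float
    parental_means: tuple
    n_hom: int
    n_het: int
    n_ambiguous: int
    mean_hom_unweighted: float = np.nan
    mean_het_unweighted: float = np.nan


def _logit_ci(p_hat: float, n_eff: float) -> tuple:
    p = min(max(p_hat, 1e-9), 1 - 1e-9)
    se = np.sqrt(1.0 / (n_eff * p * (1.0 - p)))
    lo = np.log(p / (1 - p)) - 1.96 * se
    hi = np.log(p / (1 - p)) + 1.96 * se
    return float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi)))


def effect_size(
    probs: GenotypeProbabilities,
    pheno: pd.DataFrame,
    locus: tuple,
    parental_means: tuple,
    ambiguity_band: tuple = (0.45, 0.55),
) -> EffectEstimate:
    """Per-genotype-class mean courtship proportions and the QTL effect as
    a percent of the parental-species difference.

    Genotype classes are maximum-posterior calls at the locus; calls with
    P(het) inside ``ambiguity_band`` are excluded from the class means.
    Class means weight each male by his total courtship minutes (pooled
    proportion); unweighted per-male means are reported alongside.  The 95%
    CI is a normal approximation on the logit scale.
    """
    p_cyd, p_mel = parental_means
    if p_mel - p_cyd == 0:
        raise ValueError("parental means are equal; percent effect undefined")
    keep, ph, y, n, _ = _align(probs, pheno)
    p_loc = keep.p_het_at(*locus)
    het = p_loc > ambiguity_band[1]
    hom = p_loc < ambiguity_band[0]
    n_amb = int((~het & ~hom).sum())
    if not het.any() or not hom.any():
        raise ValueError("both genotype classes must be represented at the locus")

    out = {}
    for name, mask in (("hom", hom), ("het", het)):
        tot_y, tot_n = y[mask].sum(), n[mask].sum()
        p_hat = tot_y / tot_n
        out[name] = (float(p_hat), _logit_ci(p_hat, tot_n), float(np.mean(y[mask] / n[mask])), int(mask.sum()))

    percent = 100.0 * (out["het"][0] - out["hom"][0]) / (p_mel - p_cyd)
    return EffectEstimate(
        locus=locus,
        mean_hom=out["hom"][0],
        mean_het=out["het"][0],
        ci_hom=out["hom"][1],
        ci_het=out["het"][1],
        percent_of_parental_difference=percent,
        parental_means=tuple(parental_means),
        n_hom=out["hom"][3],
        n_het=out["het"][3],
        n_ambiguous=n_amb,
        mean_hom_unweighted=out["hom"][2],
        mean_het_unweighted=out["het"][2],
    )


def compare_groups(pheno_a: pd.DataFrame, pheno_b: pd.DataFrame) -> dict:
    """Likelihood-ratio comparison of mean courtship proportion between two
    groups of males (binomial mixed model with a group factor vs intercept
    only).  Returns 2*dlnL, d.f. = 1 and the chi-square P value."""
    frames = []
    for label, ph in (("a", pheno_a), ("b", pheno_b)):
        ph = ph.copy()
        total = ph["minutes_mel"] + ph["minutes_cyd"]
        if total.sum() == 0:
            raise ValueError(f"group {label} has zero total courtship minutes")
        ph = ph[total > 0]
        ph["group"] = 1.0 if label == "b" else 0.0
        frames.append(ph)
    d = pd.concat(frames, ignore_index=True)
    y = d["minutes_mel"].to_numpy(dtype=float)
    n = y + d["minutes_cyd"].to_numpy(dtype=float)
    g = d["group"].to_numpy()
    full = fit_single(y, n, np.column_stack([np.ones(len(y)), g]))
    null = fit_single(y, n, np.ones((len(y), 1)))
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    return {"two_delta_lnl": stat, "df": 1, "p": float(stats.chi2.sf(stat, df=1))}


def per_cue_effects(
    calls: pd.DataFrame,
    pheno: pd.DataFrame,
    n_tests: int = 6,
) -> dict:
    """Post hoc per-cue models: do the QTLs act on courtship toward one
    female type or both?

    ``calls`` is indexed by individual id with one 0/1 genotype column per
    QTL.  For each female type the response sqrt(minutes / n_trials) is
    modeled linearly on the three genotype columns; each locus gets a
    marginal F test (d.f. 1, n - p) Bonferroni-corrected for ``n_tests``
    tests, and residual variance homogeneity is checked with Levene's test
    across groups defined by the number of heterozygous loci.
    """
    import statsmodels.api as sm

    pheno = pheno.set_index("id") if "id" in pheno.columns else pheno
    common = [i for i in calls.index if i in pheno.index]
    if not common:
        raise ValueError("no shared individuals between calls and phenotypes")
    calls = calls.loc[common]
    ph = pheno.loc[common]
    trials = ph["n_trials"].to_numpy(dtype=float)
    usable = trials > 0
    if not usable.all():
        warnings.warn(f"excluding {int((~usable).sum())} males with zero trials")
    calls, ph, trials = calls[usable], ph[usable], trials[usable]

    G = calls.to_numpy(dtype=float)
    X = sm.add_constant(G)
    n_obs, n_par = X.shape
    results = {}
    for species, col in (("cydno", "minutes_cyd"), ("melpomene", "minutes_mel")):
        resp = np.sqrt(ph[col].to_numpy(dtype=float) / trials)
        if resp.std() == 0:  # degenerate: no variation to explain
            rows = [
                {"locus": locus, "F": 0.0, "df1": 1, "df2": n_obs - n_par,
                 "p_raw": 1.0, "p_bonferroni": 1.0}
                for locus in calls.columns
            ]
            results[species] = {
                "tests": pd.DataFrame(rows),
                "levene": {"stat": np.nan, "p": np.nan},
            }
            continue
        fit = sm.OLS(resp, X).fit()
        resid = fit.resid
        het_count = G.sum(axis=1).astype(int)
        groups = [resid[het_count == k] for k in np.unique(het_count)]
        lev_stat, lev_p = (np.nan, np.nan)
        if len(groups) > 1:
            lev_stat, lev_p = stats.levene(*groups, center="median")
        rows = []
        for j, locus in enumerate(calls.columns):
            f_stat = float(fit.tvalues[j + 1] ** 2)  # marginal 1-df F
            p_raw = float(stats.f.sf(f_stat, 1, n_obs - n_par))
            rows.append(
                {
                    "locus": locus,
                    "F": f_stat,
                    "df1": 1,
                    "df2": n_obs - n_par,
                    "p_raw": p_raw,
                    "p_bonferroni": min(1.0, n_tests * p_raw),
                }
            )
        results[species] = {
            "tests": pd.DataFrame(rows),
            "levene": {"stat": float(lev_stat), "p": float(lev_p)},
        }
    return results
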
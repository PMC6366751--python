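"""Winner's-curse (Beavis effect) simulations for QTL effect sizes.

With modest sample sizes, QTL effects are reported only after clearing a
genome-wide significance threshold, and replicates that overestimate the
effect by sampling are more likely to clear it — so the conditional
distribution of reported effects is inflated relative to the truth.  This
module plants a known effect at a focal genotype column, resimulates
courtship phenotypes many times per true effect, records each replicate's
focal-locus LOD and estimated effect, and summarizes the conditional
distribution of estimates among the significant replicates.

Significance is assessed at the focal locus against the genome-wide
permutation threshold passed in (not by a fresh genome-wide scan per
replicate), and the estimated effect uses the same minutes-weighted
class-mean estimator as the empirical analysis, so simulated and empirical
quantities are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import fit_binomial_mixed
from .scan import LN10
from .simulate import CountSpec, qtl_effect_logit, solve_logit_for_mean

__all__ = ["BeavisGrid", "run_beavis", "prob_significant_below"]

DEFAULT_EFFECT_GRID = tuple(range(5, 41, 5))  # percent of the parental difference


@dataclass
class BeavisGrid:
    """Per-replicate records of a Beavis simulation grid.

    ``records`` columns: true_effect, rep, lod, est_effect, significant.
    """

    records: pd.DataFrame
    threshold: float
    n_reps: int
    seed: int

    def true_effects(self) -> np.ndarray:
        return np.unique(self.records["true_effect"].to_numpy())

    def summary(self) -> pd.DataFrame:
        """Unconditional and conditional-on-significance mean estimates."""
        rows = []
        for e, grp in self.records.groupby("true_effect"):
            sig = grp[grp["significant"]]
            rows.append(
                {
                    "true_effect": e,
                    "mean_all": grp["est_effect"].mean(),
                    "mean_significant": sig["est_effect"].mean() if len(sig) else np.nan,
                    "power": len(sig) / len(grp),
                }
            )
        return pd.DataFrame(rows)

    def conditional_quantile(self, q: float) -> pd.DataFrame:
        rows = []
        for e, grp in self.records.groupby("true_effect"):
            sig = grp.loc[grp["significant"], "est_effect"]
            rows.append(
                {
                    "true_effect": e,
                    "quantile": float(np.quantile(sig, q)) if len(sig) else np.nan,
                    "n_significant": len(sig),
                }
            )
        return pd.DataFrame(rows)


def run_beavis(
    genotype: np.ndarray,
    effect_grid=DEFAULT_EFFECT_GRID,
    n_reps: int = 1000,
    threshold: float = 2.99,
    parental_means: tuple = (0.05, 0.95),
    overdispersion_sd: float = 1.0,
    trials_spec: CountSpec | None = None,
    minutes_per_trial_spec: CountSpec | None = None,
    trial_length_minutes: int = 15,
    seed: int = 0,
    chunk: int = 250,
) -> BeavisGrid:
    """Simulate the Beavis-effect grid at a focal locus.

    ``genotype`` is the 0/1 genotype column at the focal locus for the
    mapping population (the real column or a simulated one).  For each true
    effect (percent of the parental difference) and each replicate, courtship
    phenotypes are regenerated, the focal-locus mixed-model LOD computed,
    and the effect re-estimated from the minutes-weighted class means.
    """
    g = np.asarray(genotype, dtype=float)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("genotype column must be coded 0/1")
    if g.std() == 0:
        raise ValueError("monomorphic genotype column")
    effect_grid = [float(e) for e in effect_grid]
    if any(not 0 <= e <= 100 for e in effect_grid):
        raise ValueError("effects must be in [0, 100] percent")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p_cyd, p_mel = parental_means
    gap = p_mel - p_cyd
    trials_spec = trials_spec or CountSpec("shifted_poisson", lam=4.2, shift=1)
    minutes_per_trial_spec = minutes_per_trial_spec or CountSpec("poisson", lam=1.65)
    rng = np.random.default_rng(seed)
    n_ind = len(g)
    het = g == 1.0
    b0 = solve_logit_for_mean(p_cyd, overdispersion_sd)

    frames = []
    for eff in effect_grid:
        beta = qtl_effect_logit(eff, parental_means, overdispersion_sd)
        lods = np.empty(n_reps)
        ests = np.empty(n_reps)
        for lo in range(0, n_reps, chunk):
            hi = min(lo + chunk, n_reps)
            b = hi - lo
            eta = b0 + beta * g
            if overdispersion_sd > 0:
                eta = eta + rng.normal(0.0, overdispersion_sd, (b, n_ind))
            else:
                eta = np.broadcast_to(eta, (b, n_ind))
            trials = np.maximum(trials_spec.draw((b, n_ind), rng), 1)
            total = np.minimum(
                rng.poisson(minutes_per_trial_spec.lam * trials)
                if minutes_per_trial_spec.kind == "poisson"
                else np.vectorize(lambda t: minutes_per_trial_spec.draw(t, rng).sum())(trials),
                trials * trial_length_minutes,
            ).astype(float)
            total = np.maximum(total, 0.0)
            y = rng.binomial(total.astype(int), 1.0 / (1.0 + np.exp(-eta))).astype(float)
            # zero-courtship males carry no information; they simply
            # contribute nothing to the binomial likelihood (n_i = 0)
            X = np.column_stack([np.ones(n_ind), g])
            full = fit_binomial_mixed(y, total, X[None, :, :], nodes=25)
            null = fit_binomial_mixed(y, total, np.ones((1, n_ind, 1)), nodes=25)
            lods[lo:hi] = np.maximum(full["loglik"] - null["loglik"], 0.0) / LN10
            # minutes-weighted class means, as in the empirical estimator
            with np.errstate(invalid="ignore", divide="ignore"):
                p_het = y[:, het].sum(axis=1) / total[:, het].sum(axis=1)
                p_hom = y[:, ~het].sum(axis=1) / total[:, ~het].sum(axis=1)
            ests[lo:hi] = 100.0 * (p_het - p_hom) / gap
        frames.append(
            pd.DataFrame(
                {
                    "true_effect": eff,
                    "rep": np.arange(n_reps),
                    "lod": lods,
                    "est_effect": ests,
                    "significant": lods >= threshold,
                }
            )
        )
    return BeavisGrid(
        records=pd.concat(frames, ignore_index=True),
        threshold=threshold,
        n_reps=n_reps,
        seed=seed,
    )


def prob_significant_below(grid: BeavisGrid, observed_effect: float) -> pd.DataFrame:
    """P(estimated effect < observed | significant) per true effect.

    Cells with zero significant replicates are returned with NaN and
    ``defined=False``.
    """
    if grid.records.empty:
        raise ValueError("empty Beavis grid")
    rows = []
    for e, grp in grid.records.groupby("true_effect"):
        sig = grp.loc[grp["significant"], "est_effect"].to_numpy()
        rows.append(
            {
                "true_effect": e,
                "prob_below": float((sig < observed_effect).mean()) if sig.size else np.nan,
                "n_significant": int(sig.size),
                "defined": bool(sig.size),
            }
        )
    return pd.DataFrame(rows)
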
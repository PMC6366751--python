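"""Synthetic backcross pedigrees, marker data, courtship phenotypes and
four-population allele frequencies.

The generator emulates the study design of an interspecific Heliconius-style
backcross: 21 chromosomes, hom/het segregation with Haldane (no-interference)
crossovers, RAD-like genotyping error and missingness, and per-male binomial
courtship-minute phenotypes with planted QTLs plus individual-level
overdispersion on the logit scale.  Trial counts default to 1 + Poisson(4.2)
(median 5 trials per male) and courtship minutes per trial to Poisson(1.65)
so that the median proportion of 15-minute trial time spent courting is
about 0.11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LinkageMap
from .ld import recomb_fraction

__all__ = [
    "QtlSpec",
    "CountSpec",
    "SimulationConfig",
    "simulate_backcross",
    "simulate_preference_phenotypes",
    "simulate_four_population_frequencies",
    "DEFAULT_CHROMOSOMES",
]

#: 21 chromosomes of 50 cM, a typical Heliconius-scale linkage map.
DEFAULT_CHROMOSOMES: tuple = tuple((f"chr{i}", 50.0) for i in range(1, 22))


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: an allele substitution (hom -> het) shifts the expected
    courtship proportion by ``effect_pct``/100 of the parental-species gap."""

    chromosome: str
    position_cm: float
    effect_pct: float

    def __post_init__(self):
        if not 0 <= self.effect_pct <= 100:
            raise ValueError("effect_pct must be in [0, 100]")
        if self.position_cm < 0:
            raise ValueError("position_cm must be >= 0")


@dataclass(frozen=True)
class CountSpec:
    """Distribution of a per-male count.

    kinds: ``fixed`` (value), ``poisson`` (lam), ``shifted_poisson``
    (shift + Poisson(lam)).
    """

    kind: str = "poisson"
    lam: float = 1.0
    shift: int = 0
    value: int = 1

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, int(self.value))
        if self.kind == "poisson":
            return rng.poisson(self.lam, size)
        if self.kind == "shifted_poisson":
            return self.shift + rng.poisson(self.lam, size)
        raise ValueError(f"unknown count distribution {self.kind!r}")


@dataclass
class SimulationConfig:
    n_individuals: int = 139
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    marker_spacing: float = 5.0
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.02
    qtl_specs: list = field(default_factory=list)
    parental_means: tuple = (0.05, 0.95)  # (cydno, melpomene) courtship proportion
    trials_spec: CountSpec = field(
        default_factory=lambda: CountSpec("shifted_poisson", lam=4.2, shift=1)
    )
    minutes_per_trial_spec: CountSpec = field(
        default_factory=lambda: CountSpec("poisson", lam=1.65)
    )
    trial_length_minutes: int = 15
    overdispersion_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for name, length in self.chromosomes:
            if length < 0:
                raise ValueError(f"chromosome {name} has negative length")
        for rate in (self.genotyping_error_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        p_cyd, p_mel = self.parental_means
        if not (0 <= p_cyd < p_mel <= 1):
            raise ValueError("need 0 <= cydno mean < melpomene mean <= 1")
        if self.overdispersion_sd < 0:
            raise ValueError("overdispersion_sd must be >= 0")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")


def _marker_positions(length: float, spacing: float) -> np.ndarray:
    pos = np.arange(0.0, length + 1e-9, spacing)
    if len(pos) < 2:  # degenerate chromosome: keep two (possibly co-located) markers
        pos = np.array([0.0, length])
    return pos


def simulate_backcross(config: SimulationConfig):
    """Simulate a backcross: (LinkageMap, observed genotypes, true genotypes).

    True genotypes per chromosome follow a two-state Markov chain with switch
    probability equal to the Haldane recombination fraction of each marker
    gap (no crossover interference).  Observed genotypes flip hom<->het with
    the genotyping error rate and are masked (NaN) with the missing rate.
    Both genotype frames are indexed by individual id with one column per
    marker.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = np.array([f"ind{i:04d}" for i in range(1, n + 1)])

    rows = []
    true_cols, obs_cols, names = [], [], []
    for chrom, length in config.chromosomes:
        pos = _marker_positions(length, config.marker_spacing)
        mnames = [f"{chrom}_m{j + 1}" for j in range(len(pos))]
        rows.append(pd.DataFrame({"marker": mnames, "chrom": chrom, "pos_cm": pos}))

        r = recomb_fraction(np.diff(pos))
        g0 = rng.integers(0, 2, size=n)
        switches = rng.random((n, len(pos) - 1)) < r
        truth = np.empty((n, len(pos)), dtype=float)
        truth[:, 0] = g0
        truth[:, 1:] = (g0[:, None] + np.cumsum(switches, axis=1)) % 2

        obs = truth.copy()
        if config.genotyping_error_rate > 0:
            flip = rng.random(obs.shape) < config.genotyping_error_rate
            obs[flip] = 1.0 - obs[flip]
        if config.missing_rate > 0:
            obs[rng.random(obs.shape) < config.missing_rate] = np.nan

        true_cols.append(truth)
        obs_cols.append(obs)
        names.extend(mnames)

    lmap = LinkageMap(pd.concat(rows, ignore_index=True))
    truth_df = pd.DataFrame(np.concatenate(true_cols, axis=1), index=ids, columns=names)
    obs_df = pd.DataFrame(np.concatenate(obs_cols, axis=1), index=ids, columns=names)
    truth_df.index.name = obs_df.index.name = "id"
    return lmap, obs_df, truth_df


def _qtl_column(lmap: LinkageMap, spec: QtlSpec) -> str:
    """Truth-lattice marker nearest to a planted QTL (errors if off-map)."""
    sub = lmap.chrom_table(spec.chromosome)  # KeyError for unknown chromosome
    length = float(sub["pos_cm"].max())
    if spec.position_cm > length + 1e-9:
        raise ValueError(
            f"QTL position {spec.position_cm} cM beyond {spec.chromosome} ({length} cM)"
        )
    j = int(np.argmin(np.abs(sub["pos_cm"].to_numpy() - spec.position_cm)))
    return str(sub["marker"].iloc[j])


def solve_logit_for_mean(target: float, sigma: float) -> float:
    """Logit location b such that E[expit(b + sigma*Z)] = target, Z ~ N(0,1).

    With individual-level overdispersion, a raw logit offset does not move
    the *population mean* proportion by the nominal amount (the logit-normal
    mean is not expit of the location).  Solving for the location that hits
    the target marginal mean keeps planted effects unbiased on the
    proportion scale, which is the scale effects are defined on.
    """
    target = float(np.clip(target, 1e-9, 1 - 1e-9))
    if sigma == 0:
        return float(np.log(target / (1.0 - target)))
    x, w = np.polynomial.hermite.hermgauss(61)
    z, w = np.sqrt(2.0) * x, w / np.sqrt(np.pi)

    def mean_minus_target(b):
        return float(w @ (1.0 / (1.0 + np.exp(-(b + sigma * z))))) - target

    from scipy.optimize import brentq

    return float(brentq(mean_minus_target, -80.0, 80.0, xtol=1e-12))


def qtl_effect_logit(effect_pct: float, parental_means: tuple, sigma: float = 0.0) -> float:
    """Logit-scale coefficient moving the expected (marginal) proportion from
    the hom baseline by effect_pct/100 of the parental gap."""
    p_cyd, p_mel = parental_means
    target = p_cyd + effect_pct / 100.0 * (p_mel - p_cyd)
    return solve_logit_for_mean(target, sigma) - solve_logit_for_mean(p_cyd, sigma)


def simulate_preference_phenotypes(
    true_genotypes: pd.DataFrame,
    lmap: LinkageMap,
    qtl_specs,
    parental_means: tuple = (0.05, 0.95),
    overdispersion_sd: float = 1.0,
    trials_spec: CountSpec | None = None,
    minutes_per_trial_spec: CountSpec | None = None,
    trial_length_minutes: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate courtship-minute phenotypes with planted QTLs.

    For male i, total courtship minutes n_i are the sum over trials of the
    per-trial minutes draw (capped at the trial length); minutes toward the
    melpomene female are Binomial(n_i, p_i) with

        logit(p_i) = logit(p_cyd) + sum_q beta_q * het_iq + u_i,
        u_i ~ Normal(0, overdispersion_sd^2),

    where beta_q shifts the expected proportion by effect_q% of the parental
    gap for a hom -> het substitution at QTL q.  Returns a phenotype table
    (id, minutes_mel, minutes_cyd, n_trials).
    """
    p_cyd, p_mel = parental_means
    if not (0 <= p_cyd < p_mel <= 1):
        raise ValueError("need 0 <= cydno mean < melpomene mean <= 1")
    trials_spec = trials_spec or CountSpec("shifted_poisson", lam=4.2, shift=1)
    minutes_per_trial_spec = minutes_per_trial_spec or CountSpec("poisson", lam=1.65)
    rng = np.random.default_rng(seed)
    n = len(true_genotypes)

    eta = np.full(n, solve_logit_for_mean(p_cyd, overdispersion_sd))
    for spec in qtl_specs:
        col = _qtl_column(lmap, spec)
        if col not in true_genotypes.columns:
            raise ValueError(f"true-genotype matrix lacks locus column {col!r}")
        beta = qtl_effect_logit(spec.effect_pct, parental_means, overdispersion_sd)
        eta = eta + beta * true_genotypes[col].to_numpy(dtype=float)
    if overdispersion_sd > 0:
        eta = eta + rng.normal(0.0, overdispersion_sd, n)

    trials = np.maximum(trials_spec.draw(n, rng), 1)
    lam = minutes_per_trial_spec
    if lam.kind == "poisson":  # sum of independent per-trial Poisson draws
        total = rng.poisson(lam.lam * trials)
    else:
        total = np.array([lam.draw(t, rng).sum() for t in trials])
    total = np.minimum(total, trials * trial_length_minutes)

    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(total, p)
    return pd.DataFrame(
        {
            "id": true_genotypes.index.to_numpy(),
            "minutes_mel": y,
            "minutes_cyd": total - y,
            "n_trials": trials,
        }
    )


def simulate_four_population_frequencies(
    n_sites: int,
    introgression_fraction: float,
    seed: int = 0,
    chrom: str = "chr1",
    spacing_bp: int = 1000,
) -> pd.DataFrame:
    """Per-site derived-allele frequencies for (P1, P2, P3, outgroup).

    P1 and P2 are conspecific populations drawn from a shared low-derived
    Beta(1.5, 8) distribution; P3 is the divergent donor with Beta(8, 1.5)
    frequencies; the outgroup is fixed ancestral (0).  Introgression moves
    P2 toward P3 proportionally at every site:
    p2 = (1 - f) * p2_background + f * p3, so the windowed f_d estimate is
    centred near f.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if not 0 <= introgression_fraction <= 1:
        raise ValueError("introgression_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    f = introgression_fraction
    p1 = rng.beta(1.5, 8.0, n_sites)
    p2_bg = rng.beta(1.5, 8.0, n_sites)
    p3 = rng.beta(8.0, 1.5, n_sites)
    p2 = (1.0 - f) * p2_bg + f * p3
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": spacing_bp * np.arange(1, n_sites + 1),
            "p1": p1,
            "p2": p2,
            "p3": p3,
            "p4": 0.0,
        }
    )
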
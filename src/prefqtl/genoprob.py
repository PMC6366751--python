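"""Posterior genotype probabilities along a backcross linkage map.

A backcross individual's true genotype sequence along a chromosome is a
two-state Markov chain (hom / het) with switch probability across a gap of
d cM equal to the Haldane recombination fraction r(d), a flat 0.5/0.5 prior
at the chromosome start, and emissions that equal the true state with
probability 1 - error_rate (missing markers are uninformative).  The
forward-backward algorithm yields P(het) at every marker and at every
grid position (whole-cM steps by default), with grid positions treated as
pseudo-markers that emit nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeProbabilities, LinkageMap
from .ld import recomb_fraction

__all__ = ["compute_genoprob"]


def _chrom_grid(positions: np.ndarray, grid_step: float):
    """Union of marker positions and whole-grid_step positions, sorted.

    Returns (grid positions, indices of the marker positions within the grid).
    """
    lo, hi = 0.0, float(positions.max())
    steps = np.arange(lo, hi + 1e-9, grid_step)
    grid = np.unique(np.round(np.concatenate([positions, steps]), 9))
    marker_idx = np.searchsorted(grid, np.round(positions, 9))
    return grid, marker_idx


def compute_genoprob(
    lmap: LinkageMap,
    genotypes: pd.DataFrame,
    error_rate: float = 0.001,
    grid_step: float = 1.0,
) -> GenotypeProbabilities:
    """Forward-backward genotype posteriors for every individual.

    Parameters
    ----------
    genotypes : DataFrame indexed by individual id, one column per map
        marker, values 0 (hom), 1 (het) or NaN (missing).
    error_rate : probability that an observed non-missing genotype differs
        from the true one (applied symmetrically); must be in [0, 0.5).
    grid_step : spacing (cM) of the pseudo-marker evaluation grid added to
        the marker positions.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    unknown = set(genotypes.columns) - set(lmap.markers)
    if unknown:
        raise ValueError(f"markers not on the map: {sorted(unknown)[:5]}")

    ids = genotypes.index.to_numpy()
    n_ind = len(ids)
    chrom_frames = []
    post_blocks = []
    for chrom in lmap.chromosomes:
        sub = lmap.chrom_table(chrom)
        markers = [m for m in sub["marker"] if m in genotypes.columns]
        if not markers:
            raise ValueError(f"no genotype columns for chromosome {chrom}")
        pos = sub.set_index("marker").loc[markers, "pos_cm"].to_numpy(dtype=float)
        obs = genotypes[markers].to_numpy(dtype=float)  # (n_ind, n_markers)

        grid, marker_idx = _chrom_grid(pos, grid_step)
        n_pos = len(grid)

        # emission probabilities P(obs | state) per individual/grid point/state
        emit = np.ones((n_ind, n_pos, 2))
        for j, mi in enumerate(marker_idx):
            o = obs[:, j]
            seen = ~np.isnan(o)
            is_het = seen & (o == 1.0)
            is_hom = seen & (o == 0.0)
            if np.any(seen & ~is_het & ~is_hom):
                raise ValueError(f"genotype codes must be 0/1/NaN (marker {markers[j]})")
            # column order: state 0 = hom, state 1 = het
            emit[is_hom, mi, 0] *= 1.0 - error_rate
            emit[is_hom, mi, 1] *= error_rate
            emit[is_het, mi, 0] *= error_rate
            emit[is_het, mi, 1] *= 1.0 - error_rate

        gaps = np.diff(grid)
        if np.any(gaps < 0):
            raise ValueError("grid positions must be non-decreasing")
        r = recomb_fraction(gaps)  # (n_pos-1,)

        # scaled forward-backward, vectorized across individuals
        alpha = np.empty((n_ind, n_pos, 2))
        scale = np.empty((n_ind, n_pos))
        a = 0.5 * emit[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        if np.any(scale[:, 0] == 0):
            raise ValueError("impossible genotype data at zero error rate")
        alpha[:, 0] = a / scale[:, 0, None]
        for t in range(1, n_pos):
            stay, sw = 1.0 - r[t - 1], r[t - 1]
            pred = np.empty((n_ind, 2))
            pred[:, 0] = alpha[:, t - 1, 0] * stay + alpha[:, t - 1, 1] * sw
            pred[:, 1] = alpha[:, t - 1, 0] * sw + alpha[:, t - 1, 1] * stay
            a = pred * emit[:, t]
            s = a.sum(axis=1)
            if np.any(s == 0):
                raise ValueError("impossible genotype data at zero error rate")
            scale[:, t] = s
            alpha[:, t] = a / s[:, None]

        beta = np.ones((n_ind, 2))
        post = np.empty((n_ind, n_pos))
        post[:, -1] = alpha[:, -1, 1]
        for t in range(n_pos - 2, -1, -1):
            stay, sw = 1.0 - r[t], r[t]
            be = beta * emit[:, t + 1]
            nb = np.empty_like(be)
            nb[:, 0] = be[:, 0] * stay + be[:, 1] * sw
            nb[:, 1] = be[:, 0] * sw + be[:, 1] * stay
            beta = nb / scale[:, t + 1, None]
            unnorm = alpha[:, t] * beta
            post[:, t] = unnorm[:, 1] / unnorm.sum(axis=1)

        is_marker = np.zeros(n_pos, dtype=bool)
        is_marker[marker_idx] = True
        chrom_frames.append(
            pd.DataFrame({"chrom": chrom, "pos_cm": grid, "is_marker": is_marker})
        )
        post_blocks.append(post)

    grid_df = pd.concat(chrom_frames, ignore_index=True)
    return GenotypeProbabilities(ids, grid_df, np.concatenate(post_blocks, axis=1))
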
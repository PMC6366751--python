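"""Map-distance arithmetic and linkage-disequilibrium decay under random mating.

Two map functions convert genetic distance d (in cM) to a recombination
fraction r:

* Haldane (default, no crossover interference): r = (1 - exp(-2d/100)) / 2
* Kosambi (interference): r = tanh(2d/100) / 2

Under random mating, LD between two loci with recombination fraction r decays
geometrically: D(t) = D(0) * (1 - r)^t, i.e. a fractional loss of r per
generation (0.5 for unlinked loci).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "recomb_fraction",
    "ld_decline",
    "ld_trajectory",
    "expected_recombinants",
]

_FUNCTIONS = ("haldane", "kosambi")


def recomb_fraction(d_cm, function: str = "haldane"):
    """Recombination fraction for a map distance of ``d_cm`` centiMorgans."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    if function == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif function == "kosambi":
        r = 0.5 * np.tanh(2.0 * d / 100.0)
    else:
        raise ValueError(f"unknown map function {function!r}; use one of {_FUNCTIONS}")
    return float(r) if np.isscalar(d_cm) else r


def ld_decline(
    d_cm: float | None = None,
    t: float = 1,
    *,
    r: float | None = None,
    unlinked: bool = False,
    function: str = "haldane",
) -> dict:
    """LD decay over ``t`` generations of random mating.

    Exactly one of ``d_cm``, ``r`` or ``unlinked=True`` specifies the locus
    pair.  Returns per-generation loss (= r), the fraction of the original D
    retained after t generations ((1-r)^t), and the fraction lost.
    """
    if t < 0:
        raise ValueError("generations must be >= 0")
    given = sum(x is not None and x is not False for x in (d_cm, r, unlinked))
    if given != 1:
        raise ValueError("specify exactly one of d_cm, r, unlinked")
    if unlinked:
        r_val = 0.5
    elif r is not None:
        if not 0 <= r <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")
        r_val = float(r)
    else:
        r_val = recomb_fraction(d_cm, function)
    retained = (1.0 - r_val) ** t
    return {
        "r": r_val,
        "generations": t,
        "per_generation_loss_pct": round(100.0 * r_val, 1),
        "retained_fraction": retained,
        "lost_fraction": 1.0 - retained,
    }


def ld_trajectory(
    d_cm: float | None = None,
    t_max: int = 50,
    *,
    r: float | None = None,
    unlinked: bool = False,
    function: str = "haldane",
) -> pd.DataFrame:
    """D(t)/D(0) for t = 0..t_max generations (columns t, retained_fraction)."""
    base = ld_decline(d_cm, 0, r=r, unlinked=unlinked, function=function)
    t = np.arange(int(t_max) + 1)
    return pd.DataFrame({"t": t, "retained_fraction": (1.0 - base["r"]) ** t})


def expected_recombinants(d_cm: float, n_meioses: float, function: str = "haldane") -> float:
    """Expected number of recombinant meioses between loci ``d_cm`` apart."""
    if n_meioses < 0:
        raise ValueError("n_meioses must be >= 0")
    return n_meioses * recomb_fraction(d_cm, function)
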
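"""Windowed four-taxon admixture estimation from derived-allele frequencies.

Sites carry derived-allele frequencies for (P1, P2, P3, O): P1 an allopatric
population conspecific with P2, P2 the sympatric population tested for
introgression, P3 the donor/recipient candidate, and O an outgroup used to
polarize alleles.  Per site,

    ABBA = (1 - p1) * p2 * p3 * (1 - p4)
    BABA = p1 * (1 - p2) * p3 * (1 - p4)

and the dynamic-donor denominator substitutes pD = max(p2, p3) for both p2
and p3.  Over a window, D = sum(ABBA - BABA) / sum(ABBA + BABA) and
f_d = sum(ABBA - BABA) / sum(ABBA_D - BABA_D); f_d approximates the
proportional effective migration rate (0 = no localized admixture, 1 =
complete localized admixture).  Windows are half-open [start, end) on
0-based physical coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "site_components",
    "windowed_fd",
    "read_frequency_csv",
    "frequencies_from_vcf",
]

FREQ_COLUMNS = ["chrom", "pos", "p1", "p2", "p3", "p4"]


def site_components(p1, p2, p3, p4):
    """Per-site (abba, baba, abba_d, baba_d) summands; inputs may be arrays."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    for name, p in zip("p1 p2 p3 p4".split(), (p1, p2, p3, p4)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} outside [0, 1]")
    pd_ = np.maximum(p2, p3)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    abba_d = (1 - p1) * pd_ * pd_ * (1 - p4)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - p4)
    return abba, baba, abba_d, baba_d


def _validate_freqs(freqs: pd.DataFrame) -> pd.DataFrame:
    missing = set(FREQ_COLUMNS) - set(freqs.columns)
    if missing:
        raise ValueError(f"frequency table missing columns {sorted(missing)}")
    for chrom, grp in freqs.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return freqs


def windowed_fd(
    freqs: pd.DataFrame,
    width: int = 100_000,
    step: int = 20_000,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Sliding-window D and f_d.

    Windows tile each chromosome as half-open [start, start + width) with
    the given step, starting at 0.  Windows with fewer than ``min_sites``
    sites or a non-positive f_d denominator are emitted with f_d = NaN and
    ``defined = False``; negative f_d values are reported, not clipped.
    Output columns: chrom, start, end, n_sites, D, fd, defined.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if not 0 < step <= width:
        raise ValueError("need 0 < step <= width")
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    freqs = _validate_freqs(freqs)

    out = []
    for chrom, grp in freqs.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        abba, baba, abba_d, baba_d = site_components(
            grp["p1"], grp["p2"], grp["p3"], grp["p4"]
        )
        num = np.concatenate([[0.0], np.cumsum(abba - baba)])
        den_d = np.concatenate([[0.0], np.cumsum(abba_d - baba_d)])
        den_t = np.concatenate([[0.0], np.cumsum(abba + baba)])
        last = pos.max()
        starts = np.arange(0, last + 1, step)
        for start in starts:
            end = start + width
            i = np.searchsorted(pos, start, side="left")
            j = np.searchsorted(pos, end, side="left")
            n_sites = int(j - i)
            s_num = num[j] - num[i]
            s_dd = den_d[j] - den_d[i]
            s_dt = den_t[j] - den_t[i]
            d_stat = s_num / s_dt if s_dt > 0 else np.nan
            ok = n_sites >= min_sites and s_dd > 0
            out.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": n_sites,
                    "D": d_stat,
                    "fd": s_num / s_dd if ok else np.nan,
                    "defined": bool(ok),
                }
            )
    return pd.DataFrame(out)


def read_frequency_csv(path) -> pd.DataFrame:
    """Read and validate a per-site frequency CSV (chrom,pos,p1,p2,p3,p4)."""
    return _validate_freqs(pd.read_csv(path))


def frequencies_from_vcf(path, pops: dict) -> pd.DataFrame:
    """Derived-allele frequencies from a VCF with population sample lists.

    ``pops`` maps 'p1','p2','p3','p4' to lists of sample names; the
    alternate allele is polarized against the outgroup ('p4') consensus:
    sites where the outgroup carries the ALT allele at frequency > 0.5 are
    flipped, and sites with fully missing outgroup genotypes are skipped.
    Requires cyvcf2; biallelic SNPs only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {}
    for key in ("p1", "p2", "p3", "p4"):
        members = pops.get(key, [])
        missing = [s for s in members if s not in samples]
        if missing:
            raise ValueError(f"samples not in VCF for {key}: {missing}")
        idx[key] = np.array([samples.index(s) for s in members], dtype=int)
        if idx[key].size == 0:
            raise ValueError(f"population {key} is empty")
    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        freqs = {}
        skip = False
        for key, cols in idx.items():
            sub = gts[cols].ravel()
            called = ~np.isnan(sub)
            if not called.any():
                skip = key == "p4"
                freqs[key] = np.nan
            else:
                freqs[key] = float(sub[called].mean())
        if skip or any(np.isnan(freqs[k]) for k in freqs):
            continue
        if freqs["p4"] > 0.5:  # polarize: outgroup carries the ancestral state
            freqs = {k: 1.0 - v for k, v in freqs.items()}
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "p1": freqs["p1"],
                "p2": freqs["p2"],
                "p3": freqs["p3"],
                "p4": freqs["p4"],
            }
        )
    return _validate_freqs(pd.DataFrame(rows, columns=FREQ_COLUMNS))
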
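"""File formats and the end-to-end pipeline driver.

The genotype interchange format is an R/qtl-style cross CSV: a header row of
``id`` plus marker names, a second row with each marker's chromosome, a
third row with its cM position, then one row per individual with genotype
codes (default ``CC`` hom, ``CM`` het, ``-``/``NA``/empty missing).  The
rotated variant (one row per marker) is auto-detected.  Phenotypes travel
in a plain CSV with columns id, minutes_mel, minutes_cyd, n_trials.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import LinkageMap, validate_phenotypes

logger = logging.getLogger("prefqtl")

__all__ = [
    "read_cross",
    "write_cross",
    "read_phenotypes",
    "write_phenotypes",
    "RunConfig",
    "pipeline_run",
]

DEFAULT_CODES = {"CC": 0.0, "CM": 1.0}
MISSING_CODES = {"-", "", "NA", "na", "nan"}


def write_cross(lmap: LinkageMap, genotypes: pd.DataFrame, path,
                codes: dict = DEFAULT_CODES, missing: str = "-") -> None:
    """Write genotypes + map in the R/qtl-style cross CSV dialect."""
    inv = {v: k for k, v in codes.items()}
    markers = [m for m in lmap.markers if m in genotypes.columns]
    tab = lmap.table.set_index("marker")
    with open(path, "w") as fh:
        fh.write("id," + ",".join(markers) + "\n")
        fh.write("," + ",".join(str(tab.loc[m, "chrom"]) for m in markers) + "\n")
        fh.write("," + ",".join(f"{tab.loc[m, 'pos_cm']:g}" for m in markers) + "\n")
        g = genotypes[markers].to_numpy()
        for i, ind in enumerate(genotypes.index):
            row = [inv[v] if not np.isnan(v) else missing for v in g[i]]
            fh.write(f"{ind}," + ",".join(row) + "\n")


def _parse_cross_frame(raw: pd.DataFrame, codes: dict):
    header = raw.iloc[0].tolist()
    markers = [str(m) for m in header[1:]]
    chroms = [str(c) for c in raw.iloc[1, 1:].tolist()]
    try:
        pos = [float(p) for p in raw.iloc[2, 1:].tolist()]
    except (TypeError, ValueError) as err:
        raise ValueError(f"marker position row is not numeric: {err}") from None
    lmap = LinkageMap(pd.DataFrame({"marker": markers, "chrom": chroms, "pos_cm": pos}))
    body = raw.iloc[3:]
    ids = body.iloc[:, 0].astype(str).to_numpy()
    vals = np.full((len(ids), len(markers)), np.nan)
    for j in range(len(markers)):
        col = body.iloc[:, j + 1]
        for i, cell in enumerate(col):
            s = "" if pd.isna(cell) else str(cell).strip()
            if s in MISSING_CODES:
                continue
            if s not in codes:
                raise ValueError(
                    f"unknown genotype code {s!r} at data row {i + 1}, "
                    f"marker {markers[j]!r}"
                )
            vals[i, j] = codes[s]
    genotypes = pd.DataFrame(vals, index=ids, columns=markers)
    genotypes.index.name = "id"
    return lmap, genotypes


def read_cross(
    genotype_csv,
    pheno_csv=None,
    codes: dict = DEFAULT_CODES,
    fmt: str = "auto",
):
    """Read an R/qtl-style cross CSV (auto-detecting the rotated layout).

    Returns (LinkageMap, genotype DataFrame) or, with ``pheno_csv``,
    (LinkageMap, genotypes, phenotypes, excluded_ids) where ``excluded_ids``
    lists phenotyped individuals lacking genotype data.
    """
    raw = pd.read_csv(genotype_csv, header=None, dtype=object, keep_default_na=False)
    if raw.shape[0] < 4 and raw.shape[1] >= 4:
        raw = raw.T.reset_index(drop=True)
    else:

        def _numeric_row(r):
            try:
                [float(x) for x in raw.iloc[r, 1:].tolist()]
                return True
            except (TypeError, ValueError):
                return False

        if fmt == "csvr" or (fmt == "auto" and not _numeric_row(2) and raw.shape[1] > 3):
            transposed = raw.T.reset_index(drop=True)
            try:
                [float(x) for x in transposed.iloc[2, 1:].tolist()]
                raw = transposed
            except (TypeError, ValueError):
                pass
    lmap, genotypes = _parse_cross_frame(raw, codes)
    if pheno_csv is None:
        return lmap, genotypes
    pheno = read_phenotypes(pheno_csv)
    genotyped = set(genotypes.index)
    excluded = [i for i in pheno["id"].astype(str) if i not in genotyped]
    if excluded:
        logger.warning(
            "%d phenotyped individuals have no genotype data and are excluded "
            "from mapping", len(excluded),
        )
    return lmap, genotypes, pheno, excluded


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    pheno["id"] = pheno["id"].astype(str)
    return validate_phenotypes(pheno)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    validate_phenotypes(pheno).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of an end-to-end mapping run."""

    genotype_csv: str
    pheno_csv: str
    out_dir: str
    error_rate: float = 0.001
    grid_step: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    map_function: str = "haldane"
    parental_means: tuple = (0.05, 0.95)

    def __post_init__(self):
        for name in ("genotype_csv", "pheno_csv"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name}: {getattr(self, name)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed, "version": __version__}


def pipeline_run(config: RunConfig) -> dict:
    """Run genotype probabilities -> genome scan -> permutation threshold ->
    multi-QTL model -> effect sizes, writing per-stage CSVs and a JSON
    summary to ``config.out_dir``.  Returns the summary dict."""
    from .genoprob import compute_genoprob
    from .multiqtl import effect_size, fit_multiqtl, support_interval
    from .scan import permutation_threshold, scan_glmm

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    logger.info("[read] %s + %s", config.genotype_csv, config.pheno_csv)
    lmap, genotypes, pheno, dropped = read_cross(config.genotype_csv, config.pheno_csv)
    logger.info(
        "[read] %d markers, %d genotyped individuals, %d phenotyped "
        "(%d without genotypes)",
        len(lmap.markers), len(genotypes), len(pheno), len(dropped),
    )

    logger.info("[genoprob] error_rate=%g grid_step=%g", config.error_rate, config.grid_step)
    probs = compute_genoprob(lmap, genotypes, config.error_rate, config.grid_step)
    probs.to_frame().to_csv(out / "genoprob.csv", index=False)

    scan = scan_glmm(probs, pheno)
    scan.table.to_csv(out / "genome_scan_lod_score.csv", index=False)
    logger.info("[scan] %d positions, n=%d", len(scan.table), scan.n_used)

    perm = permutation_threshold(
        probs, pheno, n_permutations=config.n_permutations,
        alpha=config.alpha, seed=config.seed,
    )
    thr = perm.threshold(config.alpha)
    pd.DataFrame({"max_lod": perm.max_lods}).to_csv(out / "permutations.csv", index=False)
    logger.info("[permute] n=%d threshold(%.2f)=%.3f", config.n_permutations, config.alpha, thr)

    peaks = []
    for chrom in lmap.chromosomes:
        c, pos, lod = scan.peak(chrom)
        if lod >= thr:
            lo, hi = support_interval(scan, chrom)
            peaks.append(
                {
                    "chrom": c, "pos_cm": pos, "lod": lod,
                    "ci_lo": lo, "ci_hi": hi,
                    "p_genomewide": perm.pvalue(lod),
                }
            )
    summary = {"provenance": prov, "threshold": thr, "n_used": scan.n_used,
               "excluded_zero_courtship": scan.excluded_ids, "peaks": peaks}

    if peaks:
        loci = [(p["chrom"], p["pos_cm"]) for p in peaks]
        model = fit_multiqtl(probs, pheno, loci, threshold=thr)
        effects = []
        for locus in loci:
            est = effect_size(probs, pheno, locus, config.parental_means)
            effects.append(
                {
                    "locus": f"{locus[0]}@{locus[1]:g}",
                    "mean_hom": est.mean_hom, "mean_het": est.mean_het,
                    "percent_of_parental_difference": est.percent_of_parental_difference,
                }
            )
        model.drop_tests.to_csv(out / "qtl_model_drop_tests.csv", index=False)
        summary["model"] = {
            "loci": [f"{c}@{p:g}" for c, p in model.loci],
            "interactions": model.interactions,
            "lod": model.lod,
            "plod": model.plod,
            "sigma": model.sigma,
        }
        summary["effects"] = effects
        logger.info("[fit] LOD=%.2f pLODa=%.2f", model.lod, model.plod)
    else:
        logger.info("[fit] no peaks above threshold; skipping multi-QTL model")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
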
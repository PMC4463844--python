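"""Null-model confidence intervals for Delta(SNP-index).

Under the null hypothesis of no QTL, the allele frequency in each bulk is
driven only by Mendelian sampling of the bulked individuals and by read
sampling.  The simulation draws, for each bulk independently,

  1. k genotypes from the neutral genotype law of the mating design
     (F2 1:2:1, F4 7:2:7, RIL 1:0:1 for LL:LH:HH),
  2. the bulk's true high-allele frequency p (each individual contributes
     0, 1/2 or 1),
  3. high-allele reads ~ Binomial(depth, p*(1-eps) + (1-p)*eps),

then forms Delta = high-bulk index - low-bulk index.  Empirical two-sided
quantiles of many such replicates, tabulated by read depth, give the
confidence bounds against which observed Delta values are judged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["NullDesign", "CiTable", "simulate_null_delta", "build_ci_table", "attach_ci"]

#: Neutral per-site genotype probabilities (LL, LH, HH) by generation.
GENOTYPE_PROBS = {
    "F2": (0.25, 0.5, 0.25),
    "F4": (7 / 16, 1 / 8, 7 / 16),
    "RIL": (0.5, 0.0, 0.5),
}


@dataclass(frozen=True)
class NullDesign:
    """Mating design and sequencing-error assumptions for the null model."""

    generation: str = "F4"
    k: int = 10
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.generation not in GENOTYPE_PROBS:
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.k < 1:
            raise ValueError("bulk size k must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def genotype_probs(self) -> tuple[float, float, float]:
        return GENOTYPE_PROBS[self.generation]


def _bulk_index(
    rng: np.random.Generator, design: NullDesign, depth: int, n_reps: int
) -> np.ndarray:
    counts = rng.multinomial(design.k, design.genotype_probs, size=n_reps)
    p = (counts[:, 1] * 0.5 + counts[:, 2]) / design.k
    eps = design.error_rate
    p_read = p * (1.0 - eps) + (1.0 - p) * eps
    high = rng.binomial(depth, p_read)
    return high / depth


def simulate_null_delta(
    design: NullDesign,
    depth_lsb: int,
    depth_hsb: int,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo sample of Delta(SNP-index) under no QTL.

    The two bulks are simulated independently at their respective depths;
    deterministic under a fixed seed.
    """
    if depth_lsb < 1 or depth_hsb < 1:
        raise ValueError("depths must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hsb = _bulk_index(rng, design, depth_hsb, n_reps)
    lsb = _bulk_index(rng, design, depth_lsb, n_reps)
    return hsb - lsb


@dataclass
class CiTable:
    """Simulated null quantiles of Delta indexed by read depth.

    ``bounds`` has the depth as index and columns ``lo95, hi95, lo99,
    hi99`` (generally ``lo<level>``/``hi<level>`` for each requested
    level).  Lookups at depths outside the table clamp to the nearest
    tabulated depth.
    """

    bounds: pd.DataFrame
    design: NullDesign
    n_reps: int
    seed: int | None = None
    levels: tuple[float, ...] = (0.95, 0.99)

    def __post_init__(self) -> None:
        self.bounds = self.bounds.sort_index()

    @property
    def depths(self) -> np.ndarray:
        return self.bounds.index.to_numpy()

    def _nearest(self, depth) -> np.ndarray:
        tab = self.depths
        d = np.atleast_1d(np.asarray(depth))
        j = np.clip(np.searchsorted(tab, d), 0, len(tab) - 1)
        jm = np.maximum(j - 1, 0)
        use_lower = np.abs(tab[jm] - d) <= np.abs(tab[j] - d)
        return np.where(use_lower & (j > 0), tab[jm], tab[j])

    def lookup(self, depth, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) bounds at the given depth(s), depth clamped to
        the nearest tabulated value."""
        pct = _level_tag(level)
        near = self._nearest(depth)
        lo = self.bounds[f"lo{pct}"].loc[near].to_numpy()
        hi = self.bounds[f"hi{pct}"].loc[near].to_numpy()
        return lo, hi

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"## null CI table: generation={self.design.generation} k={self.design.k} "
                f"error_rate={self.design.error_rate} n_reps={self.n_reps} seed={self.seed}\n"
            )
            fh.write("#depth\t" + "\t".join(self.bounds.columns) + "\n")
            self.bounds.to_csv(fh, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path) -> "CiTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            first = fh.readline()
            for tok in first.replace("## null CI table:", "").split():
                if "=" in tok:
                    key, val = tok.split("=", 1)
                    meta[key] = val
            df = pd.read_csv(fh, sep="\t")
        df = df.rename(columns={df.columns[0]: "depth"}).set_index("depth")
        df.columns = [c.lstrip("#") for c in df.columns]
        design = NullDesign(
            generation=meta.get("generation", "F4"),
            k=int(meta.get("k", 10)),
            error_rate=float(meta.get("error_rate", 0.0)),
        )
        seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
        levels = tuple(
            sorted({int(c[2:]) / 100 for c in df.columns if c.startswith("lo")})
        )
        return cls(bounds=df, design=design, n_reps=int(meta.get("n_reps", 0)), seed=seed,
                   levels=levels)


def _level_tag(level: float) -> str:
    return f"{level * 100:g}".replace(".", "_")


def build_ci_table(
    design: NullDesign,
    depths,
    levels: tuple[float, ...] = (0.95, 0.99),
    n_reps: int = 10_000,
    seed: int | None = None,
) -> CiTable:
    """Tabulate empirical two-sided null quantiles of Delta per read depth.

    Both bulks are simulated at the same depth for each table row (the
    depth of the less-covered bulk is the conservative lookup key).
    Quantiles are order statistics with linear interpolation.
    """
    depths = sorted({int(d) for d in np.atleast_1d(np.asarray(depths))})
    if not depths:
        raise ValueError("depths must be non-empty")
    if n_reps < 1000:
        logger.warning("build_ci_table: n_reps=%d < 1000; quantiles may be unstable", n_reps)
    rng = np.random.default_rng(seed)
    rows = {}
    for d in depths:
        delta = simulate_null_delta(design, d, d, n_reps, rng)
        row = {}
        for lvl in levels:
            alpha = 1.0 - lvl
            lo, hi = np.quantile(delta, [alpha / 2, 1.0 - alpha / 2])
            pct = _level_tag(lvl)
            row[f"lo{pct}"] = lo
            row[f"hi{pct}"] = hi
        rows[d] = row
    bounds = pd.DataFrame.from_dict(rows, orient="index")
    bounds.index.name = "depth"
    return CiTable(bounds=bounds, design=design, n_reps=n_reps, seed=seed, levels=tuple(levels))


def attach_ci(
    windows: pd.DataFrame,
    sites: pd.DataFrame,
    ci: CiTable,
) -> pd.DataFrame:
    """Average per-SNP confidence bounds into each window.

    Each SNP's bound is looked up at min(lsb_depth, hsb_depth), clamped to
    the nearest tabulated depth; a window's bound is the unweighted mean of
    the bounds of the SNPs it contains.  Windows without reportable means
    (NaN) carry NaN bounds.
    """
    out = windows.copy()
    min_depth = np.minimum(sites["lsb_depth"].to_numpy(), sites["hsb_depth"].to_numpy())
    per_site = {}
    for lvl in ci.levels:
        lo, hi = ci.lookup(min_depth, lvl)
        pct = _level_tag(lvl)
        per_site[f"lo{pct}"] = lo
        per_site[f"hi{pct}"] = hi
    cols = {name: np.full(len(windows), np.nan) for name in per_site}
    for chrom in out["chrom"].unique():
        wmask = (out["chrom"] == chrom).to_numpy()
        smask = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[smask, "pos"].to_numpy()
        starts = out.loc[wmask, "start"].to_numpy()
        ends = out.loc[wmask, "end"].to_numpy()
        lo_i = np.searchsorted(pos, starts, side="left")
        hi_i = np.searchsorted(pos, ends, side="right")
        n = hi_i - lo_i
        ok = n > 0
        safe_n = np.maximum(n, 1).astype(float)
        for name, vals in per_site.items():
            csum = np.concatenate([[0.0], np.cumsum(vals[smask])])
            mean = (csum[hi_i] - csum[lo_i]) / safe_n
            cols[name][wmask] = np.where(ok, mean, np.nan)
    for name, arr in cols.items():
        out[name] = np.where(np.isnan(out["delta"].to_numpy()), np.nan, arr)
    return out
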
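"""SNP-index, Delta(SNP-index) and sliding-window averages.

The SNP-index of a bulk at a site is the fraction of that bulk's reads
carrying the high-parent allele: 0 means every read derives from the low
parent, 1 from the high parent.  Delta(SNP-index) is the high-bulk index
minus the low-bulk index, so a genuine QTL drives Delta towards +1 while
unlinked regions fluctuate around 0.  Windowed averages use a rectangular
sliding window (default 5 Mb, 10 kb step).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["snp_index", "delta_snp_index", "add_indices", "sliding_windows"]

WINDOW_COLUMNS = [
    "chrom", "start", "end", "mid", "n_snps", "lsb_index", "hsb_index", "delta",
]


def snp_index(high_count, depth):
    """Fraction of reads supporting the high-parent allele.

    Both arguments may be scalars or arrays.  Zero or negative depth is a
    contract violation (such sites must have been filtered out earlier).
    """
    high = np.asarray(high_count, dtype=float)
    d = np.asarray(depth, dtype=float)
    if np.any(d <= 0):
        raise ValueError("snp_index undefined at zero depth; filter sites first")
    if np.any(high < 0) or np.any(high > d):
        raise ValueError("high_count must lie in [0, depth]")
    out = high / d
    return float(out) if out.ndim == 0 else out


def delta_snp_index(hsb_index, lsb_index):
    """Delta = high-bulk index minus low-bulk index, in [-1, 1]."""
    return np.asarray(hsb_index, dtype=float) - np.asarray(lsb_index, dtype=float)


def add_indices(sites: pd.DataFrame) -> pd.DataFrame:
    """Attach lsb_index, hsb_index and delta columns to a polarized site table."""
    out = sites.copy()
    out["lsb_index"] = snp_index(out["lsb_high"], out["lsb_depth"])
    out["hsb_index"] = snp_index(out["hsb_high"], out["hsb_depth"])
    out["delta"] = delta_snp_index(out["hsb_index"], out["lsb_index"])
    return out


def _window_starts(length: int, step: int) -> np.ndarray:
    return np.arange(1, length + 1, step, dtype=np.int64)


def sliding_windows(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 5_000_000,
    step_bp: int = 10_000,
    min_snps: int = 3,
    value_columns: tuple[str, ...] = ("lsb_index", "hsb_index", "delta"),
    depth_weighted: bool = False,
) -> pd.DataFrame:
    """Unweighted window means of per-SNP statistics along each chromosome.

    Windows start at 1, 1+step, 1+2*step, ... while the start does not
    exceed the chromosome length; each spans [start, min(start+W-1, L)]
    (1-based inclusive, terminal window truncated).  A window's mean is the
    plain average over the SNPs it contains; windows holding fewer than
    ``min_snps`` SNPs are emitted with NaN means so sparse regions stay
    visible but unreported.

    ``sites`` must be position-sorted within each chromosome.  With
    ``depth_weighted=True`` each bulk's index is weighted by that bulk's
    depth and delta by the smaller of the two depths, instead of the plain
    SNP average.
    """
    weight_for = {"lsb_index": "lsb_depth", "hsb_index": "hsb_depth"}
    if step_bp <= 0 or window_bp < step_bp:
        raise ValueError("require window_bp >= step_bp > 0")
    frames = []
    for chrom, length in chrom_lengths.items():
        sub = sites.loc[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites on {chrom} are not position-sorted")
        starts = _window_starts(int(length), int(step_bp))
        ends = np.minimum(starts + int(window_bp) - 1, int(length))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        win = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "mid": (starts + ends) // 2,
                "n_snps": n,
            }
        )
        ok = n >= min_snps
        safe_n = np.maximum(n, 1).astype(float)
        for col in value_columns:
            vals = sub[col].to_numpy(dtype=float)
            if depth_weighted:
                if col in weight_for:
                    w = sub[weight_for[col]].to_numpy(dtype=float)
                else:
                    w = np.minimum(
                        sub["lsb_depth"].to_numpy(dtype=float),
                        sub["hsb_depth"].to_numpy(dtype=float),
                    )
                csum = np.concatenate([[0.0], np.cumsum(vals * w)])
                wsum = np.concatenate([[0.0], np.cumsum(w)])
                denom = np.maximum(wsum[hi] - wsum[lo], 1e-300)
                mean = (csum[hi] - csum[lo]) / denom
            else:
                csum = np.concatenate([[0.0], np.cumsum(vals)])
                mean = (csum[hi] - csum[lo]) / safe_n
            win[col] = np.where(ok, mean, np.nan)
        frames.append(win)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "mid", "n_snps", *value_columns])
    return pd.concat(frames, ignore_index=True)
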
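"""Calling candidate QTL intervals from windowed Delta(SNP-index) scans.

A window is *significant* when its mean Delta falls outside the simulated
null confidence bounds at the chosen level and, by default, its bulk
indices satisfy the extreme-allele-frequency criteria (high bulk >= 0.9,
low bulk <= 0.1).  Runs of consecutive significant windows are merged into
candidate intervals whose boundaries are the outermost window endpoints,
mirroring the flanking-marker convention used when such intervals are
reported.  Physical interval length is the plain difference of the
flanking coordinates (end - start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QtlInterval",
    "call_intervals",
    "refine_to_snps",
    "interval_length",
    "genetic_length",
    "genes_in_interval",
    "intervals_to_bed",
    "intervals_report",
]


@dataclass
class QtlInterval:
    """A candidate QTL region merged from consecutive significant windows."""

    chrom: str
    start: int
    end: int
    peak_delta: float
    peak_pos: int
    level: int  # highest significance level (percent) every window attained
    mean_hsb_index: float
    mean_lsb_index: float
    n_windows: int
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must not exceed end")

    @property
    def length_bp(self) -> int:
        return interval_length(self.start, self.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def interval_length(start: int, end: int) -> int:
    """Physical span in bp as the difference of the flanking coordinates."""
    return int(end) - int(start)


def genetic_length(pos_a_cm: float, pos_b_cm: float) -> float:
    """Genetic span in cM between two map positions."""
    return abs(float(pos_b_cm) - float(pos_a_cm))


def _tag(level: int) -> str:
    return f"{level:g}"


def call_intervals(
    windows: pd.DataFrame,
    level: int = 95,
    hsb_min: float | None = 0.9,
    lsb_max: float | None = 0.1,
    min_run: int = 2,
    abs_delta_min: float | None = None,
) -> list[QtlInterval]:
    """Merge runs of significant windows into candidate QTL intervals.

    Significance of a window requires its Delta outside the attached
    two-sided null bound at ``level`` percent, AND (unless disabled by
    passing None) mean high-bulk index >= hsb_min and mean low-bulk index
    <= lsb_max, AND |Delta| >= abs_delta_min if that optional absolute
    cutoff is set.  Runs of at least ``min_run`` consecutive windows are
    reported; boundaries are the outermost window endpoints.  Each
    interval records the highest level (99 over 95) at which *every* one
    of its windows is significant.
    """
    lo_col, hi_col = f"lo{_tag(level)}", f"hi{_tag(level)}"
    if lo_col not in windows.columns or hi_col not in windows.columns:
        raise ValueError(
            f"windows carry no {level}% confidence bounds; run null_ci.attach_ci first"
        )

    def _significant(lvl: int) -> np.ndarray:
        lo = windows[f"lo{_tag(lvl)}"].to_numpy(dtype=float)
        hi = windows[f"hi{_tag(lvl)}"].to_numpy(dtype=float)
        delta = windows["delta"].to_numpy(dtype=float)
        sig = (delta < lo) | (delta > hi)
        if hsb_min is not None:
            sig &= windows["hsb_index"].to_numpy(dtype=float) >= hsb_min
        if lsb_max is not None:
            sig &= windows["lsb_index"].to_numpy(dtype=float) <= lsb_max
        if abs_delta_min is not None:
            sig &= np.abs(delta) >= abs_delta_min
        return np.where(np.isnan(delta), False, sig)

    sig = _significant(level)
    has99 = "lo99" in windows.columns
    sig99 = _significant(99) if has99 else np.zeros(len(windows), dtype=bool)

    intervals: list[QtlInterval] = []
    for chrom in windows["chrom"].unique():
        idx = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        flags = sig[idx]
        run_start = None
        for j in range(len(idx) + 1):
            if j < len(idx) and flags[j]:
                if run_start is None:
                    run_start = j
                continue
            if run_start is not None:
                run = idx[run_start:j]
                if len(run) >= min_run:
                    sub = windows.iloc[run]
                    peak_row = sub.iloc[int(np.argmax(np.abs(sub["delta"].to_numpy())))]
                    attained = 99 if has99 and bool(sig99[run].all()) else level
                    intervals.append(
                        QtlInterval(
                            chrom=str(chrom),
                            start=int(sub["start"].min()),
                            end=int(sub["end"].max()),
                            peak_delta=float(peak_row["delta"]),
                            peak_pos=int(peak_row["mid"]),
                            level=attained,
                            mean_hsb_index=float(sub["hsb_index"].mean()),
                            mean_lsb_index=float(sub["lsb_index"].mean()),
                            n_windows=len(run),
                        )
                    )
                run_start = None
    return intervals


def refine_to_snps(
    interval: QtlInterval,
    sites: pd.DataFrame,
    ci,
    level: float = 0.95,
) -> QtlInterval:
    """Shrink an interval to its outermost individually significant SNPs.

    Mirrors reporting a QTL by its flanking markers: the refined bounds are
    the first and last SNPs inside the interval whose own Delta exceeds the
    per-SNP null bound at their observed depth.  If no SNP qualifies the
    interval is returned unchanged.
    """
    sub = sites.loc[
        (sites["chrom"] == interval.chrom)
        & (sites["pos"] >= interval.start)
        & (sites["pos"] <= interval.end)
    ]
    if sub.empty:
        return interval
    depth = np.minimum(sub["lsb_depth"].to_numpy(), sub["hsb_depth"].to_numpy())
    lo, hi = ci.lookup(depth, level)
    delta = sub["delta"].to_numpy(dtype=float)
    flank = sub.loc[(delta < lo) | (delta > hi), "pos"]
    if flank.empty:
        return interval
    out = QtlInterval(**{**interval.__dict__})
    out.start = int(flank.min())
    out.end = int(flank.max())
    return out


def genes_in_interval(gff_path, interval: QtlInterval, feature_type: str = "gene") -> list[str]:
    """Gene ids whose span overlaps the interval by at least 1 bp.

    The GFF3 is loaded into an in-memory gffutils database; strand is
    ignored for the overlap test and coordinates are 1-based inclusive on
    both sides, so a gene starting exactly at the interval end still
    overlaps by one base.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read GFF3 at {gff_path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type(feature_type):
        if (
            feat.seqid == interval.chrom
            and feat.start <= interval.end
            and feat.end >= interval.start
        ):
            genes.append(feat.id)
    return sorted(genes)


def intervals_to_bed(intervals: list[QtlInterval], path) -> None:
    """Write intervals as BED (0-based half-open; converted from the
    1-based inclusive internal coordinates)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, start=1):
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tQTL_{i}\t{abs(iv.peak_delta):.4f}\t.\n"
            )


def intervals_report(intervals: list[QtlInterval]) -> pd.DataFrame:
    """Human-readable per-interval report table."""
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "length_bp": iv.length_bp,
            "peak_delta": iv.peak_delta,
            "peak_pos": iv.peak_pos,
            "level": iv.level,
            "mean_hsb_index": iv.mean_hsb_index,
            "mean_lsb_index": iv.mean_lsb_index,
            "n_windows": iv.n_windows,
            "n_genes": len(iv.genes),
            "genes": ",".join(iv.genes),
        }
        for iv in intervals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length_bp", "peak_delta", "peak_pos", "level",
            "mean_hsb_index", "mean_lsb_index", "n_windows", "n_genes", "genes",
        ],
    )
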
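"""Model/Results interface over the QTL-seq pipeline.

``QtlSeqScan`` is built from a per-site allele-depth count table (two
bulks, two parents) plus the chromosome lengths and the mating design;
``fit()`` runs polarization, site filtering, SNP-index and
Delta(SNP-index) computation, the sliding-window scan, the null-model
confidence-interval simulation and bound attachment, and returns a
``QtlSeqResult`` holding the per-SNP table, the windowed scan with CI
bounds, and the CI table.  Interval calling, summary tables, plotting and
TSV export hang off the result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import call as _call
from . import null_ci as _null
from . import stats as _stats
from . import variant_io as _vio

__all__ = ["QtlSeqScan", "QtlSeqResult"]


class QtlSeqScan:
    """A QTL-seq genome scan model over a two-bulk count table.

    Parameters
    ----------
    counts : DataFrame
        Count table (see :mod:`qtlseq.variant_io` for the column contract).
    chrom_lengths : dict, optional
        Chromosome name -> length in bp.  Inferred from the largest
        observed position per chromosome when omitted.
    design : NullDesign, optional
        Mating design for the null simulation (default F4, bulk size 10).
    window_bp, step_bp, min_snps
        Sliding-window geometry (defaults 5 Mb, 10 kb, 3 SNPs).
    min_depth, min_quality
        Site filters: both bulks at depth >= min_depth and call quality >=
        min_quality.
    parent_fixed_frac
        Fraction of a parent's reads that must support one allele for the
        parent to count as fixed during polarization.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        chrom_lengths: dict[str, int] | None = None,
        design: _null.NullDesign | None = None,
        window_bp: int = 5_000_000,
        step_bp: int = 10_000,
        min_snps: int = 3,
        min_depth: int = 10,
        min_quality: float = 20.0,
        parent_fixed_frac: float = 0.9,
        depth_weighted: bool = False,
    ) -> None:
        self.counts = _vio._validate_counts(counts)
        if chrom_lengths is None:
            chrom_lengths = (
                self.counts.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()
            )
        self.chrom_lengths = {str(k): int(v) for k, v in chrom_lengths.items()}
        self.design = design if design is not None else _null.NullDesign()
        self.window_bp = int(window_bp)
        self.step_bp = int(step_bp)
        self.min_snps = int(min_snps)
        self.min_depth = int(min_depth)
        self.min_quality = float(min_quality)
        self.parent_fixed_frac = float(parent_fixed_frac)
        self.depth_weighted = bool(depth_weighted)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "QtlSeqScan":
        return cls(_vio.read_counts_tsv(path), **kwargs)

    @classmethod
    def from_vcf(cls, path, sample_names: dict[str, str] | None = None, **kwargs) -> "QtlSeqScan":
        return cls(_vio.read_counts_vcf(path, sample_names), **kwargs)

    def fit(
        self,
        n_reps: int = 10_000,
        seed: int | None = None,
        levels: tuple[float, ...] = (0.95, 0.99),
        ci_table: _null.CiTable | None = None,
    ) -> "QtlSeqResult":
        """Run the full scan and return a :class:`QtlSeqResult`.

        ``seed`` drives the null-model simulation (the only stochastic
        stage).  A prebuilt ``ci_table`` can be supplied to reuse null
        quantiles across runs.
        """
        polarized = _vio.polarize(
            self.counts,
            parent_fixed_frac=self.parent_fixed_frac,
            min_parent_depth=self.min_depth,
        )
        filtered = _vio.filter_sites(polarized, self.min_depth, self.min_quality)
        snps = _stats.add_indices(filtered)
        windows = _stats.sliding_windows(
            snps,
            self.chrom_lengths,
            window_bp=self.window_bp,
            step_bp=self.step_bp,
            min_snps=self.min_snps,
            depth_weighted=self.depth_weighted,
        )
        if ci_table is None:
            depths = np.unique(
                np.minimum(snps["lsb_depth"].to_numpy(), snps["hsb_depth"].to_numpy())
            )
            if depths.size == 0:
                depths = np.array([self.min_depth])
            ci_table = _null.build_ci_table(
                self.design, depths, levels=levels, n_reps=n_reps, seed=seed
            )
        windows = _null.attach_ci(windows, snps, ci_table)
        return QtlSeqResult(
            model=self,
            snp_table=snps,
            window_table=windows,
            ci_table=ci_table,
            n_input_sites=len(self.counts),
            n_polarized=len(polarized),
            n_filtered=len(filtered),
            seed=seed,
        )


@dataclass
class QtlSeqResult:
    """Fitted QTL-seq scan: per-SNP and windowed statistics with null CIs."""

    model: QtlSeqScan
    snp_table: pd.DataFrame
    window_table: pd.DataFrame
    ci_table: _null.CiTable
    n_input_sites: int
    n_polarized: int
    n_filtered: int
    seed: int | None = None
    _intervals: list = field(default_factory=list, repr=False)

    def call_intervals(self, level: int = 95, **kwargs) -> list[_call.QtlInterval]:
        """Candidate QTL intervals (see :func:`qtlseq.call.call_intervals`)."""
        self._intervals = _call.call_intervals(self.window_table, level=level, **kwargs)
        return self._intervals

    def summary(self, level: int = 95) -> str:
        """Plain-text summary of the scan in a statsmodels-like layout."""
        intervals = self.call_intervals(level=level)
        lines = [
            "QTL-seq scan summary",
            "=" * 64,
            f"design: {self.model.design.generation}, bulk size k={self.model.design.k}, "
            f"error rate {self.model.design.error_rate}",
            f"window {self.model.window_bp / 1e6:g} Mb, step {self.model.step_bp / 1e3:g} kb, "
            f"min {self.model.min_snps} SNPs/window",
            f"site filters: depth >= {self.model.min_depth} in both bulks, "
            f"qual >= {self.model.min_quality:g}",
            "-" * 64,
            f"input sites:               {self.n_input_sites}",
            f"parental fixed difference: {self.n_polarized}",
            f"passing depth/quality:     {self.n_filtered}",
            f"windows scanned:           {len(self.window_table)}"
            f"  (null reps {self.ci_table.n_reps}, seed {self.seed})",
            "-" * 64,
        ]
        if intervals:
            lines.append(f"candidate QTL intervals at {level}% (merged windows):")
            rep = _call.intervals_report(intervals)
            for _, r in rep.iterrows():
                lines.append(
                    f"  {r['chrom']}:{r['start']:,}-{r['end']:,}  "
                    f"({r['length_bp']:,} bp, {r['n_windows']} windows, level {r['level']}%)  "
                    f"peak Δ={r['peak_delta']:.3f} @ {r['peak_pos']:,}  "
                    f"HSB={r['mean_hsb_index']:.3f} LSB={r['mean_lsb_index']:.3f}"
                )
        else:
            lines.append(f"no candidate QTL intervals at the {level}% level")
        return "\n".join(lines)

    def plot(self, chrom: str | None = None, level: int = 95, ax=None):
        """Per-chromosome scan plot: both bulk indices, Delta and its CI band."""
        import matplotlib.pyplot as plt

        chroms = [chrom] if chrom else list(self.model.chrom_lengths)
        if ax is None:
            fig, axes = plt.subplots(
                len(chroms), 1, figsize=(9, 2.6 * len(chroms)), squeeze=False, sharey=True
            )
            axes = axes[:, 0]
        else:
            axes = np.atleast_1d(ax)
            fig = axes[0].figure
        tag = f"{level:g}"
        for a, c in zip(axes, chroms):
            w = self.window_table[self.window_table["chrom"] == c]
            x = w["mid"].to_numpy() / 1e6
            a.plot(x, w["hsb_index"], lw=1, label="HSB index", color="tab:red")
            a.plot(x, w["lsb_index"], lw=1, label="LSB index", color="tab:blue")
            a.plot(x, w["delta"], lw=1.2, label="Δ(SNP-index)", color="black")
            if f"lo{tag}" in w.columns:
                a.fill_between(
                    x, w[f"lo{tag}"], w[f"hi{tag}"], color="grey", alpha=0.3,
                    label=f"{level}% null CI",
                )
            a.axhline(0.0, color="grey", lw=0.5)
            a.set_ylim(-1.05, 1.05)
            a.set_ylabel(c)
        axes[-1].set_xlabel("position (Mb)")
        axes[0].legend(loc="upper right", fontsize=8, ncol=2)
        fig.tight_layout()
        return fig

    def to_tsv(self, outdir, header_comment: str | None = None) -> dict[str, str]:
        """Write snp_index.tsv, windows.tsv and ci_table.tsv into outdir."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def _write(name: str, df: pd.DataFrame) -> None:
            path = os.path.join(outdir, name)
            with open(path, "w") as fh:
                if header_comment:
                    for line in header_comment.splitlines():
                        fh.write(f"## {line}\n")
                fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
                df.to_csv(fh, sep="\t", header=False, index=False)
            paths[name] = path

        _write("snp_index.tsv", self.snp_table)
        _write("windows.tsv", self.window_table)
        ci_path = os.path.join(outdir, "ci_table.tsv")
        self.ci_table.to_tsv(ci_path)
        paths["ci_table.tsv"] = ci_path
        return paths
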
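"""Reading, writing, polarizing and filtering per-site allele-depth tables.

The central container is the *count table*: a pandas DataFrame with one row
per biallelic SNP and columns

    chrom, pos (1-based), ref, alt, qual,
    lsb_ref, lsb_alt, hsb_ref, hsb_alt,
    low_parent_ref, low_parent_alt, high_parent_ref, high_parent_alt

Counts are non-negative integers and rows are sorted by (chrom, pos).
``polarize`` converts it to a *polarized site table* in which the counted
allele in both bulks is the allele fixed in the high parent, regardless of
which input allele (REF or ALT) that happened to be — this makes the
downstream SNP-index orientation-invariant.

Coordinates are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COUNT_COLUMNS",
    "SAMPLES",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_vcf",
    "write_counts_vcf",
    "polarize",
    "filter_sites",
]

SAMPLES = ("lsb", "hsb", "low_parent", "high_parent")

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"] + [
    f"{s}_{a}" for s in SAMPLES for a in ("ref", "alt")
]

_DEPTH_COLS = COUNT_COLUMNS[5:]


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    df = df[COUNT_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be >= 1")
    for c in _DEPTH_COLS:
        df[c] = df[c].astype(np.int64)
        if (df[c] < 0).any():
            raise ValueError(f"negative depth in column {c}")
    return df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def write_counts_tsv(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a count table as TSV with a '#'-prefixed header line."""
    table = _validate_counts(table)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"## {line}\n")
        fh.write("#" + "\t".join(COUNT_COLUMNS) + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a count table written by :func:`write_counts_tsv`.

    Lines beginning '##' are comments; the column header begins with a
    single '#'.  A malformed row raises with its 1-based line number.
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    line_nos: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            rows.append(line.split("\t"))
            line_nos.append(lineno)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    if [c.strip() for c in header] != COUNT_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {header}")
    if not rows:
        return pd.DataFrame(columns=COUNT_COLUMNS).astype({"pos": np.int64})
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    for lineno, (_, row) in zip(line_nos, df.iterrows()):
        try:
            pos = int(row["pos"])
            depths = [int(row[c]) for c in _DEPTH_COLS]
            float(row["qual"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
        if pos < 1 or any(d < 0 for d in depths):
            raise ValueError(f"{path}:{lineno}: negative depth or position")
    df["qual"] = df["qual"].astype(float)
    return _validate_counts(df)


def write_counts_vcf(table: pd.DataFrame, path, sample_names: dict[str, str] | None = None) -> None:
    """Write the count table as a minimal VCF 4.2 with per-sample AD fields."""
    table = _validate_counts(table)
    names = {s: s.upper() for s in SAMPLES}
    if sample_names:
        names.update(sample_names)
    chroms = dict.fromkeys(table["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += [names[s] for s in SAMPLES]
        fh.write("\t".join(cols) + "\n")
        for _, r in table.iterrows():
            ads = [f"{r[f'{s}_ref']},{r[f'{s}_alt']}" for s in SAMPLES]
            fh.write(
                "\t".join(
                    [str(r["chrom"]), str(r["pos"]), ".", r["ref"], r["alt"],
                     f"{r['qual']:g}", "PASS", ".", "AD"] + ads
                )
                + "\n"
            )


def read_counts_vcf(path, sample_names: dict[str, str] | None = None) -> pd.DataFrame:
    """Read per-sample AD depths from a VCF into a count table.

    ``sample_names`` maps the roles lsb/hsb/low_parent/high_parent to the
    sample ids used in the VCF (defaults LSB/HSB/LOW_PARENT/HIGH_PARENT).
    Multi-allelic and indel records, and records without AD, are skipped
    and counted in the log.
    """
    from cyvcf2 import VCF

    names = {s: s.upper() for s in SAMPLES}
    if sample_names:
        names.update(sample_names)
    vcf = VCF(str(path))
    sample_idx = {}
    for role, name in names.items():
        if name not in vcf.samples:
            raise ValueError(f"sample {name!r} (role {role}) not present in {path}")
        sample_idx[role] = vcf.samples.index(name)
    rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            n_skipped += 1
            continue
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0],
            "qual": var.QUAL if var.QUAL is not None else 0.0,
        }
        ok = True
        for role, i in sample_idx.items():
            ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
            if ref_d < 0 or alt_d < 0:  # cyvcf2 encodes missing AD as negative
                ok = False
                break
            row[f"{role}_ref"] = ref_d
            row[f"{role}_alt"] = alt_d
        if not ok:
            n_skipped += 1
            continue
        rows.append(row)
    if n_skipped:
        logger.info("read_counts_vcf: skipped %d non-biallelic-SNP or AD-less records", n_skipped)
    if not rows:
        return pd.DataFrame(columns=COUNT_COLUMNS).astype({"pos": np.int64})
    return _validate_counts(pd.DataFrame(rows))


def polarize(
    table: pd.DataFrame,
    parent_fixed_frac: float = 0.9,
    min_parent_depth: int = 10,
) -> pd.DataFrame:
    """Keep parent-fixed-difference sites and count the high-parent allele.

    A parent is considered fixed for an allele when at least
    ``parent_fixed_frac`` of its reads (with depth >= ``min_parent_depth``)
    support that allele.  Only sites where the two parents are fixed for
    *opposite* alleles survive; at those sites the bulks' read counts are
    re-expressed as (high-parent-allele reads, total depth), so the
    downstream SNP-index runs from 0 (all low-parent) to 1 (all
    high-parent) irrespective of which allele the reference carried.

    Returns a frame with columns chrom, pos, qual, lsb_high, lsb_depth,
    hsb_high, hsb_depth, high_is_ref.  Dropped sites are counted in the log.
    """
    table = _validate_counts(table)

    def _fixed(ref_col: str, alt_col: str) -> np.ndarray:
        """+1 if fixed for ref, -1 if fixed for alt, 0 if uninformative."""
        ref_d = table[ref_col].to_numpy(dtype=float)
        alt_d = table[alt_col].to_numpy(dtype=float)
        tot = ref_d + alt_d
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_ref = np.where(tot > 0, ref_d / np.maximum(tot, 1), np.nan)
        deep = tot >= min_parent_depth
        out = np.zeros(len(table), dtype=np.int8)
        out[deep & (frac_ref >= parent_fixed_frac)] = 1
        out[deep & (frac_ref <= 1.0 - parent_fixed_frac)] = -1
        return out

    low = _fixed("low_parent_ref", "low_parent_alt")
    high = _fixed("high_parent_ref", "high_parent_alt")
    keep = (low != 0) & (high != 0) & (low != high)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("polarize: dropped %d sites without a parental fixed difference", n_dropped)
    sub = table.loc[keep]
    high_is_ref = high[keep] == 1
    out = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "qual": sub["qual"].to_numpy(),
            "lsb_high": np.where(high_is_ref, sub["lsb_ref"], sub["lsb_alt"]),
            "lsb_depth": sub["lsb_ref"].to_numpy() + sub["lsb_alt"].to_numpy(),
            "hsb_high": np.where(high_is_ref, sub["hsb_ref"], sub["hsb_alt"]),
            "hsb_depth": sub["hsb_ref"].to_numpy() + sub["hsb_alt"].to_numpy(),
            "high_is_ref": high_is_ref,
        }
    )
    return out.reset_index(drop=True)


def filter_sites(sites: pd.DataFrame, min_depth: int = 10, min_quality: float = 20.0) -> pd.DataFrame:
    """Apply the SNP-quality screen: depth >= min_depth in BOTH bulks and
    call quality >= min_quality (boundaries inclusive).  Idempotent."""
    if min_depth < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (
        (sites["lsb_depth"] >= min_depth)
        & (sites["hsb_depth"] >= min_depth)
        & (sites["qual"] >= min_quality)
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_sites: removed %d sites below depth/quality thresholds", n_dropped)
    return sites.loc[keep].reset_index(drop=True)
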
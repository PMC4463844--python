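"""Nucleotide-diversity estimators over accession haplotypes of a gene region.

Accessions (inbred, effectively haploid at each site) are grouped — e.g.
cultivated vs wild gene pools — and for each group the module reports the
number of segregating sites S, the average pairwise diversity per site
(theta-pi) and Watterson's estimator theta-w = S / (a1 * L) with
a1 = sum_{i=1}^{n-1} 1/i, plus the SNPs private to a single group
(polymorphic within it, monomorphic everywhere else).

Missing calls are allowed: theta-pi uses pairwise-complete comparisons
(each pair is scored over the sites where both members have calls), and S
counts sites with at least two distinct non-missing calls while L stays
the full region length.  Heterozygous or ambiguous calls are treated as
missing (selfing species; such calls are rare artefacts) and logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "theta_pi",
    "theta_w",
    "segregating_sites",
    "group_private_snps",
    "diversity_report",
]

_VALID = set("ACGT")
_MISSING = {"N", "-", ".", "", "?", "NA"}


@dataclass
class HaplotypeMatrix:
    """Accessions x sites allele calls for one gene region.

    ``calls``: DataFrame indexed by accession id, columns are 1-based site
    positions (int), values single uppercase bases or NaN for missing.
    ``groups``: Series mapping accession id -> group label.
    ``region_length``: total region length L in bp (>= max position).
    ``annotation``: optional Series mapping position -> site class
    (coding/upstream/downstream/intron).
    """

    calls: pd.DataFrame
    groups: pd.Series
    region_length: int
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        self.calls.columns = [int(c) for c in self.calls.columns]
        if self.calls.shape[1] and self.region_length < max(self.calls.columns):
            raise ValueError("region_length smaller than the largest site position")
        cleaned, n_bad = _clean_calls(self.calls)
        if n_bad:
            logger.info("HaplotypeMatrix: %d heterozygous/ambiguous calls set to missing", n_bad)
        self.calls = cleaned
        for pos in self.calls.columns:
            alleles = set(self.calls[pos].dropna())
            if len(alleles) > 2:
                raise ValueError(f"site {pos} has more than two alleles: {sorted(alleles)}")

    def subset(self, group: str | None = None, positions=None) -> "HaplotypeMatrix":
        calls = self.calls
        groups = self.groups
        if group is not None:
            ids = groups.index[groups == group]
            calls = calls.loc[calls.index.intersection(ids)]
            groups = groups.loc[calls.index]
        if positions is not None:
            calls = calls[[p for p in calls.columns if p in set(positions)]]
        ann = self.annotation
        return HaplotypeMatrix(calls.copy(), groups.copy(), self.region_length, ann)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    @classmethod
    def from_tsv(cls, path, region_length: int | None = None) -> "HaplotypeMatrix":
        """TSV with columns ``accession``, ``group``, then one column per
        1-based site position; '##' comment lines allowed.  A comment line
        '## region_length=N' supplies L when not given explicitly."""
        meta_len = None
        with open(path) as fh:
            lines = fh.read().splitlines()
        body = []
        for line in lines:
            if line.startswith("##"):
                if "region_length=" in line:
                    meta_len = int(line.split("region_length=")[1].split()[0])
                continue
            if line:
                body.append(line.split("\t"))
        header, *rows = body
        df = pd.DataFrame(rows, columns=header)
        calls = df.drop(columns=["accession", "group"]).replace(list(_MISSING), np.nan)
        calls.index = df["accession"]
        groups = pd.Series(df["group"].to_numpy(), index=df["accession"])
        length = region_length or meta_len or max(int(c) for c in calls.columns)
        return cls(calls=calls, groups=groups, region_length=length)

    @classmethod
    def from_fasta(cls, path, groups: dict[str, str]) -> "HaplotypeMatrix":
        """Aligned FASTA (one sequence per accession, equal lengths); every
        alignment column becomes a site, gaps/Ns become missing."""
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        length = lengths.pop()
        data = {
            r.id: pd.Series(list(str(r.seq).upper()), index=range(1, length + 1))
            for r in records
        }
        calls = pd.DataFrame(data).T.replace(list(_MISSING), np.nan)
        grp = pd.Series({r.id: groups[r.id] for r in records})
        return cls(calls=calls, groups=grp, region_length=length)


def _clean_calls(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    arr = calls.to_numpy(dtype=object)
    n_bad = 0
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                arr[i, j] = np.nan
                continue
            s = str(v).upper()
            if s in _MISSING:
                arr[i, j] = np.nan
            elif s in _VALID:
                arr[i, j] = s
            else:
                arr[i, j] = np.nan
                n_bad += 1
    return pd.DataFrame(arr, index=calls.index, columns=calls.columns), n_bad


def theta_pi(matrix: HaplotypeMatrix, group: str | None = None) -> float:
    """Average pairwise nucleotide diversity per compared site.

    Over all unordered accession pairs within the group, the fraction of
    pairwise-complete sites at which the two calls differ, averaged across
    pairs.  Undefined (raises) for fewer than two accessions.
    """
    sub = matrix.subset(group)
    n = len(sub.calls)
    if n < 2:
        raise ValueError("theta_pi needs at least two accessions")
    arr = sub.calls.to_numpy(dtype=object)
    present = ~pd.isna(sub.calls).to_numpy()
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        both = present[i] & present[j]
        n_comp = int(both.sum())
        if n_comp == 0:
            continue
        n_diff = int((arr[i][both] != arr[j][both]).sum())
        vals.append(n_diff / n_comp)
    if not vals:
        raise ValueError("no pairwise-complete sites in any accession pair")
    return float(np.mean(vals))


def segregating_sites(matrix: HaplotypeMatrix, group: str | None = None) -> int:
    """Sites with >=2 distinct non-missing calls within the group."""
    sub = matrix.subset(group)
    s = 0
    for pos in sub.calls.columns:
        if sub.calls[pos].dropna().nunique() >= 2:
            s += 1
    return s


def theta_w(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a1 * L), a1 = sum 1/i, i<n."""
    if n < 2:
        raise ValueError("theta_w needs n >= 2 sequences")
    if L < 1:
        raise ValueError("region length must be >= 1")
    if S < 0:
        raise ValueError("segregating-site count must be >= 0")
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (a1 * L)


def group_private_snps(matrix: HaplotypeMatrix) -> pd.DataFrame:
    """Per-site group exclusivity: a SNP is private to group G when it is
    polymorphic within G and monomorphic (or uncalled) in every other group.

    Returns a frame with columns position, polymorphic_in (comma-joined
    group list) and private_to (group label or empty string).
    """
    if len(matrix.group_names) < 1:
        raise ValueError("no groups defined")
    rows = []
    for pos in matrix.calls.columns:
        poly = [
            g
            for g in matrix.group_names
            if matrix.calls.loc[matrix.groups[matrix.groups == g].index.intersection(matrix.calls.index), pos]
            .dropna()
            .nunique()
            >= 2
        ]
        rows.append(
            {
                "position": pos,
                "polymorphic_in": ",".join(poly),
                "private_to": poly[0] if len(poly) == 1 else "",
            }
        )
    return pd.DataFrame(rows, columns=["position", "polymorphic_in", "private_to"])


def diversity_report(matrix: HaplotypeMatrix) -> pd.DataFrame:
    """Per-group n, S, theta-pi and theta-w (per site), mirroring a
    wild-vs-cultivated diversity comparison table."""
    rows = []
    for g in matrix.group_names:
        sub = matrix.subset(g)
        n = len(sub.calls)
        S = segregating_sites(matrix, g)
        rows.append(
            {
                "group": g,
                "n_accessions": n,
                "segregating_sites": S,
                "theta_pi": theta_pi(matrix, g) if n >= 2 else np.nan,
                "theta_w": theta_w(S, n, matrix.region_length) if n >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)
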
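"""Marker segregation tests, single-marker association and phenotype summaries.

These are the classical-genetics companions to the sequencing scan: a
Mendelian segregation goodness-of-fit filter for markers, a single-marker
regression scan reporting the percent phenotypic variance explained (PVE,
R^2), LOD score and additive effect at every marker, and replicated-trial
phenotype statistics (per-environment mean/SD/CV, broad-sense heritability
from ANOVA variance components, transgressive-segregant counts and a
normality check).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simdata import GenotypeMatrix, individual_means

__all__ = [
    "SegregationTest",
    "segregation_filter",
    "single_marker_scan",
    "broad_sense_h2",
    "PhenoSummary",
    "pheno_summary",
]


@dataclass
class SegregationTest:
    chi2: float
    p_value: float
    passed: bool
    counts: tuple[int, ...]
    expected: tuple[float, ...]


def segregation_filter(
    genotypes,
    expected_ratio: tuple[float, ...] = (1.0, 1.0),
    alpha: float = 0.05,
) -> SegregationTest:
    """Pearson chi-square goodness of fit of marker genotypes to a
    Mendelian ratio (default 1:1 on the two homozygous classes).

    ``genotypes`` is either a sequence of LL/LH/HH codes — heterozygotes
    are excluded before the homozygote 1:1 test — or a pre-tallied tuple of
    class counts matching ``expected_ratio``.  No continuity correction;
    df = classes - 1.
    """
    if isinstance(genotypes, (tuple, list)) and all(
        isinstance(x, (int, np.integer)) for x in genotypes
    ):
        counts = tuple(int(x) for x in genotypes)
    else:
        codes = pd.Series(list(genotypes))
        counts = (int((codes == "LL").sum()), int((codes == "HH").sum()))
    if len(counts) != len(expected_ratio) or len(counts) < 2:
        raise ValueError("counts and expected_ratio must align over >=2 classes")
    total = sum(counts)
    if total == 0:
        raise ValueError("zero marker genotypes to test")
    ratio = np.asarray(expected_ratio, dtype=float)
    expected = ratio / ratio.sum() * total
    chi2 = float(((np.asarray(counts) - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=len(counts) - 1))
    return SegregationTest(
        chi2=chi2, p_value=p, passed=p >= alpha, counts=counts, expected=tuple(expected)
    )


def single_marker_scan(geno: GenotypeMatrix, pheno: pd.DataFrame) -> pd.DataFrame:
    """Regress per-individual mean phenotype on allele dosage at each marker.

    Per marker: R^2 = 100*(1 - RSS1/RSS0) percent of the variance of the
    individual means explained by the dosage regression; LOD =
    (n/2)*log10(RSS0/RSS1); additive effect a = (mean_HH - mean_LL)/2 in
    trait units.  Monomorphic markers are emitted with NaN statistics and
    ``monomorphic=True``.
    """
    means = individual_means(pheno).reindex(geno.individuals)
    if means.isna().any():
        raise ValueError("phenotypes missing for some genotyped individuals")
    y = means.to_numpy(dtype=float)
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    sites = geno.snp_map.sites
    rows = []
    for j in range(geno.snp_map.n_sites):
        dos = geno.dosage[:, j].astype(float)
        mono = np.all(dos == dos[0])
        row = {
            "marker": f"{sites['chrom'].iat[j]}:{sites['pos'].iat[j]}",
            "chrom": sites["chrom"].iat[j],
            "pos": int(sites["pos"].iat[j]),
            "monomorphic": bool(mono),
        }
        for g, label in ((0, "mean_LL"), (1, "mean_LH"), (2, "mean_HH")):
            sel = dos == g
            row[label] = float(y[sel].mean()) if sel.any() else np.nan
        if mono:
            row.update(r2=np.nan, lod=np.nan, additive=np.nan)
        elif rss0 == 0.0:  # constant phenotype: nothing to explain
            add = 0.5 * (row["mean_HH"] - row["mean_LL"])
            row.update(r2=0.0, lod=0.0, additive=add)
        else:
            dc = dos - dos.mean()
            beta = float(dc @ yc) / float(dc @ dc)
            resid = yc - beta * dc
            rss1 = float(resid @ resid)
            r2 = 100.0 * (1.0 - rss1 / rss0)
            lod = (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300))
            row.update(r2=r2, lod=lod)
            if np.isnan(row["mean_HH"]) or np.isnan(row["mean_LL"]):
                row["additive"] = beta  # dosage slope when a homozygote class is absent
            else:
                row["additive"] = 0.5 * (row["mean_HH"] - row["mean_LL"])
        rows.append(row)
    return pd.DataFrame(rows)


def _anova_components(pheno: pd.DataFrame) -> dict[str, float]:
    """Method-of-moments variance components from a balanced two-way
    (individual x environment, r replicates) ANOVA."""
    g = pheno["individual"].nunique()
    e = pheno["environment"].nunique()
    r = len(pheno) / (g * e)
    y = pheno["value"].to_numpy(dtype=float)
    grand = y.mean()
    by_g = pheno.groupby("individual")["value"].mean()
    by_e = pheno.groupby("environment")["value"].mean()
    by_ge = pheno.groupby(["individual", "environment"])["value"].mean()
    ss_g = e * r * float(((by_g - grand) ** 2).sum())
    cell_mean = pheno.groupby(["individual", "environment"])["value"].transform("mean")
    ss_err = float(((y - cell_mean.to_numpy()) ** 2).sum())
    ge_dev = (
        by_ge
        - by_g.reindex(by_ge.index.get_level_values(0)).to_numpy()
        - by_e.reindex(by_ge.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = r * float((ge_dev**2).sum())
    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1)) if e > 1 else np.nan
    df_err = g * e * (r - 1)
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    sigma2_err = max(ms_err, 0.0)
    sigma2_ge = max((ms_ge - sigma2_err) / r, 0.0) if e > 1 else np.nan
    ref_ms = ms_ge if e > 1 else sigma2_err
    sigma2_g = max((ms_g - ref_ms) / (e * r), 0.0)
    return {
        "sigma2_g": sigma2_g,
        "sigma2_ge": sigma2_ge,
        "sigma2_err": sigma2_err,
        "n_env": e,
        "n_rep": r,
    }


def broad_sense_h2(pheno: pd.DataFrame) -> float:
    """Broad-sense heritability on an entry-mean basis:
    H^2 = s2_G / (s2_G + s2_GE/e + s2_err/(e*r)).

    Requires at least two environments (NaN otherwise); assumes a balanced
    trial.
    """
    if pheno["environment"].nunique() < 2:
        return float("nan")
    c = _anova_components(pheno)
    denom = c["sigma2_g"] + c["sigma2_ge"] / c["n_env"] + c["sigma2_err"] / (
        c["n_env"] * c["n_rep"]
    )
    if denom == 0.0:
        return 1.0
    return c["sigma2_g"] / denom


@dataclass
class PhenoSummary:
    per_environment: pd.DataFrame  # mean, sd, min, max, cv_percent per environment
    h2: float
    n_transgressive_low: int
    n_transgressive_high: int
    normality_stat: float
    normality_p: float

    @property
    def n_transgressive(self) -> int:
        return self.n_transgressive_low + self.n_transgressive_high


def pheno_summary(pheno: pd.DataFrame, parent_means: tuple[float, float]) -> PhenoSummary:
    """Replicated-trial phenotype statistics.

    ``parent_means`` is (low parent, high parent).  Transgressive
    segregants are individuals whose across-trial mean falls below the low
    parent or above the high parent.  Normality of the individual means is
    checked with the D'Agostino-Pearson skewness/kurtosis omnibus test.
    """
    low_parent, high_parent = sorted(parent_means)
    per_env = (
        pheno.groupby("environment")["value"]
        .agg(mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    per_env["cv_percent"] = 100.0 * per_env["sd"] / per_env["mean"]
    means = individual_means(pheno)
    if len(means) >= 8:  # skew/kurtosis omnibus test needs n >= 8
        stat, p = sps.normaltest(means.to_numpy())
    else:
        stat, p = np.nan, np.nan
    return PhenoSummary(
        per_environment=per_env,
        h2=broad_sense_h2(pheno),
        n_transgressive_low=int((means < low_parent).sum()),
        n_transgressive_high=int((means > high_parent).sum()),
        normality_stat=float(stat),
        normality_p=float(p),
    )
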
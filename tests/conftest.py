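"""Shared fixtures and independent oracles for the test suite.

The oracles here (selfing Markov chain, exhaustive null-Delta enumeration,
brute-force window averaging, brute-force pairwise diversity) are written
independently of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, multinomial

import qtlseq as q
from qtlseq.null_ci import NullDesign, build_ci_table
from qtlseq.variant_io import filter_sites, polarize
from qtlseq.stats import add_indices


# ---------------------------------------------------------------- oracles

def selfing_genotype_law(n_selfing: int) -> np.ndarray:
    """Exact (LL, LH, HH) probabilities after n selfing generations from an
    F1 heterozygote, by iterating the one-locus selfing Markov chain."""
    transition = np.array(
        [[1.0, 0.0, 0.0],
         [0.25, 0.5, 0.25],
         [0.0, 0.0, 1.0]]
    )
    dist = np.array([0.0, 1.0, 0.0])
    for _ in range(n_selfing):
        dist = dist @ transition
    return dist


def enumerate_null_delta_pmf(design: NullDesign, depth_lsb: int, depth_hsb: int) -> dict:
    """Exact pmf of Delta(SNP-index) under the null by exhaustive
    enumeration of bulk genotype compositions and read outcomes."""

    def index_pmf(depth: int) -> dict:
        k = design.k
        pmf: dict[float, float] = {}
        for n_ll in range(k + 1):
            for n_lh in range(k - n_ll + 1):
                n_hh = k - n_ll - n_lh
                pg = multinomial.pmf([n_ll, n_lh, n_hh], k, design.genotype_probs)
                if pg == 0.0:
                    continue
                p = (0.5 * n_lh + n_hh) / k
                pr = p * (1 - design.error_rate) + (1 - p) * design.error_rate
                for h in range(depth + 1):
                    v = h / depth
                    pmf[v] = pmf.get(v, 0.0) + pg * binom.pmf(h, depth, pr)
        return pmf

    out: dict[float, float] = {}
    for vh, ph in index_pmf(depth_hsb).items():
        for vl, pl in index_pmf(depth_lsb).items():
            d = round(vh - vl, 10)
            out[d] = out.get(d, 0.0) + ph * pl
    return out


def brute_force_windows(pos, values, length, window, step, min_snps):
    """Window means by scanning every SNP for every window."""
    rows = []
    start = 1
    while start <= length:
        end = min(start + window - 1, length)
        inside = [v for p, v in zip(pos, values) if start <= p <= end]
        rows.append(
            (start, end, len(inside),
             float(np.mean(inside)) if len(inside) >= min_snps else np.nan)
        )
        start += step
    return rows


def brute_force_theta_pi(calls: pd.DataFrame) -> float:
    """Double loop over accession pairs and sites."""
    ids = list(calls.index)
    vals = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            diffs = comp = 0
            for c in calls.columns:
                x, y = calls.loc[ids[a], c], calls.loc[ids[b], c]
                if pd.isna(x) or pd.isna(y):
                    continue
                comp += 1
                diffs += x != y
            if comp:
                vals.append(diffs / comp)
    return float(np.mean(vals))


# ---------------------------------------------------------------- fixtures

MAJOR_QTL_SEEDS = dict(map=11, breed=12, pheno=13, reads=14, fit=15)


def simulate_major_qtl_dataset(
    seeds=None, n_sites=2000, n_individuals=221, h2=1.0, k=10,
    mean_depth=30.0, error_rate=0.005, qtl_pos=850_000, require_hom=True,
):
    """One 10 Mb chromosome with a fully penetrant (by default) seed-weight
    QTL at ~850 kb, extreme homozygous bulks of 10, reads at depth ~30."""
    s = dict(MAJOR_QTL_SEEDS)
    if seeds:
        s.update(seeds)
    snp_map = q.make_snp_map(1, 10_000_000, n_sites, 1.0, seed=s["map"])
    geno = q.breed_f4(snp_map, n_individuals, seed=s["breed"])
    pos = snp_map.positions("Ca1")
    causal = int(pos[np.argmin(np.abs(pos - qtl_pos))])
    qtl = q.QtlSpec("Ca1", causal, h2=h2)
    pheno = q.simulate_phenotypes(geno, qtl, seed=s["pheno"])
    bulks = q.select_bulks(
        pheno, geno, k=k, require_homozygous_at=("Ca1", causal) if require_hom else None
    )
    counts = q.sequence_bulks(geno, bulks, mean_depth, error_rate, seed=s["reads"])
    return dict(
        snp_map=snp_map, geno=geno, causal=causal, qtl=qtl,
        pheno=pheno, bulks=bulks, counts=counts,
    )


def simulate_null_dataset(seed=0, n_sites=2000, n_individuals=60, mean_depth=30.0,
                          unlinked=False):
    """No-QTL dataset: bulks picked on a trait with (effectively) no genetic
    component, so bulk allele frequencies follow the neutral F4 law.
    ``unlinked=True`` uses an enormous map density (adjacent sites several
    Morgans apart) so sites segregate independently."""
    cm_per_mb = 1e7 if unlinked else 1.0
    length = 1_000_000 if unlinked else 10_000_000
    rng = np.random.default_rng(seed)
    snp_map = q.make_snp_map(1, length, n_sites, cm_per_mb, seed=seed + 1)
    geno = q.breed_f4(snp_map, n_individuals, seed=seed + 2)
    trait = pd.DataFrame(
        {
            "individual": geno.individuals,
            "environment": "env1",
            "replicate": 1,
            "value": rng.normal(size=geno.n_individuals),
        }
    )
    bulks = q.select_bulks(trait, geno, k=10)
    counts = q.sequence_bulks(geno, bulks, mean_depth, 0.0, seed=seed + 3)
    return dict(snp_map=snp_map, geno=geno, bulks=bulks, counts=counts)


@pytest.fixture(scope="session")
def major_qtl_dataset():
    return simulate_major_qtl_dataset()


@pytest.fixture(scope="session")
def fitted_result(major_qtl_dataset):
    model = q.QtlSeqScan(
        major_qtl_dataset["counts"],
        chrom_lengths={"Ca1": 10_000_000},
        design=NullDesign("F4", 10, 0.005),
    )
    return model.fit(seed=MAJOR_QTL_SEEDS["fit"])


@pytest.fixture(scope="session")
def null_snp_table():
    """Polarized, filtered, indexed sites from a large unlinked null
    simulation, plus a matching CI table — fresh data for coverage checks."""
    data = simulate_null_dataset(seed=100, n_sites=20_000, n_individuals=30,
                                 unlinked=True)
    sites = add_indices(filter_sites(polarize(data["counts"])))
    depths = np.unique(np.minimum(sites["lsb_depth"], sites["hsb_depth"]))
    ci = build_ci_table(NullDesign("F4", 10, 0.0), depths, n_reps=10_000, seed=101)
    return sites, ci
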
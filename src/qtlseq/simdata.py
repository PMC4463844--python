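"""Synthetic bulked-segregant data for an intra-specific F4 mapping population.

The generator emulates the study design that QTL-seq assumes: two inbred
parents fixed for opposite alleles at every marker site, an F4 population
advanced from their F1 by single-seed descent (three selfing generations),
replicated multi-environment phenotypes under a single major-QTL model,
extreme-tail bulks of homozygous individuals, and short-read allele counts
sampled from the pooled bulks.

Genotypes are coded as the dosage of the high-parent allele (0 = LL,
1 = LH, 2 = HH).  All randomness flows through a single
``numpy.random.Generator`` seeded by the caller, so every stage is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "GenotypeMatrix",
    "QtlSpec",
    "BulkSets",
    "DOSAGE_TO_CODE",
    "CODE_TO_DOSAGE",
    "make_snp_map",
    "breed_f4",
    "simulate_phenotypes",
    "select_bulks",
    "sequence_bulks",
]

DOSAGE_TO_CODE = {0: "LL", 1: "LH", 2: "HH"}
CODE_TO_DOSAGE = {v: k for k, v in DOSAGE_TO_CODE.items()}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SnpMap:
    """Catalogue of parent-differentiating biallelic SNP sites.

    ``sites`` has one row per SNP with columns ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt`` and ``high_is_ref`` (whether the reference genome
    carries the high-parent allele at that site).  Positions are strictly
    increasing within a chromosome.
    """

    chromosomes: list[tuple[str, int]]
    sites: pd.DataFrame
    cm_per_mb: float = 1.0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.loc[self.sites["chrom"] == chrom, "pos"].to_numpy()

    def site_index(self, chrom: str, pos: int) -> int:
        """Row index of the site at (chrom, pos); KeyError if absent."""
        hit = np.flatnonzero(
            (self.sites["chrom"] == chrom).to_numpy()
            & (self.sites["pos"] == pos).to_numpy()
        )
        if hit.size == 0:
            raise KeyError(f"no site at {chrom}:{pos}")
        return int(hit[0])

    def high_allele(self) -> np.ndarray:
        """The high-parent base at every site."""
        return np.where(self.sites["high_is_ref"], self.sites["ref"], self.sites["alt"])


@dataclass
class GenotypeMatrix:
    """Genotypes of a mapping population at every SnpMap site.

    ``dosage`` is an (n_individuals, n_sites) int8 array counting
    high-parent alleles (0, 1 or 2).
    """

    individuals: list[str]
    dosage: np.ndarray
    snp_map: SnpMap
    generation: str = "F4"

    def __post_init__(self) -> None:
        bad = set(np.unique(self.dosage)) - {0, 1, 2}
        if bad:
            raise ValueError(f"genotype dosages outside {{0,1,2}}: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def codes(self) -> pd.DataFrame:
        """Individuals x sites frame of LL/LH/HH codes."""
        code = np.array(["LL", "LH", "HH"])[self.dosage]
        cols = [f"{c}:{p}" for c, p in zip(self.snp_map.sites["chrom"], self.snp_map.sites["pos"])]
        return pd.DataFrame(code, index=self.individuals, columns=cols)

    def to_tsv(self, path) -> None:
        self.codes().rename_axis("individual").to_csv(path, sep="\t")


@dataclass
class QtlSpec:
    """A single additive/dominant QTL placed on a SnpMap site.

    The additive effect is derived from the parental trait means: an LL
    individual has expected value ``low_parent_mean`` and an HH individual
    ``high_parent_mean`` (plus dominance for heterozygotes).  ``h2`` is the
    broad-sense heritability targeted on an entry-mean basis across the
    replicated trial.
    """

    chrom: str
    pos: int
    h2: float
    low_parent_mean: float = 8.9
    high_parent_mean: float = 30.1
    dominance: float = 0.0

    @property
    def baseline(self) -> float:
        return 0.5 * (self.low_parent_mean + self.high_parent_mean)

    @property
    def additive(self) -> float:
        return 0.5 * (self.high_parent_mean - self.low_parent_mean)


@dataclass
class BulkSets:
    """Low- and high-tail bulks of individual ids (disjoint, equal size)."""

    lsb: list[str]
    hsb: list[str]
    k: int = field(default=0)

    def __post_init__(self) -> None:
        if self.k == 0:
            self.k = len(self.lsb)
        if len(self.lsb) != len(self.hsb):
            raise ValueError("bulks must be of equal size")
        if set(self.lsb) & set(self.hsb):
            raise ValueError("bulks must be disjoint")


def make_snp_map(
    n_chrom: int = 8,
    chrom_length_bp: int = 10_000_000,
    n_sites_per_chrom: int = 1000,
    cm_per_mb: float = 1.0,
    seed: int | None = None,
) -> SnpMap:
    """Scatter parent-differentiating SNP sites uniformly along chromosomes.

    Positions are sampled uniformly, deduplicated and sorted, so each
    chromosome carries exactly ``n_sites_per_chrom`` strictly increasing
    sites.  The reference allele matches the high parent at a random half
    of the sites, mimicking a reference genome unrelated to either parent.
    """
    if n_chrom < 1:
        raise ValueError(f"n_chrom must be >= 1, got {n_chrom}")
    if chrom_length_bp <= 0:
        raise ValueError(f"chrom_length_bp must be positive, got {chrom_length_bp}")
    if n_sites_per_chrom < 0:
        raise ValueError(f"n_sites_per_chrom must be >= 0, got {n_sites_per_chrom}")
    if n_sites_per_chrom > chrom_length_bp:
        raise ValueError("more sites requested than base pairs available")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"Ca{i + 1}", int(chrom_length_bp)) for i in range(n_chrom)]
    frames = []
    for name, length in chromosomes:
        pos = np.array([], dtype=np.int64)
        while pos.size < n_sites_per_chrom:
            draw = rng.integers(1, length + 1, size=2 * n_sites_per_chrom + 16)
            pos = np.unique(np.concatenate([pos, draw]))
        pos = np.sort(rng.choice(pos, size=n_sites_per_chrom, replace=False))
        ref_idx = rng.integers(0, 4, size=n_sites_per_chrom)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites_per_chrom)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "high_is_ref": rng.random(n_sites_per_chrom) < 0.5,
                }
            )
        )
    sites = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "high_is_ref"])
    )
    return SnpMap(chromosomes=chromosomes, sites=sites, cm_per_mb=cm_per_mb)


def _gamete(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    pos: np.ndarray,
    length_bp: int,
    cm_per_mb: float,
) -> np.ndarray:
    """One meiotic product: Poisson crossovers, uniform breakpoints (Haldane)."""
    morgans = length_bp / 1e6 * cm_per_mb / 100.0
    n_xo = rng.poisson(morgans)
    phase0 = rng.integers(0, 2)
    if n_xo == 0:
        return (hap_a if phase0 == 0 else hap_b).copy()
    breaks = np.sort(rng.uniform(0.0, length_bp, size=n_xo))
    phase = (phase0 + np.searchsorted(breaks, pos)) % 2
    return np.where(phase == 0, hap_a, hap_b)


def breed_f4(
    snp_map: SnpMap,
    n_individuals: int = 221,
    seed: int | None = None,
    generation: str = "F4",
) -> GenotypeMatrix:
    """Advance an F1 to the requested generation by single-seed descent.

    Every line starts from the F1 (one haplotype from each parent) and is
    selfed once per generation, keeping a single offspring — so F4 means
    three rounds of selfing.  Crossovers per chromosome are Poisson with
    mean equal to the genetic length in Morgans, breakpoints uniform and
    interference-free.  No selection is applied during breeding.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    if snp_map.n_sites == 0:
        raise ValueError("snp_map has no sites")
    n_selfing = {"F1": 0, "F2": 1, "F3": 2, "F4": 3}.get(generation)
    if n_selfing is None:
        raise ValueError(f"unsupported generation {generation!r}")
    rng = np.random.default_rng(seed)
    chrom_arr = snp_map.sites["chrom"].to_numpy()
    pos_arr = snp_map.sites["pos"].to_numpy()
    chrom_slices = {
        name: (np.flatnonzero(chrom_arr == name), length)
        for name, length in snp_map.chromosomes
    }
    m = snp_map.n_sites
    dosage = np.empty((n_individuals, m), dtype=np.int8)
    for i in range(n_individuals):
        hap_a = np.zeros(m, dtype=np.int8)  # low-parent gamete
        hap_b = np.ones(m, dtype=np.int8)  # high-parent gamete
        for _ in range(n_selfing):
            new_a = np.empty(m, dtype=np.int8)
            new_b = np.empty(m, dtype=np.int8)
            for idx, length in chrom_slices.values():
                if idx.size == 0:
                    continue
                p = pos_arr[idx]
                new_a[idx] = _gamete(rng, hap_a[idx], hap_b[idx], p, length, snp_map.cm_per_mb)
                new_b[idx] = _gamete(rng, hap_a[idx], hap_b[idx], p, length, snp_map.cm_per_mb)
            hap_a, hap_b = new_a, new_b
        dosage[i] = hap_a + hap_b
    ids = [f"{generation}_{i + 1:04d}" for i in range(n_individuals)]
    return GenotypeMatrix(individuals=ids, dosage=dosage, snp_map=snp_map, generation=generation)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    qtl: QtlSpec,
    n_environments: int = 3,
    n_replicates: int = 2,
    env_sd: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicated multi-environment phenotypes under a single-QTL model.

    value = baseline + a*(dosage-1) + d*[het] + environment shift + residual.
    The residual variance is solved so that the broad-sense heritability on
    an entry-mean basis (genetic variance over genetic variance plus
    residual variance of an individual's mean across e*r observations)
    equals ``qtl.h2``.  Environment shifts are additive and shared by all
    individuals; no genotype-by-environment interaction is generated.

    Returns a tidy frame with columns individual, environment, replicate,
    value.
    """
    if not 0.0 < qtl.h2 <= 1.0:
        raise ValueError(f"h2 must be in (0, 1], got {qtl.h2}")
    if n_environments < 1 or n_replicates < 1:
        raise ValueError("need at least one environment and one replicate")
    causal = geno.snp_map.site_index(qtl.chrom, qtl.pos)
    rng = np.random.default_rng(seed)
    dos = geno.dosage[:, causal].astype(float)
    g = qtl.baseline + qtl.additive * (dos - 1.0) + qtl.dominance * (dos == 1.0)
    var_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    e, r = n_environments, n_replicates
    if qtl.h2 < 1.0 and var_g > 0.0:
        sigma2_eps = var_g * (1.0 / qtl.h2 - 1.0) * e * r
    else:
        sigma2_eps = 0.0
    env_shift = rng.normal(0.0, env_sd, size=e)
    rows = []
    for j in range(e):
        for rep in range(r):
            noise = rng.normal(0.0, np.sqrt(sigma2_eps), size=len(g)) if sigma2_eps > 0 else 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "individual": geno.individuals,
                        "environment": f"env{j + 1}",
                        "replicate": rep + 1,
                        "value": g + env_shift[j] + noise,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    if not np.isfinite(out["value"]).all():
        raise AssertionError("non-finite phenotype generated")
    return out


def read_genotypes_tsv(path, cm_per_mb: float = 1.0) -> GenotypeMatrix:
    """Read an individuals-x-markers LL/LH/HH table written by
    :meth:`GenotypeMatrix.to_tsv`.

    Marker columns are named ``chrom:pos``; allele identities are not part
    of the genotype file, so the reconstructed SnpMap carries placeholder
    bases (sufficient for segregation and association statistics).
    """
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l and not l.startswith("##")]
    header = lines[0].lstrip("#").split("\t")
    rows = [l.split("\t") for l in lines[1:]]
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    chroms: list[str] = []
    positions: list[int] = []
    for col in df.columns:
        chrom, pos = col.rsplit(":", 1)
        chroms.append(chrom)
        positions.append(int(pos))
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": "A", "alt": "T", "high_is_ref": False}
    )
    lengths = sites.groupby("chrom", sort=False)["pos"].max().astype(int)
    snp_map = SnpMap(
        chromosomes=[(c, int(l)) for c, l in lengths.items()],
        sites=sites,
        cm_per_mb=cm_per_mb,
    )
    try:
        dosage = (
            df.map(lambda v: CODE_TO_DOSAGE[v]).to_numpy(dtype=np.int8)
            if hasattr(df, "map")
            else df.applymap(lambda v: CODE_TO_DOSAGE[v]).to_numpy(dtype=np.int8)
        )
    except KeyError as exc:
        raise ValueError(f"{path}: unknown genotype code {exc}") from None
    return GenotypeMatrix(
        individuals=[str(i) for i in df.index], dosage=dosage, snp_map=snp_map
    )


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Read a tidy phenotype table (individual, environment, replicate, value)."""
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l and not l.startswith("##")]
    header = lines[0].lstrip("#").split("\t")
    if header[:4] != ["individual", "environment", "replicate", "value"]:
        raise ValueError(f"{path}: unexpected phenotype columns {header}")
    df = pd.DataFrame([l.split("\t") for l in lines[1:]], columns=header)
    df["individual"] = df["individual"].astype(str)
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise ValueError(f"{path}: non-finite trait values")
    return df


def individual_means(pheno: pd.DataFrame) -> pd.Series:
    """Mean trait value per individual across environments and replicates."""
    return pheno.groupby("individual")["value"].mean()


def select_bulks(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    k: int = 10,
    require_homozygous_at: tuple[str, int] | None = None,
) -> BulkSets:
    """Pick the k lowest- and k highest-scoring individuals as bulks.

    Individuals are ranked by their mean trait value across all
    environments and replicates; ties break on the individual id (stable).
    With ``require_homozygous_at`` set, heterozygotes at that site are
    skipped while filling each tail — emulating the homozygosity screen
    applied to the real bulks before pooling.
    """
    if 2 * k > geno.n_individuals:
        raise ValueError(f"2k = {2 * k} exceeds population size {geno.n_individuals}")
    means = individual_means(pheno)
    means = means.reindex(geno.individuals)
    if means.isna().any():
        missing = means.index[means.isna()][:3].tolist()
        raise ValueError(f"individuals without phenotypes: {missing}")
    order = sorted(geno.individuals, key=lambda i: (means[i], i))
    eligible = set(geno.individuals)
    if require_homozygous_at is not None:
        site = geno.snp_map.site_index(*require_homozygous_at)
        het = np.asarray(geno.dosage[:, site] == 1)
        eligible -= {ind for ind, h in zip(geno.individuals, het) if h}
    lsb = [i for i in order if i in eligible][:k]
    if len(lsb) < k:
        raise ValueError(f"fewer than k={k} eligible individuals in the low tail")
    hsb_pool = [i for i in reversed(order) if i in eligible and i not in set(lsb)][:k]
    if len(hsb_pool) < k:
        raise ValueError(f"fewer than k={k} eligible individuals in the high tail")
    return BulkSets(lsb=lsb, hsb=hsb_pool, k=k)


def sequence_bulks(
    geno: GenotypeMatrix,
    bulks: BulkSets,
    mean_depth: float = 30.0,
    error_rate: float = 0.005,
    seed: int | None = None,
    depth_model: str = "poisson",
    site_qual: float = 60.0,
) -> pd.DataFrame:
    """Sample per-site read counts from the pooled bulks and both parents.

    At each site the bulk's true high-allele frequency is
    p = (2*n_HH + n_LH) / (2k).  The observed depth is Poisson(mean_depth)
    truncated at 1 (or constant round(mean_depth) with
    ``depth_model='constant'``), and the number of high-allele reads is
    Binomial(depth, p*(1-e) + (1-p)*e) with e the per-read error rate.
    Parents are emitted under the same read model with p fixed at 0 (low
    parent) and 1 (high parent).

    Returns a count table (see :mod:`qtlseq.variant_io` for the column
    contract) with ref/alt depths for samples LSB, HSB, LOW_PARENT and
    HIGH_PARENT.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError(f"error_rate must be in [0, 0.5), got {error_rate}")
    if not bulks.lsb or not bulks.hsb:
        raise ValueError("empty bulks")
    rng = np.random.default_rng(seed)
    idx = {ind: i for i, ind in enumerate(geno.individuals)}
    m = geno.snp_map.n_sites
    sites = geno.snp_map.sites

    def _depths(n: int) -> np.ndarray:
        if depth_model == "constant":
            return np.full(n, max(1, int(round(mean_depth))), dtype=np.int64)
        if depth_model == "poisson":
            return np.maximum(rng.poisson(mean_depth, size=n), 1)
        raise ValueError(f"unknown depth_model {depth_model!r}")

    def _sample(p_high: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = _depths(m)
        p_read = p_high * (1.0 - error_rate) + (1.0 - p_high) * error_rate
        high = rng.binomial(d, p_read)
        return high, d

    out = {"chrom": sites["chrom"], "pos": sites["pos"], "ref": sites["ref"],
           "alt": sites["alt"], "qual": site_qual}
    high_is_ref = sites["high_is_ref"].to_numpy()
    samples = {
        "lsb": geno.dosage[[idx[i] for i in bulks.lsb]].sum(axis=0) / (2.0 * bulks.k),
        "hsb": geno.dosage[[idx[i] for i in bulks.hsb]].sum(axis=0) / (2.0 * bulks.k),
        "low_parent": np.zeros(m),
        "high_parent": np.ones(m),
    }
    for name, p in samples.items():
        high, d = _sample(np.asarray(p, dtype=float))
        low = d - high
        out[f"{name}_ref"] = np.where(high_is_ref, high, low)
        out[f"{name}_alt"] = np.where(high_is_ref, low, high)
    return pd.DataFrame(out)
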
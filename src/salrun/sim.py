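"""Synthetic data with the statistical structure the pipeline assumes.

Genotypes follow a two-level Balding–Nichols F-model (regions around an
ancestral pool, populations around regions), so PCA/ancestry analyses see a
hierarchical structure like the Maritimes / Newfoundland / Labrador regional
clusters of Atlantic Canada. Trait loci carry a deterministic allele-frequency
cline on the logit scale against a standardized latitude-linked climate axis.
Climate tables emulate 19 bioclim-style variables, several latitude-graded and
several deliberately collinear (|r| > 0.7) to exercise predictor decorrelation;
the future table displaces the present one with a latitude-graded shift
(largest in the north). Daily count series are Poisson draws around one or two
Gaussian seasonal peaks with per-year jitter and optional planted multi-year
trends.

Every generator is a pure function of a :class:`SimConfig` (seeded), and
ground truth is returned alongside the data for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MARKER_COLUMNS

log = logging.getLogger(__name__)

#: latitudes spanning the Maritimes (~46°N) to Labrador (~55°N)
_DEFAULT_LATS = (46.1, 46.9, 47.0, 47.6, 47.9, 48.5, 49.3, 51.2, 53.6, 55.0, 54.3)

#: bioclim-style variables driven by latitude in the generator (temperature-like)
LAT_DRIVEN = ("BIO1", "BIO5", "BIO6", "BIO7", "BIO10", "BIO11")
#: pairs constructed to be strongly collinear with an existing variable
COLLINEAR_PAIRS = {"BIO2": "BIO1", "BIO9": "BIO10", "BIO17": "BIO16"}

TRAITS = ("early", "late", "modality")


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the study design: 11 populations in 3 regional clusters
    (4 Maritimes-like, 5 Newfoundland-like, 2 Labrador-like), 27 individuals
    per population (297 total), 5,000 biallelic SNPs with 50 planted trait
    loci per phenotype, and 28 years of daily counts.
    """

    n_pops: int = 11
    pops_per_region: tuple[int, ...] = (4, 5, 2)
    n_ind_per_pop: int = 27
    n_snps: int = 5000
    fst_between_regions: float = 0.08
    fst_within_region: float = 0.02
    n_trait_loci: int = 50
    effect_size: float = 1.0
    latitudes: tuple[float, ...] = _DEFAULT_LATS
    n_years: int = 28
    start_year: int = 1994
    seed: int = 0
    # counts
    mean_total_count: float = 600.0
    run_sd_days: float = 12.0
    year_jitter_sd: float = 3.0
    trend_slopes: tuple[float, ...] | None = None  # days/year per population
    # climate
    climate_noise_sd: float = 0.3
    displacement: float = 1.0  # future-minus-present shift (sd units) at the highest latitude
    # river-specific deviation of the run-timing/climate trait axis from the
    # pure latitude gradient (sd in latitude-z units); gives each river its
    # own thermal identity, so the trait is correlated with, but not fully
    # collinear to, regional structure
    site_effect_sd: float = 0.6
    # optional local LD for prune tests: each SNP copied this many times
    ld_block_copy: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_ind_per_pop, self.n_snps, self.n_years) <= 0:
            raise ValueError("all counts must be positive")
        if sum(self.pops_per_region) != self.n_pops:
            raise ValueError("pops_per_region must partition n_pops")
        if not 0 < self.fst_within_region <= self.fst_between_regions < 1:
            raise ValueError("need 0 < fst_within_region <= fst_between_regions < 1")
        if self.n_trait_loci >= self.n_snps:
            raise ValueError("n_trait_loci must be < n_snps")
        if len(self.latitudes) != self.n_pops:
            raise ValueError("one latitude per population required")

    @property
    def k_regions(self) -> int:
        return len(self.pops_per_region)

    @property
    def pop_names(self) -> list[str]:
        return [f"POP{i + 1:02d}" for i in range(self.n_pops)]

    @property
    def region_of_pop(self) -> list[str]:
        out = []
        for r, k in enumerate(self.pops_per_region):
            out += [f"REG{r + 1}"] * k
        return out

    def climate_z(self) -> np.ndarray:
        """Standardized latitude (drives the bioclim-style climate variables)."""
        lat = np.asarray(self.latitudes, dtype=float)
        return (lat - lat.mean()) / lat.std()

    def trait_axis(self) -> np.ndarray:
        """Standardized per-population run-timing axis: latitude gradient plus
        a seeded river-specific deviation. Trait clines and mean run dates are
        planted on this axis, so the trait correlates with climate and with
        regional structure without being collinear to either."""
        rng = np.random.default_rng(self.seed + 4)
        z = self.climate_z() + rng.normal(0, self.site_effect_sd, self.n_pops)
        return (z - z.mean()) / z.std()


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    trait_loci: dict[str, list[int]]
    ancestral_k: int
    planted_slopes: dict[int, float]
    modality_labels: dict[str, str]
    phenotypes: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Two-level F-model genotypes with logit-scale climate clines at trait loci.

    Ancestral frequencies ~ U(0.05, 0.95); regional frequencies are Beta draws
    with variance F_between·p(1-p); population frequencies are Beta draws
    around the regional value with variance F_within·q(1-q). Trait loci shift
    logit(p_pop) by effect_size × standardized climate; frequencies falling
    outside (0,1) after the cline are clamped to [0.01, 0.99] with a warning.
    Genotypes are Binomial(2, p_pop).
    """
    rng = np.random.default_rng(cfg.seed)
    n_base = cfg.n_snps if cfg.ld_block_copy == 0 else -(-cfg.n_snps // (1 + cfg.ld_block_copy))
    p_anc = rng.uniform(0.05, 0.95, size=n_base)

    region_idx = np.repeat(np.arange(cfg.k_regions), cfg.pops_per_region)
    p_reg = _beta_around(rng, np.tile(p_anc, (cfg.k_regions, 1)), cfg.fst_between_regions)
    p_pop = _beta_around(rng, p_reg[region_idx], cfg.fst_within_region)

    if cfg.ld_block_copy > 0:
        reps = 1 + cfg.ld_block_copy
        p_pop = np.repeat(p_pop, reps, axis=1)[:, : cfg.n_snps]

    truth = _plant_trait_loci(cfg, rng)
    expected = expected_phenotypes(cfg, truth.modality_labels)
    n_clamped = 0
    for trait, loci in truth.trait_loci.items():
        v = expected[trait].to_numpy(dtype=float)
        z = (v - v.mean()) / v.std() if v.std() > 0 else v * 0.0
        for j in loci:
            if truth.planted_slopes[j] == 0.0:
                continue
            shifted = _expit(_logit(np.clip(p_pop[:, j], 1e-6, 1 - 1e-6))
                             + truth.planted_slopes[j] * z)
            n_clamped += int(((shifted < 0.01) | (shifted > 0.99)).sum())
            p_pop[:, j] = np.clip(shifted, 0.01, 0.99)
    if n_clamped:
        log.warning("simulate_genotypes: clamped %d clined frequencies to [0.01, 0.99]", n_clamped)

    dosages = rng.binomial(2, np.repeat(p_pop, cfg.n_ind_per_pop, axis=0)).astype(float)
    markers = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(cfg.n_snps)],
            "chrom": ["chr" + str(1 + j // max(1, cfg.n_snps // 10)) for j in range(cfg.n_snps)],
            "pos": [1000 * (1 + j % max(1, cfg.n_snps // 10)) for j in range(cfg.n_snps)],
            "ref": "A",
            "alt": "T",
        }
    )[MARKER_COLUMNS]
    individuals = [
        f"{pop}_i{k + 1}" for pop in cfg.pop_names for k in range(cfg.n_ind_per_pop)
    ]
    pop_labels = [pop for pop in cfg.pop_names for _ in range(cfg.n_ind_per_pop)]
    g = GenotypeMatrix(dosages, markers, individuals, pop_labels)
    return g, truth


def _beta_around(rng, p, fst):
    """Beta draws with mean p and variance fst·p(1-p) (Balding–Nichols)."""
    p = np.clip(p, 1e-4, 1 - 1e-4)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _plant_trait_loci(cfg: SimConfig, rng) -> SimTruth:
    picks = rng.choice(cfg.n_snps, size=cfg.n_trait_loci * len(TRAITS), replace=False)
    trait_loci = {
        t: sorted(int(j) for j in picks[i * cfg.n_trait_loci : (i + 1) * cfg.n_trait_loci])
        for i, t in enumerate(TRAITS)
    }
    slopes = {}
    for loci in trait_loci.values():
        for j in loci:
            slopes[j] = float(cfg.effect_size * rng.choice((-1.0, 1.0)))
    # Maritimes-like region (lowest latitudes, region 1) runs bimodal, as in
    # the study where almost all Maritimes populations show two timing peaks.
    modality = {
        pop: ("multiple" if reg == "REG1" else "single")
        for pop, reg in zip(cfg.pop_names, cfg.region_of_pop)
    }
    return SimTruth(
        trait_loci=trait_loci,
        ancestral_k=cfg.k_regions,
        planted_slopes=slopes,
        modality_labels=modality,
    )


def expected_phenotypes(cfg: SimConfig, modality_labels: dict[str, str]) -> pd.DataFrame:
    """Noise-free population phenotypes implied by the count model.

    early/late are the 5%/95% quantiles of each population's seasonal return
    density (single Gaussian or the two-component mixture, evaluated on the
    day-of-year grid); modality is the binary label. Trait clines are planted
    against these standardized values, so planted loci are associated with
    the phenotype the GWA stage later measures from the realized counts
    (pooling over years makes the realized values track these closely).
    """
    z = cfg.trait_axis()
    base_mean = 170 + 12 * z
    doy = np.arange(60, 366)
    rows = {}
    for i, pop in enumerate(cfg.pop_names):
        mu = base_mean[i]
        if modality_labels[pop] == "multiple":
            dens = 0.55 * _gauss(doy, mu - 25, cfg.run_sd_days) + 0.45 * _gauss(
                doy, mu + 25, cfg.run_sd_days
            )
        else:
            dens = _gauss(doy, mu, cfg.run_sd_days)
        cum = np.cumsum(dens) / dens.sum()
        rows[pop] = {
            "early": float(doy[np.searchsorted(cum, 0.05)]),
            "late": float(doy[np.searchsorted(cum, 0.95)]),
            "modality": 1.0 if modality_labels[pop] == "multiple" else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Climate


def simulate_climate(cfg: SimConfig) -> pd.DataFrame:
    """Present and future bioclim-style tables (long form).

    Returns a DataFrame with columns site, variable, present, future.
    Latitude-driven variables are linear in standardized latitude plus noise;
    collinear pairs are near-copies of their partner (|r| > 0.7); the rest are
    pure noise. The future column displaces latitude-driven variables by
    ``displacement`` scaled by each site's relative latitude, so the shift is
    largest at the highest-latitude site and zero at the lowest.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    z = cfg.trait_axis()  # local climate identity: latitude gradient + river effect
    lat = np.asarray(cfg.latitudes, dtype=float)
    rel = (lat - lat.min()) / (lat.max() - lat.min()) if lat.max() > lat.min() else lat * 0
    names = [f"BIO{i}" for i in range(1, 20)]
    present = {}
    for name in names:
        if name in LAT_DRIVEN:
            # temperature-like: colder (lower) at higher latitude
            present[name] = -z + rng.normal(0, cfg.climate_noise_sd, cfg.n_pops)
        elif name in COLLINEAR_PAIRS:
            continue  # filled after partners exist
        else:
            present[name] = rng.normal(0, 1, cfg.n_pops)
    for name, partner in COLLINEAR_PAIRS.items():
        present[name] = present[partner] + rng.normal(0, 0.2, cfg.n_pops)
    future = {}
    for name in names:
        # warming shift, amplified toward the north, moves cold northern
        # sites up through the observed climate range
        shift = cfg.displacement * rel if name in LAT_DRIVEN else 0.0
        future[name] = present[name] + shift
    rows = []
    for name in names:
        for i, site in enumerate(cfg.pop_names):
            rows.append((site, name, present[name][i], future[name][i]))
    return pd.DataFrame(rows, columns=["site", "variable", "present", "future"])


def climate_wide(table: pd.DataFrame, when: str = "present") -> pd.DataFrame:
    """Pivot a long climate table to sites x variables."""
    return table.pivot(index="site", columns="variable", values=when).sort_index()


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(cfg: SimConfig, modality_labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Daily count series (long form: population, year, doy, size_class, count).

    Single-peak populations draw Poisson counts around one Gaussian bump over
    day-of-year; 'multiple' populations use a two-component mixture 50 days
    apart. Mean run date follows latitude (later in the north, as observed
    across Atlantic Canada), with per-year Gaussian jitter and an optional
    planted linear trend in days/year. Counts are split between small and
    large size classes at a fixed 60/40 ratio.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if modality_labels is None:
        modality_labels = _plant_trait_loci(cfg, np.random.default_rng(cfg.seed)).modality_labels
    z = cfg.trait_axis()
    base_mean = 170 + 12 * z  # DOY ~158 in the south to ~185 in the north
    slopes = np.zeros(cfg.n_pops) if cfg.trend_slopes is None else np.asarray(cfg.trend_slopes)
    doy = np.arange(60, 366)
    rows = []
    for i, pop in enumerate(cfg.pop_names):
        for y in range(cfg.n_years):
            year = cfg.start_year + y
            mu = base_mean[i] + slopes[i] * y + rng.normal(0, cfg.year_jitter_sd)
            if modality_labels[pop] == "multiple":
                dens = 0.55 * _gauss(doy, mu - 25, cfg.run_sd_days) + 0.45 * _gauss(
                    doy, mu + 25, cfg.run_sd_days
                )
            else:
                dens = _gauss(doy, mu, cfg.run_sd_days)
            lam = cfg.mean_total_count * dens / dens.sum()
            counts = rng.poisson(lam)
            small = rng.binomial(counts, 0.6)
            large = counts - small
            for d, s, l in zip(doy, small, large):
                if s:
                    rows.append((pop, year, int(d), "small", int(s)))
                if l:
                    rows.append((pop, year, int(d), "large", int(l)))
    return pd.DataFrame(rows, columns=["population", "year", "doy", "size_class", "count"])


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


# ---------------------------------------------------------------------------
# Population phenotypes and fixture bundle


def population_phenotypes(cfg: SimConfig, counts: pd.DataFrame | None = None,
                          truth: SimTruth | None = None) -> pd.DataFrame:
    """Per-population trait values used for population-level GWA.

    early/late are the pooled 5th/95th-percentile run-timing days computed
    from the (simulated) count series; modality is the planted binary label.
    Each individual in a population is later assigned its population's value.
    """
    from .runtiming import percentile_day

    if truth is None:
        truth = _plant_trait_loci(cfg, np.random.default_rng(cfg.seed))
    if counts is None:
        counts = simulate_counts(cfg, truth.modality_labels)
    rows = {}
    for pop in cfg.pop_names:
        sub = counts[counts["population"] == pop]
        rows[pop] = {
            "early": float(percentile_day(sub, 0.05)),
            "late": float(percentile_day(sub, 0.95)),
            "modality": 1.0 if truth.modality_labels[pop] == "multiple" else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def individual_phenotypes(g: GenotypeMatrix, pop_pheno: pd.DataFrame, trait: str) -> np.ndarray:
    """Assign each fish its population's trait value (the study's GWA design)."""
    return pop_pheno.loc[g.pop_labels, trait].to_numpy(dtype=float)


def simulate_gene_intervals(cfg: SimConfig, markers: pd.DataFrame, n_genes: int = 200) -> pd.DataFrame:
    """BED-style gene intervals on the simulated marker coordinate system."""
    rng = np.random.default_rng(cfg.seed + 3)
    chroms = pd.unique(markers["chrom"])
    max_pos = int(markers["pos"].max()) + 50_000
    rows = []
    for k in range(n_genes):
        chrom = rng.choice(chroms)
        start = int(rng.integers(1, max_pos))
        end = start + int(rng.integers(500, 20_000))
        rows.append((chrom, start, end, f"gene{k + 1}", ".", rng.choice(["+", "-"])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])


def write_fixtures(cfg: SimConfig, outdir) -> dict:
    """Generate the full synthetic bundle and write it as plain-text fixtures.

    VCF (genotypes), TSVs (population map, climate, counts, phenotypes),
    BED (gene intervals), JSON (ground truth). Returns the in-memory objects.
    """
    import os

    from .genotypes import write_vcf, write_pop_map

    os.makedirs(outdir, exist_ok=True)
    g, truth = simulate_genotypes(cfg)
    counts = simulate_counts(cfg, truth.modality_labels)
    climate = simulate_climate(cfg)
    pheno = population_phenotypes(cfg, counts, truth)
    truth.phenotypes = {t: pheno[t].to_dict() for t in pheno.columns}
    genes = simulate_gene_intervals(cfg, g.markers)

    write_vcf(g, os.path.join(outdir, "genotypes.vcf"))
    write_pop_map(g, os.path.join(outdir, "popmap.tsv"))
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index=False)
    climate.to_csv(os.path.join(outdir, "climate.tsv"), sep="\t", index=False)
    pheno.rename_axis("population").to_csv(os.path.join(outdir, "phenotypes.tsv"), sep="\t")
    bed = genes.copy()
    bed["start"] -= 1  # BED half-open, 0-based
    bed.to_csv(os.path.join(outdir, "genes.bed"), sep="\t", index=False, header=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
    return {"genotypes": g, "truth": truth, "counts": counts, "climate": climate,
            "phenotypes": pheno, "genes": genes}
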
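"""Genotype container, I/O, QC filters, LD computation/pruning, and diversity metrics.

Dosages are stored individuals x SNPs as float arrays with ``np.nan`` for
missing calls; non-missing entries are 0/1/2 counts of the alternate allele.
Missingness is preserved in the raw matrix — mean imputation happens only
inside ordination/association computations (see :func:`impute_dosages`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with marker map and population labels.

    Parameters
    ----------
    dosages : (n_individuals, n_snps) float array, entries in {0, 1, 2, nan}
    markers : DataFrame with columns id, chrom, pos, ref, alt (1-based pos)
    individuals : sequence of sample identifiers
    pop_labels : population label per individual
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    individuals: list[str]
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.markers) != m:
            raise ValueError(f"marker table has {len(self.markers)} rows for {m} SNPs")
        if len(self.individuals) != n or len(self.pop_labels) != n:
            raise ValueError("individuals / pop_labels length must match dosage rows")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage entry at individual {bad[0]}, SNP {bad[1]} is not in {{0,1,2,missing}}"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs (order preserved as given)."""
        return replace(
            self,
            dosages=self.dosages[:, index],
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def pop_freqs(self) -> pd.DataFrame:
        """Per-population alternate-allele frequencies (pops x SNPs)."""
        pops = pd.unique(pd.Series(self.pop_labels))
        rows = {}
        labels = np.asarray(self.pop_labels)
        for p in pops:
            with np.errstate(invalid="ignore"):
                rows[p] = np.nanmean(self.dosages[labels == p], axis=0) / 2.0
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.markers["id"])


@dataclass
class DiversityMetrics:
    """Weir–Cockerham FST plus per-population diversity summaries."""

    fst_per_snp: pd.Series
    fst_mean: float
    ho_per_pop: pd.Series
    pi_per_snp: pd.DataFrame  # pops x SNPs
    pi_mean_per_pop: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.pi_mean_per_pop = self.pi_per_snp.mean(axis=1, skipna=True)


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path, fmt: str = "vcf", pop_labels=None) -> GenotypeMatrix:
    """Read genotypes from a VCF or a dosage TSV.

    Biallelic SNPs only; multiallelic VCF records are skipped (count logged).
    ``pop_labels`` may be a dict/Series mapping individual -> population or a
    path to a two-column population-map TSV (individual, population).
    """
    path = str(path)
    if fmt == "vcf":
        g = _read_vcf(path)
    elif fmt == "dosage-tsv":
        g = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if pop_labels is not None:
        if isinstance(pop_labels, (str,)) or hasattr(pop_labels, "__fspath__"):
            pm = pd.read_csv(pop_labels, sep="\t", dtype=str)
            mapping = dict(zip(pm.iloc[:, 0], pm.iloc[:, 1]))
        else:
            mapping = dict(pop_labels)
        g.pop_labels = [mapping.get(i, "NA") for i in g.individuals]
    return g


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    rows, records, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", "") or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False default uses 3 for unknown)
        dos = np.array([_gt_to_dosage(gt) for gt in var.genotypes], dtype=float)
        rows.append(dos)
        records.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0])
        )
    if skipped:
        log.info("read_genotypes: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    markers = pd.DataFrame(records, columns=MARKER_COLUMNS)
    dosages = np.vstack(rows).T  # individuals x SNPs
    return GenotypeMatrix(dosages, markers, individuals, ["NA"] * len(individuals))


def _gt_to_dosage(gt) -> float:
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:
        return np.nan
    return float(a + b)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    """Dosage TSV: columns id, chrom, pos, ref, alt, then one column per individual."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dosage TSV missing columns {missing_cols}")
    individuals = [c for c in df.columns if c not in MARKER_COLUMNS]
    raw = df[individuals].to_numpy(dtype=object)
    dosages = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j]
            if isinstance(v, str):
                v = v.strip()
            if v in ("NA", ".", "", None) or (isinstance(v, float) and math.isnan(v)):
                dosages[i, j] = np.nan
            elif v in (0, 1, 2, "0", "1", "2", 0.0, 1.0, 2.0):
                dosages[i, j] = float(v)
            else:
                raise ValueError(
                    f"dosage TSV cell at marker row {i + 1}, individual "
                    f"{individuals[j]!r} is {v!r}, not one of 0/1/2/NA"
                )
    markers = df[MARKER_COLUMNS].reset_index(drop=True)
    return GenotypeMatrix(dosages.T, markers, individuals, ["NA"] * len(individuals))


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields from dosages."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        for j, row in enumerate(g.markers.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else gt_map[d] for d in g.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = g.markers.copy()
    for i, ind in enumerate(g.individuals):
        col = g.dosages[i]
        df[ind] = ["NA" if np.isnan(v) else str(int(v)) for v in col]
    df.to_csv(path, sep="\t", index=False)


def write_pop_map(g: GenotypeMatrix, path) -> None:
    pd.DataFrame({"individual": g.individuals, "population": g.pop_labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# QC


def maf_filter(g: GenotypeMatrix, cutoff: float = 0.01) -> GenotypeMatrix:
    """Retain SNPs with minor allele frequency >= cutoff (PLINK --maf semantics)."""
    if not 0.0 <= cutoff <= 0.5:
        raise ValueError("MAF cutoff must be in [0, 0.5]")
    keep = np.flatnonzero(g.maf() >= cutoff)
    return g.take_snps(keep)


def impute_dosages(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP (used inside PCA/RDA/LFMM only)."""
    out = np.array(dosages, dtype=float, copy=True)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(out, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def pairwise_r2(g: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of dosages over individuals complete at both SNPs.

    Returns ``nan`` when either SNP is monomorphic in the shared subset.
    """
    x = g.dosages[:, snp_i]
    y = g.dosages[:, snp_j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Dense r² among columns, missing entries mean-imputed; nan for monomorphic."""
    x = impute_dosages(dosages)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    r2 = c * c
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    return r2


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.5,
) -> GenotypeMatrix:
    """Greedy windowed LD pruning (PLINK --indep-pairwise style).

    Within each window of ``window_snps`` markers (per chromosome, sliding by
    ``step_snps``), while any retained pair has r² > threshold the member with
    the lower MAF is removed (tie -> larger position). Output preserves input
    marker order and is a subset of the input.
    """
    maf = g.maf()
    pos = g.markers["pos"].to_numpy()
    chrom = g.markers["chrom"].to_numpy()
    keep = np.ones(g.n_snps, dtype=bool)
    for c in pd.unique(g.markers["chrom"]):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(pos[idx], kind="stable")]
        start = 0
        while start < len(order):
            window = order[start : start + window_snps]
            live = [j for j in window if keep[j]]
            if len(live) > 1:
                r2 = _r2_matrix(g.dosages[:, live])
                _prune_window(live, r2, maf, pos, keep, r2_threshold)
            if start + window_snps >= len(order):
                break
            start += step_snps
    return g.take_snps(np.flatnonzero(keep))


def _prune_window(live, r2, maf, pos, keep, threshold) -> None:
    live = list(live)
    alive = {j: k for k, j in enumerate(live)}
    while True:
        worst, worst_pair = threshold, None
        for a_i, i in enumerate(live):
            if not keep[i]:
                continue
            for j in live[a_i + 1 :]:
                if not keep[j]:
                    continue
                v = r2[alive[i], alive[j]]
                if not np.isnan(v) and v > worst:
                    worst, worst_pair = v, (i, j)
        if worst_pair is None:
            return
        i, j = worst_pair
        if maf[i] < maf[j]:
            victim = i
        elif maf[j] < maf[i]:
            victim = j
        else:
            victim = i if pos[i] > pos[j] else j
        keep[victim] = False


# ---------------------------------------------------------------------------
# Diversity metrics


def weir_cockerham_components(
    dosages: np.ndarray, pop_labels
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir & Cockerham (1984) variance components (a, b, c).

    a: among-population; b: among-individuals-within-population;
    c: within-individual (heterozygosity) component. Computed per SNP from
    population sample sizes, allele frequencies and observed heterozygote
    proportions over non-missing genotypes.
    """
    labels = np.asarray(pop_labels)
    pops = pd.unique(pd.Series(labels))
    r = len(pops)
    if r < 2:
        raise ValueError("Weir–Cockerham FST needs >= 2 populations")
    m = dosages.shape[1]
    n_i = np.zeros((r, m))
    p_i = np.zeros((r, m))
    h_i = np.zeros((r, m))
    for k, pop in enumerate(pops):
        sub = dosages[labels == pop]
        ok = ~np.isnan(sub)
        n_i[k] = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[k] = np.nansum(sub, axis=0) / (2 * np.maximum(n_i[k], 1))
            h_i[k] = np.nansum(sub == 1, axis=0) / np.maximum(n_i[k], 1)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c


def weir_cockerham_fst(g: GenotypeMatrix, pop_labels=None) -> tuple[pd.Series, float]:
    """Per-SNP Weir–Cockerham theta and the multi-SNP ratio-of-sums average.

    SNPs monomorphic across all populations (a+b+c = 0) are excluded from the
    average and reported as ``nan`` per SNP.
    """
    labels = g.pop_labels if pop_labels is None else pop_labels
    a, b, c = weir_cockerham_components(g.dosages, labels)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    ok = (denom != 0) & ~np.isnan(denom)
    mean = float(a[ok].sum() / denom[ok].sum()) if ok.any() else float("nan")
    return pd.Series(theta, index=g.markers["id"], name="fst"), mean


def observed_heterozygosity(g: GenotypeMatrix, pop_labels=None) -> pd.Series:
    """Per-population observed heterozygosity, averaged over SNPs."""
    labels = np.asarray(g.pop_labels if pop_labels is None else pop_labels)
    out = {}
    for pop in pd.unique(pd.Series(labels)):
        sub = g.dosages[labels == pop]
        ok = ~np.isnan(sub)
        per_snp = (sub == 1).sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
        per_snp = np.where(ok.sum(axis=0) > 0, per_snp, np.nan)
        out[pop] = float(np.nanmean(per_snp))
    return pd.Series(out, name="ho")


def nucleotide_diversity(g: GenotypeMatrix, pop_labels=None) -> pd.DataFrame:
    """Per-SNP, per-population unbiased expected heterozygosity 2p(1-p)·n/(n-1).

    n is the number of non-missing diploid individuals (non-missing allele
    count / 2); SNPs with n < 2 in a population are reported as ``nan`` there.
    """
    labels = np.asarray(g.pop_labels if pop_labels is None else pop_labels)
    rows = {}
    for pop in pd.unique(pd.Series(labels)):
        sub = g.dosages[labels == pop]
        n = (~np.isnan(sub)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / (2 * n)
            pi = 2 * p * (1 - p) * n / (n - 1)
        rows[pop] = np.where(n >= 2, pi, np.nan)
    return pd.DataFrame.from_dict(rows, orient="index", columns=g.markers["id"])


def diversity_metrics(g: GenotypeMatrix) -> DiversityMetrics:
    fst_snp, fst_mean = weir_cockerham_fst(g)
    return DiversityMetrics(
        fst_per_snp=fst_snp,
        fst_mean=fst_mean,
        ho_per_pop=observed_heterozygosity(g),
        pi_per_snp=nucleotide_diversity(g),
    )
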
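"""Genotype QC, single-marker association, permutation thresholds, GWAS power
simulation, greedy LD-based QTL grouping, and moment-based heritability and
genetic-correlation estimators.

Genotypes are inbred di-allelic calls coded 0/1 per strain with NaN for
missing; the association engine is a fixed-effect least-squares regression
(per-SNP Wald test) with optional covariates, a documented stand-in for a
mixed-model engine with the same QC / permutation / power / grouping layer
on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "ScanResult",
    "qc_genotypes",
    "association_scan",
    "permutation_threshold",
    "causal_effect_size",
    "simulate_power",
    "greedy_qtl_grouping",
    "grm",
    "he_heritability",
    "he_genetic_correlation",
    "read_genotypes_csv",
    "write_genotypes_csv",
]


@dataclass
class GenotypeMatrix:
    """Strain x SNP genotype calls with a marker map.

    ``genotypes`` is a float array with entries in {0, 1, NaN}; ``chrom`` and
    ``pos`` give the marker map, with positions non-decreasing within each
    chromosome.
    """

    genotypes: np.ndarray
    snp_ids: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray
    strain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (strains x SNPs)")
        n, m = self.genotypes.shape
        self.snp_ids = tuple(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if len(self.snp_ids) != m or self.chrom.size != m or self.pos.size != m:
            raise ValueError("marker map length must equal the SNP count")
        if not self.strain_ids:
            self.strain_ids = tuple(f"strain{i}" for i in range(n))
        elif len(self.strain_ids) != n:
            raise ValueError("strain_ids length must equal the strain count")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("genotype calls must be 0, 1 or missing")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if (np.diff(p) < 0).any():
                raise ValueError(f"positions decrease within chromosome {c}")

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the '1' allele over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0)

    @property
    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.genotypes[:, keep],
            tuple(np.asarray(self.snp_ids, dtype=object)[keep]),
            self.chrom[keep],
            self.pos[keep],
            self.strain_ids,
        )


@dataclass
class ScanResult:
    """Per-SNP association results plus the context they were computed in."""

    table: pd.DataFrame  # snp, chrom, pos, af, beta, se, p, flag
    covariates: tuple[str, ...] = ()
    threshold: float | None = None


def qc_genotypes(
    g: GenotypeMatrix, maf_min: float = 0.10, missing_max: float = 0.05
) -> GenotypeMatrix:
    """Drop SNPs failing MAF or missingness filters; mean-impute the rest.

    Retains SNPs with minor allele frequency >= ``maf_min`` and missing-call
    fraction <= ``missing_max``; surviving missing calls are replaced by the
    SNP's mean genotype (so downstream arrays are dense).
    """
    af = g.allele_freq
    maf = np.minimum(af, 1.0 - af)
    keep = (maf >= maf_min) & (g.missing_fraction <= missing_max) & np.isfinite(af)
    if not keep.any():
        raise ValueError("no SNPs pass QC")
    out = g.subset(np.flatnonzero(keep))
    geno = out.genotypes
    if np.isnan(geno).any():
        col_mean = np.nanmean(geno, axis=0)
        idx = np.where(np.isnan(geno))
        geno[idx] = col_mean[idx[1]]
    return out


def _design(n: int, covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match the sample count")
        C = np.column_stack([C, cov])
    return C


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after least-squares projection on C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def association_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> ScanResult:
    """Per-SNP least-squares regression of y on genotype (+ covariates).

    Reports the genotype effect estimate, its standard error and the
    two-sided Wald p-value.  SNPs with (numerically) constant genotype are
    flagged and reported with p = 1.
    """
    y = np.asarray(y, dtype=np.float64)
    n = g.n_strains
    if y.shape != (n,):
        raise ValueError("phenotype length must equal the strain count")
    C = _design(n, covariates)
    if n < C.shape[1] + 3:
        raise ValueError("need at least 3 samples more than covariates")
    geno = np.where(np.isnan(g.genotypes), np.nanmean(g.genotypes, axis=0), g.genotypes)
    yr = _residualize(y[:, None], C)[:, 0]
    Xr = _residualize(geno, C)
    sxx = (Xr ** 2).sum(axis=0)
    dof = n - C.shape[1] - 1
    constant = sxx <= n * np.finfo(float).eps * max(1.0, float(np.abs(geno).max()))
    safe_sxx = np.where(constant, 1.0, sxx)
    beta = (Xr * yr[:, None]).sum(axis=0) / safe_sxx
    rss = (yr ** 2).sum() - beta ** 2 * safe_sxx
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / dof / safe_sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta = np.where(constant, 0.0, beta)
    se = np.where(constant, np.nan, se)
    p = np.where(constant, 1.0, p)
    table = pd.DataFrame(
        {
            "snp": list(g.snp_ids),
            "chrom": g.chrom,
            "pos": g.pos,
            "af": g.allele_freq,
            "beta": beta,
            "se": se,
            "p": p,
            "flag": np.where(constant, "constant_genotype", ""),
        }
    )
    cov_names = ()
    if covariates is not None:
        cov_names = (
            tuple(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else tuple(f"cov{i}" for i in range(np.atleast_2d(covariates).shape[-1]))
        )
    return ScanResult(table=table, covariates=cov_names)


def permutation_threshold(
    g: GenotypeMatrix,
    y: np.ndarray,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """Empirical genome-wide p-value threshold from phenotype permutations.

    The phenotype is shuffled across samples ``n_perm`` times; each
    permutation's minimum scan p-value is recorded and the empirical
    ``alpha``-quantile of that min-p distribution is returned.  Covariates,
    if given, are regressed out of both phenotype and genotypes before
    permuting (residual permutation).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    y = np.asarray(y, dtype=np.float64)
    n = g.n_strains
    C = _design(n, covariates)
    dof = n - C.shape[1] - 1
    if dof < 2:
        raise ValueError("too few samples for the permutation scan")
    geno = np.where(np.isnan(g.genotypes), np.nanmean(g.genotypes, axis=0), g.genotypes)
    Xr = _residualize(geno, C)
    yr = _residualize(y[:, None], C)[:, 0]
    # standardize for correlation-based t statistics
    xs = np.sqrt((Xr ** 2).sum(axis=0))
    keep = xs > 0
    Z = Xr[:, keep] / xs[keep]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(yr) for _ in range(n_perm)], axis=1)  # (n, P)
    perms = perms - perms.mean(axis=0)
    ys = np.sqrt((perms ** 2).sum(axis=0))
    ys[ys == 0] = 1.0
    R = Z.T @ (perms / ys)  # (M, P) correlations
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt(dof / np.maximum(1.0 - R ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    min_p = p.min(axis=0)
    return float(np.quantile(min_p, alpha))


def causal_effect_size(pve: float, var_y: float, af: float) -> float:
    """Effect size explaining ``pve`` of variance at allele frequency ``af``:
    sqrt(pve * var_y / (af * (1 - af)))."""
    if not 0.0 <= pve < 1.0:
        raise ValueError("pve must be in [0, 1)")
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    if not 0.0 < af < 1.0:
        raise ValueError("af must be strictly between 0 and 1")
    return float(np.sqrt(pve * var_y / (af * (1.0 - af))))


def simulate_power(
    g: GenotypeMatrix,
    y_base: np.ndarray,
    pve: float,
    n_causal: int,
    threshold: float,
    seed: int = 0,
    covariates: pd.DataFrame | np.ndarray | None = None,
    prefilter_p: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Simulation-based GWAS power at a given per-SNP variance explained.

    SNPs with nominal association to the base phenotype (p < ``prefilter_p``)
    are sorted by genomic position and ``n_causal`` evenly spaced ones are
    designated causal.  For each, an effect sized to explain ``pve`` of the
    phenotypic variance is added to the base phenotype, the marker is
    re-tested, and power is the fraction of causal SNPs detected below
    ``threshold``.
    """
    if n_causal < 1:
        raise ValueError("n_causal must be at least 1")
    y_base = np.asarray(y_base, dtype=np.float64)
    base = association_scan(g, y_base, covariates=covariates).table
    cand = base[base["p"] < prefilter_p].sort_values(["chrom", "pos"], kind="stable")
    if len(cand) < n_causal:
        raise ValueError(
            f"only {len(cand)} SNPs pass the p<{prefilter_p} prefilter; "
            f"need {n_causal}"
        )
    pick = np.unique(np.linspace(0, len(cand) - 1, n_causal).round().astype(int))
    causal = cand.iloc[pick]
    var_y = float(np.var(y_base, ddof=1))
    geno = np.where(np.isnan(g.genotypes), np.nanmean(g.genotypes, axis=0), g.genotypes)
    snp_index = {s: k for k, s in enumerate(g.snp_ids)}
    rows = []
    for _, rec in causal.iterrows():
        k = snp_index[rec["snp"]]
        af = float(rec["af"])
        effect = causal_effect_size(pve, var_y, af) if 0 < af < 1 else 0.0
        y_sim = y_base + effect * geno[:, k]
        single = GenotypeMatrix(
            geno[:, [k]], (rec["snp"],), g.chrom[[k]], g.pos[[k]], g.strain_ids
        )
        p = float(association_scan(single, y_sim, covariates=covariates).table["p"].iloc[0])
        rows.append(
            {
                "snp": rec["snp"],
                "chrom": rec["chrom"],
                "pos": rec["pos"],
                "af": af,
                "effect": effect,
                "p": p,
                "detected": p < threshold,
            }
        )
    detail = pd.DataFrame(rows)
    return float(detail["detected"].mean()), detail


def greedy_qtl_grouping(
    scan: ScanResult,
    g: GenotypeMatrix,
    threshold: float,
    r2_min: float = 0.2,
) -> pd.DataFrame:
    """Group significant SNPs into loci by greedy LD expansion around peaks.

    Starting from the unassigned significant SNP with the smallest p-value, a
    locus absorbs unassigned significant SNPs on the same chromosome by
    contiguous extension outward from the peak (in position order over the
    significant SNPs), stopping on each side at the first SNP whose genotype
    r-squared with the peak falls below ``r2_min``.  Repeats until every
    significant SNP is assigned.  Returns a table (snp, chrom, pos, p,
    locus, is_peak) with loci numbered in discovery order.
    """
    table = scan.table
    sig = table[table["p"] < threshold].copy()
    if sig.empty:
        raise ValueError("no SNPs below the significance threshold")
    geno = np.where(np.isnan(g.genotypes), np.nanmean(g.genotypes, axis=0), g.genotypes)
    snp_index = {s: k for k, s in enumerate(g.snp_ids)}
    sig["_col"] = [snp_index[s] for s in sig["snp"]]
    sig = sig.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    locus = np.full(len(sig), -1)
    is_peak = np.zeros(len(sig), dtype=bool)

    def _r2(a: int, b: int) -> float:
        xa, xb = geno[:, a], geno[:, b]
        if xa.std() == 0 or xb.std() == 0:
            return 0.0
        return float(np.corrcoef(xa, xb)[0, 1] ** 2)

    next_locus = 0
    while (locus < 0).any():
        open_idx = np.flatnonzero(locus < 0)
        peak = open_idx[np.argmin(sig.loc[open_idx, "p"].to_numpy())]
        locus[peak] = next_locus
        is_peak[peak] = True
        peak_col = int(sig.loc[peak, "_col"])
        peak_chrom = sig.loc[peak, "chrom"]
        for step in (1, -1):  # extend right, then left
            i = peak + step
            while 0 <= i < len(sig) and sig.loc[i, "chrom"] == peak_chrom:
                if locus[i] >= 0:
                    break
                if _r2(int(sig.loc[i, "_col"]), peak_col) < r2_min:
                    break
                locus[i] = next_locus
                i += step
        next_locus += 1
    out = sig.drop(columns="_col").copy()
    out["locus"] = locus
    out["is_peak"] = is_peak
    return out


def grm(g: GenotypeMatrix) -> np.ndarray:
    """Genetic relatedness matrix K = Z Z' / M from standardized genotypes.

    Zero-variance SNPs are dropped before standardization; the result is
    symmetric with mean diagonal 1 by construction.
    """
    geno = np.where(np.isnan(g.genotypes), np.nanmean(g.genotypes, axis=0), g.genotypes)
    mu = geno.mean(axis=0)
    sd = geno.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all SNPs are constant; GRM undefined")
    Z = (geno[:, keep] - mu[keep]) / sd[keep]
    return Z @ Z.T / int(keep.sum())


def _offdiag_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def he_heritability(K: np.ndarray, y: np.ndarray) -> float:
    """Haseman-Elston regression estimate of narrow-sense heritability.

    Regresses products of the standardized phenotype over sample pairs on
    the corresponding kinship entries (off-diagonal, with intercept); the
    slope, clamped to [0, 1], estimates the phenotypic variance fraction
    tagged by the kinship.
    """
    K = np.asarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("K and y are not aligned")
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    i, j = _offdiag_pairs(n)
    k_od = K[i, j]
    if np.std(k_od) == 0:
        raise ValueError("kinship is constant off the diagonal; slope undefined")
    z = (y - y.mean()) / y.std(ddof=0)
    prod = z[i] * z[j]
    slope = np.cov(k_od, prod, ddof=1)[0, 1] / np.var(k_od, ddof=1)
    return float(np.clip(slope, 0.0, 1.0))


def he_genetic_correlation(K: np.ndarray, y1: np.ndarray, y2: np.ndarray) -> float:
    """Cross-trait Haseman-Elston genetic correlation, clamped to [-1, 1].

    Returns NaN (flagged missing) when either trait's own HE slope is not
    positive, since the normalization is then undefined.
    """
    K = np.asarray(K, dtype=np.float64)
    y1 = np.asarray(y1, dtype=np.float64)
    y2 = np.asarray(y2, dtype=np.float64)
    n = y1.size
    if K.shape != (n, n) or y2.size != n:
        raise ValueError("K, y1 and y2 are not aligned")
    if np.std(y1) == 0 or np.std(y2) == 0:
        raise ValueError("phenotype has zero variance")
    i, j = _offdiag_pairs(n)
    k_od = K[i, j]
    var_k = np.var(k_od, ddof=1)
    if var_k == 0:
        raise ValueError("kinship is constant off the diagonal; slope undefined")
    z1 = (y1 - y1.mean()) / y1.std(ddof=0)
    z2 = (y2 - y2.mean()) / y2.std(ddof=0)
    s1 = np.cov(k_od, z1[i] * z1[j], ddof=1)[0, 1] / var_k
    s2 = np.cov(k_od, z2[i] * z2[j], ddof=1)[0, 1] / var_k
    cross = 0.5 * (z1[i] * z2[j] + z1[j] * z2[i])
    s12 = np.cov(k_od, cross, ddof=1)[0, 1] / var_k
    if s1 <= 0 or s2 <= 0:
        return float("nan")
    return float(np.clip(s12 / np.sqrt(s1 * s2), -1.0, 1.0))


# ---------------------------------------------------------------------------
# delimited I/O: genotype matrix + marker-map sidecar

def write_genotypes_csv(g: GenotypeMatrix, geno_path, map_path) -> tuple[str, str]:
    pd.DataFrame(g.genotypes, index=list(g.strain_ids), columns=list(g.snp_ids)).to_csv(
        geno_path
    )
    pd.DataFrame({"snp": list(g.snp_ids), "chrom": g.chrom, "pos": g.pos}).to_csv(
        map_path, index=False
    )
    return str(geno_path), str(map_path)


def read_genotypes_csv(geno_path, map_path) -> GenotypeMatrix:
    geno = pd.read_csv(geno_path, index_col=0)
    marker = pd.read_csv(map_path)
    if list(geno.columns) != list(marker["snp"].astype(str)):
        raise ValueError("marker map SNPs do not match the genotype columns")
    return GenotypeMatrix(
        geno.to_numpy(dtype=float),
        tuple(geno.columns),
        marker["chrom"].to_numpy(),
        marker["pos"].to_numpy(),
        tuple(str(s) for s in geno.index),
    )
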
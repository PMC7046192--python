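"""Genotype-phenotype association for the 0/0.5/1-scored colour-pattern
loci: SNP filtering (call rate, minor allele count, heterozygote fraction,
distance thinning), a Wald test from simple least-squares regression of
phenotype on allele dosage, and top-quantile hit extraction with
nearest-gene annotation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenotypeMatrix


def filter_snps(gm: GenotypeMatrix, min_n: int = 40, min_mac: int = 2,
                max_het_frac: float = 0.75, thin_bp: int = 100) -> np.ndarray:
    """Boolean site mask of biallelic SNPs passing the association filters.

    Criteria: genotyped in >= min_n individuals, minor allele count >=
    min_mac, heterozygous in <= max_het_frac of non-missing individuals,
    and thinned to a minimum inter-SNP distance (greedy left-to-right: the
    first passing SNP is kept, any subsequent passing SNP closer than
    ``thin_bp`` on the same chromosome is dropped).
    """
    biallelic = np.array([len(a) == 1 for a in gm.alt])
    called = ~gm.is_missing()
    n_called = called.sum(axis=1)
    counts = gm.allele_counts()
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mac = np.minimum(counts[:, 0], total - counts[:, 0])
    het_frac = np.divide(gm.is_het().sum(axis=1), n_called,
                         out=np.zeros(gm.n_sites), where=n_called > 0)
    mask = (biallelic & (n_called >= min_n) & (mac >= min_mac)
            & (het_frac <= max_het_frac))
    out = np.zeros_like(mask)
    for chrom in dict.fromkeys(gm.chrom):
        idx = np.flatnonzero((gm.chrom == chrom) & mask)
        last = -np.inf
        for i in idx:
            if gm.pos[i] - last >= thin_bp:
                out[i] = True
                last = gm.pos[i]
    return out


@dataclass
class AssocResult:
    chrom: str
    pos: int
    n: int
    beta: float | None
    se: float | None
    statistic: float | None
    p: float | None
    reason: str = ""


def wald_assoc(dosages, phenotypes, chrom: str = "", pos: int = 0
               ) -> AssocResult:
    """Wald test of a quantitative phenotype on allele dosage.

    Simple least-squares regression of phenotype (0/0.5/1) on dosage
    (0/1/2); the Wald statistic is (beta/SE)^2 with an asymptotic
    chi-squared(1) p-value.  Pairs with a missing value on either side are
    excluded.  Zero dosage variance or zero residual degrees of freedom
    give a null result with a reason code.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(d) | (d < 0))
    d, y = d[ok], y[ok]
    n = len(d)
    if n < 3:
        return AssocResult(chrom, pos, n, None, None, None, None,
                           "fewer than 3 complete pairs")
    sxx = np.sum((d - d.mean()) ** 2)
    if sxx == 0:
        return AssocResult(chrom, pos, n, None, None, None, None,
                           "no variance")
    beta = np.sum((d - d.mean()) * (y - y.mean())) / sxx
    resid = y - y.mean() - beta * (d - d.mean())
    df = n - 2
    if df <= 0:
        return AssocResult(chrom, pos, n, None, None, None, None,
                           "no residual degrees of freedom")
    sigma2 = np.sum(resid ** 2) / df
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0:
        # noiseless fit: statistic is unbounded, p underflows to the
        # smallest representable positive value
        return AssocResult(chrom, pos, n, float(beta), 0.0, np.inf, 5e-324)
    stat = float((beta / se) ** 2)
    p = float(stats.chi2.sf(stat, df=1))
    return AssocResult(chrom, pos, n, float(beta), se, stat,
                       max(p, 5e-324))


def assoc_scan(gm: GenotypeMatrix, phenotypes: pd.Series,
               site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP Wald association over masked sites.

    ``phenotypes`` is indexed by sample id; samples absent from it (or NaN)
    are excluded pairwise.
    """
    pheno = np.array([phenotypes.get(s, np.nan) for s in gm.samples])
    dos = gm.alt_dosage().astype(float)
    dos[dos < 0] = np.nan
    mask = np.ones(gm.n_sites, bool) if site_mask is None else site_mask
    rows = []
    for i in np.flatnonzero(mask):
        r = wald_assoc(dos[i], pheno, gm.chrom[i], int(gm.pos[i]))
        rows.append((r.chrom, r.pos, r.n, r.beta, r.se, r.statistic, r.p,
                     r.reason))
    return pd.DataFrame(rows, columns=["chrom", "pos", "n", "beta", "se",
                                       "stat", "p", "reason"])


def top_hits(results: pd.DataFrame, quantile: float = 0.9999,
             genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sites at or above the empirical quantile of the Wald statistic.

    The threshold uses the nearest-rank convention; ties at the threshold
    are all retained.  Each hit is annotated with the nearest gene by
    midpoint distance (ties report both genes).
    """
    res = results.dropna(subset=["stat"]).copy()
    if res.empty:
        return res.assign(nearest_gene=[], distance=[])
    thr = np.quantile(res["stat"].values, quantile, method="inverted_cdf")
    hits = res[res["stat"] >= thr].copy()
    if genes is None or genes.empty:
        hits["nearest_gene"] = None
        hits["distance"] = np.nan
        return hits
    mid = ((genes.start + genes.end) // 2).values
    names, dists = [], []
    for _, h in hits.iterrows():
        sub = genes[genes.chrom == h.chrom]
        if sub.empty:
            names.append(None)
            dists.append(np.nan)
            continue
        d = np.abs(((sub.start + sub.end) // 2).values - h.pos)
        best = d.min()
        tied = sub.gene_id.values[d == best]
        names.append(";".join(tied))
        dists.append(int(best))
    hits["nearest_gene"] = names
    hits["distance"] = dists
    return hits
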
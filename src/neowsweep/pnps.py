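"""Genetic-load machinery: strict 0-fold / 4-fold codon-position
classification, frequency-stratified Pn/Ps within a cohort, and gene-level
bootstrap comparisons between genomic regions.

Site classes are assigned conservatively from the reference codon: a third
position is "four-fold" only if every base substitution there is synonymous,
a position is "zero-fold" only if every substitution is non-synonymous, and
a position is classified at all only when the other two positions of its
codon are invariant across the entire dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix

# base codes 0..3 = A C G T
_CODE = "ACGT"
STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA TAG TGA


def _codon_table() -> dict[tuple, str]:
    from Bio.Data import CodonTable

    tab = CodonTable.unambiguous_dna_by_id[1]
    out = {}
    for codon, aa in tab.forward_table.items():
        out[tuple(_CODE.index(b) for b in codon)] = aa
    for codon in tab.stop_codons:
        out[tuple(_CODE.index(b) for b in codon)] = "*"
    return out


_AA = _codon_table()


def _position_class(codon: tuple, i: int) -> str:
    """Degeneracy class of position i of a reference codon."""
    aa = _AA[codon]
    syn = 0
    for b in range(4):
        if b == codon[i]:
            continue
        alt = list(codon)
        alt[i] = b
        if _AA[tuple(alt)] == aa:
            syn += 1
    if syn == 3:
        return "four-fold"
    if syn == 0:
        return "zero-fold"
    return "other"


def reference_degeneracy(refseq: np.ndarray, genes: pd.DataFrame
                         ) -> dict[int, str]:
    """Reference-only degeneracy of coding positions on one chromosome.

    ``refseq`` is the uint8 base-code array; ``genes`` the gene table for
    this chromosome (plus strand only).  Genes whose length is not a
    multiple of 3 or that contain an internal stop are skipped with a
    warning.  Returns position -> {"zero-fold", "four-fold"} (other
    positions omitted).
    """
    out: dict[int, str] = {}
    for _, g in genes.iterrows():
        if (g.end - g.start) % 3:
            warnings.warn(f"gene {g.gene_id}: length not divisible by 3, "
                          "skipped")
            continue
        codons = [tuple(int(b) for b in refseq[c:c + 3])
                  for c in range(g.start, g.end, 3)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            warnings.warn(f"gene {g.gene_id}: internal stop codon, skipped")
            continue
        for k, codon in enumerate(codons):
            for i in range(3):
                cls = _position_class(codon, i)
                if cls != "other":
                    out[g.start + 3 * k + i] = cls
    return out


def classify_degeneracy(refseq: dict[str, np.ndarray], genes: pd.DataFrame,
                        gm: GenotypeMatrix) -> pd.DataFrame:
    """Degeneracy map with the dataset-invariance requirement.

    A position keeps its reference class only if the other two positions of
    its codon carry no polymorphism anywhere in ``gm``.  Returns a frame
    with columns chrom, pos, cls, gene_id, codon_pos.
    """
    rows = []
    for chrom in genes.chrom.unique():
        poly = set(int(p) for p in gm.pos[gm.chrom == chrom])
        sub = genes[genes.chrom == chrom]
        for _, g in sub.iterrows():
            if (g.end - g.start) % 3:
                warnings.warn(f"gene {g.gene_id}: length not divisible by 3,"
                              " skipped")
                continue
            seq = refseq[chrom]
            codons = [tuple(int(b) for b in seq[c:c + 3])
                      for c in range(g.start, g.end, 3)]
            if any(c in STOP_CODONS for c in codons[:-1]):
                warnings.warn(f"gene {g.gene_id}: internal stop, skipped")
                continue
            for k, codon in enumerate(codons):
                base = g.start + 3 * k
                for i in range(3):
                    cls = _position_class(codon, i)
                    if cls == "other":
                        continue
                    others = [base + j for j in range(3) if j != i]
                    if any(o in poly for o in others):
                        continue  # invariance rule
                    rows.append((chrom, base + i, cls, g.gene_id, i))
    return pd.DataFrame(rows, columns=["chrom", "pos", "cls", "gene_id",
                                       "codon_pos"])


@dataclass
class StratifiedCounts:
    """Folded-frequency-stratified polymorphism counts for one region."""

    per_class: pd.DataFrame   # freq_class, Pn, Ps, ratio
    per_gene: pd.DataFrame    # gene_id, Pn, Ps, Ln, Ls (+ per-class cols)
    Pn: int
    Ps: int
    Ln: int
    Ls: int
    n_alleles: int

    @property
    def ratio(self) -> float | None:
        if self.Ps == 0 or self.Ls == 0 or self.Ln == 0:
            return None
        return (self.Pn / self.Ln) / (self.Ps / self.Ls)


def _in_regions(chrom, pos, regions) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for (c, lo, hi) in regions:
        mask |= (chrom == c) & (pos >= lo) & (pos < hi)
    return mask


def stratified_pnps(gm: GenotypeMatrix, degmap: pd.DataFrame, cohort,
                    regions=None, exclude=None) -> StratifiedCounts:
    """Pn/Ps stratified by folded minor-allele count within a cohort.

    Only sites genotyped in *every* cohort member are considered
    (complete-case rule).  ``regions`` / ``exclude`` are lists of
    (chrom, start, end) half-open intervals; by default all classified
    sites are used.  Frequency classes are folded minor-allele counts
    1..n on the cohort's 2n sampled alleles.
    """
    idx = gm.sample_index(cohort)
    n_alleles = 2 * len(idx)
    dm = degmap
    if regions is not None:
        dm = dm[_in_regions(dm.chrom.values, dm.pos.values, regions)]
    if exclude is not None:
        dm = dm[~_in_regions(dm.chrom.values, dm.pos.values, exclude)]

    # map classified positions onto matrix records (absent record =>
    # invariant => monomorphic, still counted in Ln/Ls)
    counts_rows = []
    per_gene: dict[str, dict] = {}
    gt = gm.gt[:, idx, :]
    missing_any = np.any(gt == -1, axis=(1, 2))
    alt_count = np.sum(gt > 0, axis=(1, 2))
    pos_by_chrom = {c: (np.flatnonzero(gm.chrom == c)) for c in
                    dict.fromkeys(gm.chrom)}
    for chrom, sub in dm.groupby("chrom", sort=False):
        rec_idx = pos_by_chrom.get(chrom)
        rec_pos = gm.pos[rec_idx] if rec_idx is not None else \
            np.empty(0, np.int64)
        where = np.searchsorted(rec_pos, sub.pos.values)
        has_rec = (where < len(rec_pos)) & \
            (rec_pos[np.minimum(where, len(rec_pos) - 1)] == sub.pos.values)
        for (p, cls, gene), hit, w in zip(
                sub[["pos", "cls", "gene_id"]].itertuples(index=False),
                has_rec, where):
            slot = per_gene.setdefault(gene, dict(
                Pn=0, Ps=0, Ln=0, Ls=0, classes={}))
            mc = 0
            if hit:
                i = rec_idx[w]
                if missing_any[i]:
                    continue  # complete-case rule: site not counted at all
                c = int(alt_count[i])
                mc = min(c, n_alleles - c)
            if cls == "zero-fold":
                slot["Ln"] += 1
            else:
                slot["Ls"] += 1
            if mc > 0:
                key = "Pn" if cls == "zero-fold" else "Ps"
                slot[key] += 1
                slot["classes"].setdefault(mc, [0, 0])
                slot["classes"][mc][0 if cls == "zero-fold" else 1] += 1
                counts_rows.append((mc, cls))

    Ln = sum(g["Ln"] for g in per_gene.values())
    Ls = sum(g["Ls"] for g in per_gene.values())
    Pn = sum(g["Pn"] for g in per_gene.values())
    Ps = sum(g["Ps"] for g in per_gene.values())
    n_fold = n_alleles // 2
    rows = []
    for fc in range(1, n_fold + 1):
        pn = sum(1 for mc, cls in counts_rows
                 if mc == fc and cls == "zero-fold")
        ps = sum(1 for mc, cls in counts_rows
                 if mc == fc and cls == "four-fold")
        ratio = ((pn / Ln) / (ps / Ls)) if (ps > 0 and Ln > 0 and Ls > 0) \
            else None
        rows.append((fc, pn, ps, ratio))
    per_class = pd.DataFrame(rows, columns=["freq_class", "Pn", "Ps",
                                            "ratio"])
    gene_rows = []
    for gene, g in per_gene.items():
        row = dict(gene_id=gene, Pn=g["Pn"], Ps=g["Ps"], Ln=g["Ln"],
                   Ls=g["Ls"])
        for fc, (pn, ps) in g["classes"].items():
            row[f"Pn_{fc}"] = pn
            row[f"Ps_{fc}"] = ps
        gene_rows.append(row)
    per_gene_df = pd.DataFrame(gene_rows).fillna(0) if gene_rows else \
        pd.DataFrame(columns=["gene_id", "Pn", "Ps", "Ln", "Ls"])
    return StratifiedCounts(per_class, per_gene_df, Pn, Ps, Ln, Ls, n_alleles)


@dataclass
class BootstrapResult:
    p: float
    observed_delta: float
    ratio_a: float
    ratio_b: float
    n_boot: int
    n_reproduced: int
    p_is_bound: bool
    ci_a: tuple
    ci_b: tuple


def _region_ratio(df: pd.DataFrame, pn_col: str, ps_col: str) -> float:
    Pn, Ps = df[pn_col].sum(), df[ps_col].sum()
    Ln, Ls = df["Ln"].sum(), df["Ls"].sum()
    if Ps == 0 or Ln == 0 or Ls == 0:
        return np.nan
    return (Pn / Ln) / (Ps / Ls)


def bootstrap_compare(genes_a: pd.DataFrame, genes_b: pd.DataFrame,
                      n_boot: int = 1000, seed=None, freq_class=None
                      ) -> BootstrapResult:
    """One-sided gene-resampling bootstrap of the Pn/Ps difference A - B.

    Genes are resampled with replacement within each region; a replicate
    "reproduces" the observed bias when its difference has the same sign as
    the point estimate.  p = 1 - (reproducing fraction); when every
    replicate reproduces, p is reported as the bound 1/n_boot rather than 0.
    ``freq_class`` restricts polymorphism counts to one folded class.
    """
    if len(genes_a) < 2 or len(genes_b) < 2:
        raise ValueError("need at least 2 resampling units per region")
    pn_col = "Pn" if freq_class is None else f"Pn_{freq_class}"
    ps_col = "Ps" if freq_class is None else f"Ps_{freq_class}"
    for df in (genes_a, genes_b):
        for col in (pn_col, ps_col):
            if col not in df.columns:
                df[col] = 0
    rng = np.random.default_rng(seed)
    r_a = _region_ratio(genes_a, pn_col, ps_col)
    r_b = _region_ratio(genes_b, pn_col, ps_col)
    obs = r_a - r_b
    # a zero observed difference has no direction; score replicates against
    # an arbitrary one so the symmetric null lands near p = 0.5
    sign = np.sign(obs) if obs != 0 else 1.0
    reps_a = np.empty(n_boot)
    reps_b = np.empty(n_boot)
    k = 0
    for r in range(n_boot):
        ia = rng.integers(0, len(genes_a), len(genes_a))
        ib = rng.integers(0, len(genes_b), len(genes_b))
        ra = _region_ratio(genes_a.iloc[ia], pn_col, ps_col)
        rb = _region_ratio(genes_b.iloc[ib], pn_col, ps_col)
        reps_a[r], reps_b[r] = ra, rb
        d = ra - rb
        if np.isfinite(d) and np.sign(d) == sign and d != 0:
            k += 1
    bound = k == n_boot
    p = (1.0 / n_boot) if bound else 1.0 - k / n_boot
    ci = lambda x: tuple(np.nanpercentile(x, [2.5, 97.5]))
    return BootstrapResult(p, obs, r_a, r_b, n_boot, k, bound,
                           ci(reps_a), ci(reps_b))
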
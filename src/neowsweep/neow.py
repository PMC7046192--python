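"""The neo-W discovery chain: scan for high-frequency female-specific
mutations, find diagnostic heterozygous sites, reconstruct the haploid
neo-W from phased fragments, measure its diversity, compare divergence
against wild-type contact-zone individuals, and date the root of the
lineage with a moment estimator.

The dating estimator T = pi / (2 mu) assumes a star genealogy (every pair
of neo-W copies coalesces at the founding fusion event), which is the
limiting shape under a rapid sweep.  It deliberately replaces Bayesian
MCMC dating: it recovers a simulated fusion age well within a factor of
two, but it does not reproduce a posterior distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenomeLayout, GenotypeMatrix, Window, iter_windows
from .stattests import TestResult, wilcoxon_signed_rank
from .winstats import het_density


# ---------------------------------------------------------------------------
# female-specific mutation scan


def female_specific_scan(gm: GenotypeMatrix, females, males,
                         layout: GenomeLayout, freq_threshold: float = 0.2,
                         size: int = 100_000, step: int = 20_000,
                         outgroups=None) -> pd.DataFrame:
    """Count, per window, alternate alleles at frequency above the
    threshold among female calls and absent from all male calls (missing
    calls are excluded from both denominators).  Undefined without males.

    ``outgroups`` enables the stricter derived-state polarisation: the
    allele must additionally be absent from those samples (e.g. allopatric
    populations), which suppresses the false-positive floor that pure
    drift in a small focal deme creates.
    """
    if len(males) == 0:
        raise ValueError("female-specific contrast undefined without males")
    fi = gm.sample_index(females)
    mi = gm.sample_index(males)
    cf = gm.allele_counts(fi)
    cm = gm.allele_counts(mi)
    nf = cf.sum(axis=1)
    nm = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_f = cf[:, 1:] / nf[:, None]
    qual_alt = ((freq_f > freq_threshold) & (cm[:, 1:] == 0)
                & (nf[:, None] > 0) & (nm[:, None] > 0))
    if outgroups:
        co = gm.allele_counts(gm.sample_index(outgroups))
        qual_alt &= co[:, 1:] == 0
    qualifies = np.any(qual_alt, axis=1)
    rows = []
    for chrom in layout.chromosomes:
        for w in iter_windows(layout, chrom, size, step):
            sl = gm.site_slice(chrom, w.start, w.end)
            rows.append((chrom, w.start, w.end,
                         int(qualifies[sl].sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# diagnostic sites


@dataclass
class DiagnosticSiteSet:
    chrom: np.ndarray
    pos: np.ndarray
    allele: np.ndarray          # alternate-allele index of the neo-W allele
    carriers: list
    n_checked: int

    def __len__(self) -> int:
        return len(self.pos)


def find_diagnostic_sites(gm: GenotypeMatrix, carriers, non_carriers,
                          outgroups=(), allow_missing_non_carriers: bool
                          = False) -> DiagnosticSiteSet:
    """Sites heterozygous for one allele in every carrier, with that allele
    absent from all non-carriers and outgroups.

    By default every non-carrier must be genotyped (and homozygous for a
    different allele) at the site; ``allow_missing_non_carriers`` relaxes
    this to "absent wherever genotyped".
    """
    ci = gm.sample_index(carriers)
    oi = gm.sample_index(list(non_carriers) + list(outgroups))
    gt_c = gm.gt[:, ci, :]
    gt_o = gm.gt[:, oi, :]
    car_called = ~np.any(gt_c == -1, axis=2)
    car_het = car_called & (gt_c[:, :, 0] != gt_c[:, :, 1])
    all_het = np.all(car_het, axis=1)
    other_called = ~np.any(gt_o == -1, axis=2)
    others_ok = np.all(other_called, axis=1) if not \
        allow_missing_non_carriers else np.ones(gm.n_sites, bool)

    chroms, poss, alleles = [], [], []
    for i in np.flatnonzero(all_het & others_ok):
        # candidate neo-W allele: shared across every carrier's het call
        cand = set(gt_c[i, 0])
        for j in range(1, gt_c.shape[1]):
            cand &= set(gt_c[i, j])
        cand.discard(-1)
        obs_other = set(gt_o[i][other_called[i]].ravel().tolist())
        cand -= obs_other
        if len(cand) != 1:
            continue
        chroms.append(gm.chrom[i])
        poss.append(int(gm.pos[i]))
        alleles.append(cand.pop())
    return DiagnosticSiteSet(np.array(chroms, dtype=object),
                             np.array(poss, dtype=np.int64),
                             np.array(alleles, dtype=np.int8),
                             list(carriers), gm.n_sites)


def check_diagnostics(gm: GenotypeMatrix, diag: DiagnosticSiteSet,
                      non_carriers) -> bool:
    """Re-assert the defining predicate of every diagnostic site."""
    ci = gm.sample_index(diag.carriers)
    oi = gm.sample_index(non_carriers)
    for chrom, pos, allele in zip(diag.chrom, diag.pos, diag.allele):
        sl = gm.site_slice(chrom, pos, pos + 1)
        if sl.stop == sl.start:
            return False
        g = gm.gt[sl.start]
        for j in ci:
            a, b = g[j]
            if a == b or allele not in (a, b):
                return False
        for j in oi:
            if allele in g[j]:
                return False
    return True


# ---------------------------------------------------------------------------
# fragment-based haploid reconstruction


@dataclass
class NeoWHaplotype:
    """Haploid neo-W calls for one carrier: allele per covered variant site
    (MISSING elsewhere), per-site supporting-fragment counts, and the
    merged genomic intervals covered by attributed fragments."""

    sample: str
    chrom: str
    pos: np.ndarray
    allele: np.ndarray          # -1 missing
    support: np.ndarray
    covered: list               # merged (start, end) intervals
    flagged: bool = False


def _merge_intervals(iv):
    if not len(iv):
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def reconstruct_neow(gm: GenotypeMatrix, diag: DiagnosticSiteSet, fragments,
                     min_support: int = 3, chrom: str = "chr15"
                     ) -> dict[str, NeoWHaplotype]:
    """Isolate the neo-W haplotype of each carrier from phased fragments.

    Fragments overlapping a diagnostic site and carrying the neo-W allele
    there are attributed to the neo-W; every variant allele those fragments
    cover becomes a candidate haploid call, emitted where the supporting
    fragment count reaches ``min_support`` (the ploidy-1 minimum-depth
    analogue).  A carrier with no attributed fragments yields an
    all-missing haplotype, flagged.
    """
    sl = gm.site_slice(chrom)
    sites = gm.pos[sl]
    out = {}
    dmask = diag.chrom == chrom
    dpos = diag.pos[dmask]
    for sample in diag.carriers:
        j = gm.sample_index([sample])[0]
        frag_idx = set()
        for p in dpos:
            cov = fragments.covering(sample, chrom, int(p))
            if len(cov) == 0:
                continue
            carr = fragments.carries_derived(sample, chrom, cov, int(p))
            frag_idx.update(int(c) for c in cov[carr])
        d = fragments.frags.get(sample, {}).get(chrom)
        if not frag_idx or d is None:
            out[sample] = NeoWHaplotype(sample, chrom, sites,
                                        np.full(len(sites), -1, np.int8),
                                        np.zeros(len(sites), np.int32),
                                        [], flagged=True)
            continue
        fidx = np.fromiter(frag_idx, dtype=int)
        starts, ends = d["start"][fidx], d["end"][fidx]
        support = np.zeros(len(sites), dtype=np.int32)
        votes_alt = np.zeros(len(sites), dtype=np.int32)
        lo = np.searchsorted(sites, starts)
        hi = np.searchsorted(sites, ends)
        for k, (a, b) in enumerate(zip(lo, hi)):
            if a == b:
                continue
            cover = np.arange(a, b)
            support[cover] += 1
            carr = fragments.derived_mask(sample, chrom, int(fidx[k]),
                                          sites[cover])
            votes_alt[cover[carr]] += 1
        allele = np.full(len(sites), -1, np.int8)
        called = support >= min_support
        maj_alt = votes_alt * 2 > support
        maj_ref = (support - votes_alt) * 2 > support
        allele[called & maj_alt] = 1
        allele[called & maj_ref] = 0
        # never contradict the carrier's diploid genotype
        gt = gm.gt[sl, j, :]
        ok_call = (allele < 0) | np.any(gt == allele[:, None], axis=1) | \
            np.any(gt == -1, axis=1)
        allele[~ok_call] = -1
        covered = _merge_intervals(list(zip(starts.tolist(), ends.tolist())))
        out[sample] = NeoWHaplotype(sample, chrom, sites, allele, support,
                                    covered)
    return out


def neow_fasta(haps: dict[str, NeoWHaplotype], gm: GenotypeMatrix, path
               ) -> None:
    """Export reconstructed haploid sequences over variant-site columns,
    missing calls as N."""
    from .io_core import write_fasta

    recs = {}
    for sample, h in haps.items():
        sl = gm.site_slice(h.chrom)
        bases = []
        for i, a in zip(range(sl.start, sl.stop), h.allele):
            bases.append("N" if a < 0 else
                         (gm.ref[i] if a == 0 else gm.alt[i][a - 1]))
        recs[sample] = "".join(bases)
    write_fasta(recs, path)


# ---------------------------------------------------------------------------
# haploid diversity and divergence


def _interval_overlap(a, b) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def haploid_pi(haps: dict[str, NeoWHaplotype] | list,
               region: tuple[int, int] | None = None) -> float | None:
    """Mean per-base pairwise mismatch among reconstructed haploid
    sequences, averaged over pairs.

    For each pair, the denominator is the length of the overlap of their
    covered intervals (optionally intersected with ``region``) and the
    numerator the number of variant sites where both are called and
    differ.  Pairs with no overlap are skipped; None if no pair is usable.
    """
    hs = list(haps.values()) if isinstance(haps, dict) else list(haps)
    if len(hs) < 2:
        raise ValueError("need at least 2 haplotypes")
    vals = []
    for i in range(len(hs)):
        for j in range(i + 1, len(hs)):
            a, b = hs[i], hs[j]
            cov_a, cov_b = a.covered, b.covered
            if region is not None:
                cov_a = _merge_intervals(
                    [(max(s, region[0]), min(e, region[1]))
                     for s, e in cov_a if e > region[0] and s < region[1]])
                cov_b = _merge_intervals(
                    [(max(s, region[0]), min(e, region[1]))
                     for s, e in cov_b if e > region[0] and s < region[1]])
            denom = _interval_overlap(cov_a, cov_b)
            if denom <= 0:
                continue
            both = (a.allele >= 0) & (b.allele >= 0)
            if region is not None:
                both &= (a.pos >= region[0]) & (a.pos < region[1])
            diff = int(np.sum(both & (a.allele != b.allele)))
            vals.append(diff / denom)
    return None if not vals else float(np.mean(vals))


@dataclass
class DivergenceReport:
    windows: pd.DataFrame
    test: TestResult | None
    n_windows: int


def divergence_test(gm: GenotypeMatrix, neow_females, wildtype,
                    layout: GenomeLayout, chrom: str = "chr15",
                    region_start: int = 0, size: int = 100_000,
                    step: int = 100_000, min_sites: int = 20_000
                    ) -> DivergenceReport:
    """Compare per-window heterozygosity density between neo-W females and
    wild-type individuals over the colinear region.

    Each usable window contributes the two group means as a pair; the
    paired two-sided Wilcoxon signed-rank p (zero differences dropped) asks
    whether the neo-W haplotype has measurably diverged from the autosomal
    copies.  Fewer than 6 usable windows gives a null p with a warning.
    """
    rows = []
    for w in iter_windows(layout, chrom, size, step):
        if w.start < region_start:
            continue
        denom = (w.end - w.start) if not gm.includes_invariant else None
        if denom is not None and denom < min_sites:
            continue
        ha = [het_density(gm, s, w) for s in neow_females]
        hb = [het_density(gm, s, w) for s in wildtype]
        ha = [h for h in ha if h is not None]
        hb = [h for h in hb if h is not None]
        if len(ha) < 2 or len(hb) < 2:
            continue
        rows.append((chrom, w.start, w.end, float(np.mean(ha)),
                     float(np.mean(hb))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "het_neow",
                                     "het_wildtype"])
    if len(df) < 6:
        import warnings
        warnings.warn(f"only {len(df)} usable windows; Wilcoxon p not "
                      "computed")
        return DivergenceReport(df, None, len(df))
    test = wilcoxon_signed_rank(df.het_neow.values, df.het_wildtype.values)
    return DivergenceReport(df, test, len(df))


# ---------------------------------------------------------------------------
# dating


def years_to_generations(years: float, generations_per_year: float = 12.0
                         ) -> float:
    return years * generations_per_year


def generations_to_years(generations: float,
                         generations_per_year: float = 12.0) -> float:
    return generations / generations_per_year


@dataclass
class RootAge:
    generations: float | None
    years: float | None
    pi: float | None
    mu: float
    generations_per_year: float


def root_age(pi: float | None, mu: float,
             generations_per_year: float = 12.0) -> RootAge:
    """Moment estimate of the neo-W root age from haploid diversity.

    Under a star genealogy every pair of neo-W copies diverges for 2T
    generations, so T = pi / (2 mu); years follow from the generations-
    per-year conversion.  Returns null fields when pi is null.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if pi is None:
        return RootAge(None, None, None, mu, generations_per_year)
    gen = pi / (2.0 * mu)
    return RootAge(gen, generations_to_years(gen, generations_per_year),
                   pi, mu, generations_per_year)
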
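"""Sliding-window diversity and differentiation statistics.

pi is the mean per-site expected mismatch among alleles sampled without
replacement within a population; d_XY the mean per-site cross-population
mismatch probability; FST the Hudson estimator 1 - pi_within/d_XY computed
as a ratio of window averages.  For variants-only genotype matrices,
positions without a record are taken as genotyped and invariant, so
per-base denominators use the window span; matrices that include invariant
records use their per-window record counts instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenomeLayout, GenotypeMatrix, Window, iter_windows


@dataclass
class WindowStat:
    window: Window
    statistic: str
    value: float | None
    populations: tuple
    n_sites: int
    passed_min_sites: bool = True


def _pairs(n: np.ndarray) -> np.ndarray:
    return n * (n - 1) / 2.0


def _site_pi(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pi from allele-count rows; returns (pi, usable mask)."""
    n = counts.sum(axis=1)
    usable = n >= 2
    same = np.zeros(len(counts))
    same[usable] = np.sum(_pairs(counts[usable]), axis=1) / \
        _pairs(n[usable])
    return 1.0 - same, usable


def _site_dxy(cx: np.ndarray, cy: np.ndarray) -> tuple[np.ndarray,
                                                       np.ndarray]:
    nx, ny = cx.sum(axis=1), cy.sum(axis=1)
    usable = (nx >= 1) & (ny >= 1)
    match = np.zeros(len(cx))
    match[usable] = np.sum(cx[usable] * cy[usable], axis=1) / \
        (nx[usable] * ny[usable])
    return 1.0 - match, usable


def _window_denominator(gm: GenotypeMatrix, window: Window,
                        n_records: int) -> int:
    return n_records if gm.includes_invariant else window.end - window.start


def window_diversity(gm: GenotypeMatrix, populations: dict[str, list],
                     window: Window) -> dict:
    """pi per population and d_XY / Hudson FST per population pair in one
    window.  Missing calls are excluded per site; a window with zero usable
    sites yields None values rather than NaN."""
    sl = gm.site_slice(window.chrom, window.start, window.end)
    idx = {p: gm.sample_index(s) for p, s in populations.items()}
    counts = {p: gm.allele_counts(i)[sl] for p, i in idx.items()}
    nrec = sl.stop - sl.start
    denom = _window_denominator(gm, window, nrec)
    out: dict = {"pi": {}, "dxy": {}, "fst": {}, "n_sites": nrec}
    pi_sums = {}
    for p, c in counts.items():
        pi, use = _site_pi(c)
        pi_sums[p] = pi[use].sum()
        out["pi"][p] = None if denom == 0 else pi_sums[p] / denom
    names = list(populations)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            dxy, use = _site_dxy(counts[a], counts[b])
            dxy_sum = dxy[use].sum()
            out["dxy"][(a, b)] = None if denom == 0 else dxy_sum / denom
            within = 0.5 * (pi_sums[a] + pi_sums[b])
            out["fst"][(a, b)] = None if dxy_sum == 0 else \
                1.0 - within / dxy_sum
    return out


def het_density(gm: GenotypeMatrix, sample: str, window: Window) -> float | None:
    """Heterozygous calls per genotyped site for one sample in a window."""
    j = gm.sample_index([sample])[0]
    sl = gm.site_slice(window.chrom, window.start, window.end)
    gt = gm.gt[sl, j, :]
    half = (gt[:, 0] == -1) != (gt[:, 1] == -1)
    if np.any(half):
        raise ValueError(f"sample {sample!r} has haploid-coded calls; "
                         "het_density requires diploid genotypes")
    called = ~np.any(gt == -1, axis=1)
    if gm.includes_invariant:
        denom = int(called.sum())
    else:
        denom = (window.end - window.start) - int((~called).sum())
    if denom <= 0:
        return None
    het = int(np.sum(called & (gt[:, 0] != gt[:, 1])))
    return het / denom


def genome_scan(gm: GenotypeMatrix, populations: dict[str, list],
                layout: GenomeLayout, statistic: str, size: int = 100_000,
                step: int = 20_000, min_sites: int = 20_000,
                chroms=None, start: int | None = None,
                end: int | None = None) -> pd.DataFrame:
    """Windowed scan of one statistic over the genome.

    ``statistic`` is one of pi / dxy / fst / het.  Windows whose per-base
    denominator falls below ``min_sites`` are emitted with a null value and
    ``pass_min_sites=False`` (mirroring the "fewer than 20,000 genotyped
    sites" rule).  ``start``/``end`` restrict the scanned region, e.g. the
    distal colinear portion of chr15.
    """
    if statistic not in {"pi", "dxy", "fst", "het"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    for pop, ids in populations.items():
        gm.sample_index(ids)  # raises on unknown samples
    rows = []
    for chrom in (chroms or layout.chromosomes):
        for w in iter_windows(layout, chrom, size, step):
            if start is not None and w.start < start:
                continue
            if end is not None and w.end > end:
                continue
            sl = gm.site_slice(chrom, w.start, w.end)
            nrec = sl.stop - sl.start
            denom = _window_denominator(gm, w, nrec)
            ok = denom >= min_sites
            if statistic == "het":
                for pop, ids in populations.items():
                    for s in ids:
                        v = het_density(gm, s, w) if ok else None
                        rows.append((chrom, w.start, w.end, nrec, "het",
                                     f"{pop}:{s}", v, ok))
                continue
            res = window_diversity(gm, populations, w) if ok else None
            if statistic == "pi":
                for pop in populations:
                    v = res["pi"][pop] if ok else None
                    rows.append((chrom, w.start, w.end, nrec, "pi", pop, v,
                                 ok))
            else:
                names = list(populations)
                for i, a in enumerate(names):
                    for b in names[i + 1:]:
                        v = res[statistic][(a, b)] if ok else None
                        rows.append((chrom, w.start, w.end, nrec, statistic,
                                     f"{a}~{b}", v, ok))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "stat", "pops", "value",
                                       "pass_min_sites"])


def fourfold_pi(gm: GenotypeMatrix, degmap: pd.DataFrame, population,
                regions=None) -> float | None:
    """Mean per-site pi over classified 4-fold degenerate positions.

    The denominator counts every classified 4-fold position (variant or
    invariant); positions with no variant record contribute zero.
    """
    idx = gm.sample_index(population)
    four = degmap[degmap.cls == "four-fold"]
    if regions is not None:
        from .pnps import _in_regions
        four = four[_in_regions(four.chrom.values, four.pos.values, regions)]
    if len(four) == 0:
        return None
    counts = gm.allele_counts(idx)
    total = 0.0
    n_classified = 0
    for chrom, sub in four.groupby("chrom", sort=False):
        rec = np.flatnonzero(gm.chrom == chrom)
        rec_pos = gm.pos[rec]
        w = np.searchsorted(rec_pos, sub.pos.values)
        hit = (w < len(rec_pos)) & \
            (rec_pos[np.minimum(w, len(rec_pos) - 1)] == sub.pos.values)
        n_classified += len(sub)
        if hit.any():
            pi, use = _site_pi(counts[rec[w[hit]]])
            total += pi[use].sum()
    return total / n_classified


def depth_genotype(window_depths, band: float = 0.2) -> str | None:
    """Copy-number call from normalised per-window read depths.

    The median over windows is classified by the nearest anchor among
    {1.0 -> "two copies", 0.5 -> "one copy", 0.0 -> "zero copies"}; a call
    is made only strictly within ``band`` of an anchor, otherwise
    "no-call".  Depths are expected to be normalised by the sample's
    genome-wide mean.
    """
    d = np.asarray(window_depths, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return None
    med = float(np.median(d))
    anchors = {1.0: "two copies", 0.5: "one copy", 0.0: "zero copies"}
    best = min(anchors, key=lambda a: abs(med - a))
    if abs(med - best) >= band:
        return "no-call"
    return anchors[best]


def write_scan(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a scan table with a commented header naming the parameters."""
    with open(path, "w") as fh:
        fh.write("# neowsweep window scan; FST estimator: Hudson "
                 "(1 - pi_within/dxy), ratio of window sums\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)
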
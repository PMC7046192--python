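"""Per-window haplotype cluster assignment ("chromosome painting") of the
supergene against three reference allele groups.

Each 20-kb window is treated separately (limiting the reach of phasing
switch errors); a haplotype joins a reference group only if its average
distance to that group's members is strictly less than 80% of the mean of
its average distances to the other two groups, otherwise it stays
unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenomeLayout, HaplotypeSet, Window, iter_windows

CLUSTERS = ("dorippus", "chrysippus", "orientis")
UNASSIGNED = "unassigned"
MISSING_STATE = "missing"


def hap_distance(hap_a: np.ndarray, hap_b: np.ndarray,
                 min_sites: int = 100) -> float | None:
    """Proportion of differing alleles over pairwise-complete sites.

    Returns None when fewer than ``min_sites`` sites are complete in both
    haplotypes.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n < min_sites:
        return None
    return float(np.sum(a[ok] != b[ok]) / n)


def _mean_group_distance(hap: np.ndarray, group: np.ndarray,
                         min_sites: int) -> float | None:
    ds = [hap_distance(hap, g, min_sites) for g in group]
    ds = [d for d in ds if d is not None]
    return None if not ds else float(np.mean(ds))


def assign_cluster(hap: np.ndarray, references: dict[str, np.ndarray],
                   ratio: float = 0.8, min_sites: int = 100) -> str:
    """Assign one haplotype (alleles over a window's sites) to a reference
    group, or leave it unassigned.

    Let d_g be the mean distance to members of group g.  The haplotype is
    assigned to the closest group g* iff d_g* < ratio * mean(d of the
    other two groups), with strict inequality.  Any group without a
    computable distance leaves the haplotype unassigned.
    """
    d = {}
    for name, group in references.items():
        m = _mean_group_distance(hap, group, min_sites)
        if m is None:
            return UNASSIGNED
        d[name] = m
    names = list(d)
    best = min(names, key=lambda n: d[n])
    others = [d[n] for n in names if n != best]
    # strict inequality, guarded against float noise at the exact boundary
    if d[best] < ratio * float(np.mean(others)) - 1e-12:
        return best
    return UNASSIGNED


@dataclass
class PaintedChromosome:
    """Per-window cluster calls for the two haplotype tracks of one sample."""

    sample: str
    windows: list[Window]
    calls: list[tuple[str, str]]            # one (hap0, hap1) per window
    genotype: tuple[str, str] | None = None  # majority call per track
    mosaic: tuple[bool, bool] = (False, False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, (c0, c1) in zip(self.windows, self.calls):
            for h, c in enumerate((c0, c1)):
                rows.append((self.sample, h, w.chrom, w.start, w.end, c))
        return pd.DataFrame(rows, columns=["sample", "hap", "chrom", "start",
                                           "end", "cluster"])


def paint_chromosome(sample: str, haps: HaplotypeSet,
                     references: dict[str, HaplotypeSet],
                     layout: GenomeLayout, chrom: str,
                     region: tuple[int, int] | None = None,
                     window_size: int = 20_000, ratio: float = 0.8,
                     min_sites: int = 100) -> PaintedChromosome:
    """Paint both phased haplotypes of ``sample`` window by window.

    ``haps`` must contain rows labelled '<sample>_h0' and '<sample>_h1'.
    The supergene genotype call per track is the majority cluster over
    windows inside ``region`` (default: all painted windows); a track with
    more than one cluster among its window calls is flagged mosaic.
    """
    labels = [f"{sample}_h0", f"{sample}_h1"]
    try:
        rows = [haps.labels.index(l) for l in labels]
    except ValueError:
        raise KeyError(f"sample {sample!r} not phased in haplotype set")
    windows = iter_windows(layout, chrom, window_size, window_size)
    if region is not None:
        windows = [w for w in windows
                   if w.start >= region[0] and w.end <= region[1]]
    calls = []
    for w in windows:
        sub = haps.window_view(w)
        refsub = {name: ref.window_view(w)
                  for name, ref in references.items()}
        pair = []
        for r in rows:
            hap = sub[r]
            if np.all(hap < 0) or hap.size == 0:
                pair.append(MISSING_STATE)
                continue
            pair.append(assign_cluster(hap, refsub, ratio, min_sites))
        calls.append(tuple(pair))
    genotype = []
    mosaic = []
    for h in (0, 1):
        track = [c[h] for c in calls
                 if c[h] not in (UNASSIGNED, MISSING_STATE)]
        if not track:
            genotype.append(MISSING_STATE)
            mosaic.append(False)
            continue
        vals, counts = np.unique(track, return_counts=True)
        genotype.append(str(vals[np.argmax(counts)]))
        mosaic.append(len(vals) > 1)
    return PaintedChromosome(sample, windows, calls,
                             tuple(genotype), tuple(mosaic))


def paint_cohort(samples, haps: HaplotypeSet,
                 references: dict[str, HaplotypeSet], layout: GenomeLayout,
                 chrom: str, region=None, **kw) -> pd.DataFrame:
    """Long-format painting table for a set of samples (tile-plot ready)."""
    frames = []
    for s in samples:
        frames.append(paint_chromosome(s, haps, references, layout, chrom,
                                       region=region, **kw).to_frame())
    return pd.concat(frames, ignore_index=True)
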
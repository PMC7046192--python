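"""Core data containers, file readers/writers and windowing conventions.

All coordinates are 0-based half-open internally; VCF and GFF positions
(1-based) are converted at the I/O boundary.  Missing genotype calls are a
first-class state (allele index -1) and are propagated, never imputed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SEXES = {"F": "female", "M": "male", "female": "female", "male": "male",
         "U": "unknown", "unknown": "unknown"}
PHENO_SCORES = {0.0, 0.5, 1.0}


class ParseError(ValueError):
    """Raised when an input file does not conform to its format."""


# ---------------------------------------------------------------------------
# Genome layout and windows


@dataclass(frozen=True)
class ScaffoldSpan:
    scaffold: str
    start: int
    end: int


@dataclass
class GenomeLayout:
    """Mapping of pseudo-chromosomes to lengths and ordered scaffold spans."""

    lengths: dict[str, int]
    spans: dict[str, list[ScaffoldSpan]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, spans in self.spans.items():
            prev = 0
            for s in spans:
                if s.start < prev or s.end <= s.start:
                    raise ValueError(
                        f"scaffold spans on {chrom} overlap or are unordered")
                prev = s.end
            if spans and spans[-1].end != self.lengths[chrom]:
                raise ValueError(
                    f"{chrom}: length {self.lengths[chrom]} != last span end "
                    f"{spans[-1].end}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @classmethod
    def from_table(cls, path: str | os.PathLike) -> "GenomeLayout":
        """Read a tab-separated layout: chrom, length[, scaffold, start, end]."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if "chrom" not in df.columns or "length" not in df.columns:
            raise ParseError(f"{path}: need columns 'chrom' and 'length'")
        lengths = {}
        spans: dict[str, list[ScaffoldSpan]] = {}
        for _, row in df.iterrows():
            lengths[str(row["chrom"])] = int(row["length"])
            if "scaffold" in df.columns and not pd.isna(row.get("scaffold")):
                spans.setdefault(str(row["chrom"]), []).append(
                    ScaffoldSpan(str(row["scaffold"]),
                                 int(row["start"]), int(row["end"])))
        return cls(lengths, spans)

    def to_table(self, path: str | os.PathLike) -> None:
        rows = []
        for chrom, length in self.lengths.items():
            if self.spans.get(chrom):
                for s in self.spans[chrom]:
                    rows.append((chrom, length, s.scaffold, s.start, s.end))
            else:
                rows.append((chrom, length, "", "", ""))
        pd.DataFrame(rows, columns=["chrom", "length", "scaffold", "start",
                                    "end"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval; the unit of every sliding statistic."""

    chrom: str
    start: int
    end: int
    n_sites: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad window bounds [{self.start}, {self.end})")


def iter_windows(layout: GenomeLayout, chrom: str, size: int = 100_000,
                 step: int = 20_000) -> list[Window]:
    """Full-size sliding windows over a chromosome.

    Windows start at 0, step, 2*step, ...; a trailing partial window is not
    emitted, matching fixed-width windowed scans.  ``size > length`` yields
    an empty list.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    length = layout.lengths[chrom]
    out = []
    start = 0
    while start + size <= length:
        out.append(Window(chrom, start, start + size))
        start += step
    return out


# ---------------------------------------------------------------------------
# Genotype matrix


@dataclass
class FilterPolicy:
    """Per-call genotype filter.

    ``min_dp`` applies to every call.  ``min_gq`` applies only to
    heterozygous and alternate-homozygous calls; reference-homozygous calls
    are retained regardless of quality (the asymmetric rule used for the
    resequencing genotypes).  Calls lacking DP/GQ tags pass by default
    (``absent_passes``).
    """

    min_dp: int = 8
    min_gq: int = 20
    absent_passes: bool = True

    @classmethod
    def permissive(cls) -> "FilterPolicy":
        return cls(min_dp=0, min_gq=0)


class GenotypeMatrix:
    """Diploid genotypes at variant sites for a set of samples.

    Attributes
    ----------
    samples : list of sample ids (column order)
    chrom : (n_sites,) array of chromosome names
    pos : (n_sites,) int array, 0-based positions, strictly increasing
        within each chromosome
    ref, alt : per-site reference base and list of alternate alleles
    gt : (n_sites, n_samples, 2) int8 allele indices, -1 = missing
    dp, gq : (n_sites, n_samples) int32 per-call depth / quality (-1 absent)
    includes_invariant : whether invariant sites are present as records.
        When False (the usual variants-only matrix), per-base denominators
        assume unrecorded positions are genotyped and invariant.
    """

    def __init__(self, samples, chrom, pos, ref, alt, gt, dp=None, gq=None,
                 includes_invariant=False):
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alt = [list(a) for a in alt]
        self.gt = np.asarray(gt, dtype=np.int8)
        n = len(self.pos)
        k = len(self.samples)
        if self.gt.shape != (n, k, 2):
            raise ValueError("gt shape mismatch")
        self.dp = (np.full((n, k), -1, np.int32) if dp is None
                   else np.asarray(dp, dtype=np.int32))
        self.gq = (np.full((n, k), -1, np.int32) if gq is None
                   else np.asarray(gq, dtype=np.int32))
        self.includes_invariant = includes_invariant
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic queries ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None

    def site_slice(self, chrom: str, start: int | None = None,
                   end: int | None = None) -> slice:
        """Index range of sites on ``chrom`` within [start, end)."""
        mask = np.flatnonzero(self.chrom == chrom)
        if mask.size == 0:
            return slice(0, 0)
        lo, hi = mask[0], mask[-1] + 1
        p = self.pos[lo:hi]
        a = lo + (np.searchsorted(p, start) if start is not None else 0)
        b = lo + (np.searchsorted(p, end) if end is not None else len(p))
        return slice(int(a), int(b))

    def is_missing(self) -> np.ndarray:
        return np.any(self.gt == MISSING, axis=2)

    def is_het(self) -> np.ndarray:
        ok = ~self.is_missing()
        return ok & (self.gt[:, :, 0] != self.gt[:, :, 1])

    def alt_dosage(self) -> np.ndarray:
        """(n_sites, n_samples) count of non-reference alleles; -1 missing."""
        d = np.sum(self.gt > 0, axis=2).astype(np.int8)
        d[self.is_missing()] = MISSING
        return d

    def allele_counts(self, sample_idx=None, n_alleles: int | None = None
                      ) -> np.ndarray:
        """(n_sites, n_alleles) counts of each allele among non-missing calls."""
        gt = self.gt if sample_idx is None else self.gt[:, sample_idx, :]
        if n_alleles is None:
            n_alleles = int(max(2, max((1 + len(a)) for a in self.alt))) \
                if self.alt else 2
        out = np.zeros((gt.shape[0], n_alleles), dtype=np.int32)
        for a in range(n_alleles):
            out[:, a] = np.sum(gt == a, axis=(1, 2))
        return out

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.chrom, self.pos, self.ref,
            self.alt, self.gt[:, idx, :], self.dp[:, idx], self.gq[:, idx],
            self.includes_invariant)


# ---------------------------------------------------------------------------
# VCF I/O


def _apply_filter(gm: GenotypeMatrix, policy: FilterPolicy) -> None:
    """Set calls failing the policy to MISSING, in place."""
    called = ~gm.is_missing()
    dp_known = gm.dp >= 0
    gq_known = gm.gq >= 0
    if policy.absent_passes:
        fail_dp = dp_known & (gm.dp < policy.min_dp)
    else:
        fail_dp = ~dp_known | (gm.dp < policy.min_dp)
    nonref = called & np.any(gm.gt != 0, axis=2)
    if policy.absent_passes:
        fail_gq = gq_known & (gm.gq < policy.min_gq)
    else:
        fail_gq = ~gq_known | (gm.gq < policy.min_gq)
    kill = called & (fail_dp | (nonref & fail_gq))
    gm.gt[kill] = MISSING


def load_genotypes(path: str | os.PathLike,
                   policy: FilterPolicy | None = None) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`, applying the call filter.

    Depth-failing calls become MISSING; heterozygous / alternate-homozygous
    calls additionally require GQ >= ``policy.min_gq``.  Reference-homozygous
    calls are kept whatever their quality.
    """
    from cyvcf2 import VCF

    policy = policy or FilterPolicy()
    try:
        vcf = VCF(str(path))
    except Exception as e:  # htslib raises bare exceptions on bad files
        raise ParseError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)
    chrom, pos, ref, alt, gts, dps, gqs = [], [], [], [], [], [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(list(v.ALT))
        g = np.array(v.genotypes, dtype=np.int32)[:, :2]
        gts.append(g.astype(np.int8))
        dp = v.format("DP")
        gq = v.format("GQ")
        n = len(samples)
        dps.append(np.full(n, -1, np.int32) if dp is None
                   else np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
        gqs.append(np.full(n, -1, np.int32) if gq is None
                   else np.where(gq[:, 0] < 0, -1, gq[:, 0]).astype(np.int32))
    if not pos:
        raise ParseError(f"{path}: no variant records")
    gm = GenotypeMatrix(samples, chrom, pos, ref, alt,
                        np.stack(gts), np.stack(dps), np.stack(gqs))
    _apply_filter(gm, policy)
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike,
              layout: GenomeLayout | None = None,
              header_meta: dict | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF (GT:DP:GQ)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=neowsweep\n")
        for k, v in (header_meta or {}).items():
            fh.write(f"##{k}={v}\n")
        if layout is not None:
            for c, ln in layout.lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(gm.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            alt = ",".join(gm.alt[i]) if gm.alt[i] else "."
            cells = []
            for j in range(len(gm.samples)):
                a, b = gm.gt[i, j]
                g = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
                dp = "." if gm.dp[i, j] < 0 else str(gm.dp[i, j])
                gq = "." if gm.gq[i, j] < 0 else str(gm.gq[i, j])
                cells.append(f"{g}:{dp}:{gq}")
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t{alt}"
                     f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata


REQUIRED_SAMPLE_COLS = ["sample", "sex", "population"]
OPTIONAL_SAMPLE_COLS = ["pheno_A", "pheno_B", "pheno_C", "infected",
                        "neoW", "matriline"]


def load_samples(path: str | os.PathLike | io.IOBase) -> pd.DataFrame:
    """Load and validate the tab-separated per-sample metadata table.

    Columns: sample, sex (F/M/U), population, pheno_A/B/C in {0, 0.5, 1}
    or blank, infected (yes/no/unknown), neoW (yes/no/unknown), matriline.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    for col in REQUIRED_SAMPLE_COLS:
        if col not in df.columns:
            raise ParseError(f"sample table missing column {col!r}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ParseError(f"duplicate sample id {dup!r}")
    df["sex"] = df["sex"].map(lambda s: SEXES.get(str(s), None))
    if df["sex"].isna().any():
        raise ParseError("sex must be one of F/M/U (or female/male/unknown)")
    for col in ("pheno_A", "pheno_B", "pheno_C"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & ~vals.isin([0.0, 0.5, 1.0])
            if bad.any():
                raise ParseError(
                    f"{col}: phenotype scores must be 0, 0.5 or 1 "
                    f"(got {vals[bad].iloc[0]})")
            df[col] = vals
    for col in ("infected", "neoW"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.lower().map(
                {"yes": "yes", "no": "no", "true": "yes", "false": "no",
                 "unknown": "unknown", "nan": "unknown"})
    return df.set_index("sample", drop=False)


def write_samples(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genes (GFF3) and FASTA


def load_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene features from a GFF3 into a frame with 0-based coordinates.

    Returns columns: gene_id, chrom, start, end, strand.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GFF columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            gid = None
            for kv in attrs.split(";"):
                if kv.startswith("ID=") or kv.startswith("Parent="):
                    gid = kv.split("=", 1)[1]
                    break
            if ftype == "gene":
                rows.append((gid, chrom, int(start) - 1, int(end), strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    return df


def write_gff(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(f"{g.chrom}\tneowsweep\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")


def write_fasta(records: dict[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def load_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Haplotype alignments (variant-site columns)


class HaplotypeSet:
    """Aligned haplotypes over a shared set of variant-site columns.

    ``alleles`` is (n_haps, n_sites) int8 with allele indices and -1 for
    missing.  Used by clustering, neo-W reconstruction and distance matrices.
    """

    def __init__(self, labels, chrom, pos, alleles):
        self.labels = list(labels)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.labels), len(self.pos)):
            raise ValueError("alleles shape mismatch")

    @property
    def n_haps(self) -> int:
        return len(self.labels)

    def site_slice(self, chrom: str, start=None, end=None) -> slice:
        mask = np.flatnonzero(self.chrom == chrom)
        if mask.size == 0:
            return slice(0, 0)
        lo, hi = mask[0], mask[-1] + 1
        p = self.pos[lo:hi]
        a = lo + (np.searchsorted(p, start) if start is not None else 0)
        b = lo + (np.searchsorted(p, end) if end is not None else len(p))
        return slice(int(a), int(b))

    def window_view(self, window: Window) -> np.ndarray:
        return self.alleles[:, self.site_slice(window.chrom, window.start,
                                               window.end)]
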
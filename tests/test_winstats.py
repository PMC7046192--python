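"""Window statistics against brute-force oracles, plus the copy-number
depth genotyper."""

import numpy as np
import pytest

from neowsweep.io_core import GenomeLayout, GenotypeMatrix, Window
from neowsweep import winstats
from neowsweep.pnps import classify_degeneracy
import pandas as pd


def _gm(gt, pos=None, samples=None, includes_invariant=True):
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples, _ = gt.shape
    pos = np.arange(n_sites) if pos is None else np.asarray(pos)
    samples = samples or [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, ["c"] * n_sites, pos, ["A"] * n_sites,
                          [["T"]] * n_sites, gt,
                          includes_invariant=includes_invariant)


def oracle_pi(gt_pop):
    """Brute force: average mismatch over all allele pairs per site."""
    vals = []
    for site in gt_pop:
        alleles = [a for call in site for a in call if a >= 0]
        n = len(alleles)
        if n < 2:
            continue
        mm = sum(alleles[i] != alleles[j]
                 for i in range(n) for j in range(i + 1, n))
        vals.append(mm / (n * (n - 1) / 2))
    return vals


def oracle_dxy(gt_a, gt_b):
    vals = []
    for sa, sb in zip(gt_a, gt_b):
        aa = [x for call in sa for x in call if x >= 0]
        bb = [x for call in sb for x in call if x >= 0]
        if not aa or not bb:
            continue
        mm = sum(x != y for x in aa for y in bb)
        vals.append(mm / (len(aa) * len(bb)))
    return vals


class TestWindowDiversity:
    def test_identical_pairs_zero_pi(self):
        gt = np.tile([[0, 1], [0, 1]], (5, 1, 1))
        gm = _gm(gt)
        w = Window("c", 0, 5)
        res = winstats.window_diversity(gm, {"p": gm.samples}, w)
        # heterozygous but identical genotypes still segregate alleles
        assert res["pi"]["p"] == pytest.approx(np.mean(oracle_pi(gt)))

    def test_fixed_difference(self):
        # 3 fixed differences among 100 genotyped sites
        gt = np.zeros((3, 4, 2), np.int8)
        gt[:, 2:, :] = 1
        gm = _gm(gt, pos=[10, 40, 70], includes_invariant=False)
        w = Window("c", 0, 100)
        res = winstats.window_diversity(
            gm, {"a": ["S0", "S1"], "b": ["S2", "S3"]}, w)
        assert res["dxy"][("a", "b")] == pytest.approx(0.03)
        assert res["fst"][("a", "b")] == pytest.approx(1.0)

    def test_random_matrix_matches_oracle(self, rng):
        for _ in range(20):
            gt = rng.integers(0, 2, size=(30, 4, 2)).astype(np.int8)
            gt[rng.random((30, 4)) < 0.15] = -1
            gm = _gm(gt)
            w = Window("c", 0, 30)
            pops = {"a": ["S0", "S1"], "b": ["S2", "S3"]}
            res = winstats.window_diversity(gm, pops, w)
            ia, ib = [0, 1], [2, 3]
            exp_pi = np.sum(oracle_pi(gt[:, ia])) / 30
            exp_dxy = np.sum(oracle_dxy(gt[:, ia], gt[:, ib])) / 30
            assert res["pi"]["a"] == pytest.approx(exp_pi, abs=1e-12)
            assert res["dxy"][("a", "b")] == pytest.approx(exp_dxy,
                                                           abs=1e-12)

    def test_self_dxy_identity(self, rng):
        """dXY of a population against itself equals pi * (n-1)/n — the
        with-replacement vs without-replacement correction."""
        gt = rng.integers(0, 2, size=(25, 5, 2)).astype(np.int8)
        gm = _gm(gt)
        w = Window("c", 0, 25)
        pops = {"a": gm.samples, "b": gm.samples}
        res = winstats.window_diversity(gm, pops, w)
        n = 10  # sampled alleles
        assert res["pi"]["a"] == pytest.approx(
            res["dxy"][("a", "b")] * n / (n - 1), rel=1e-9)

    def test_identical_populations_fst_near_zero(self, rng):
        vals = []
        for _ in range(60):
            gt = rng.integers(0, 2, size=(200, 8, 2)).astype(np.int8)
            gm = _gm(gt)
            w = Window("c", 0, 200)
            res = winstats.window_diversity(
                gm, {"a": gm.samples[:4], "b": gm.samples[4:]}, w)
            f = res["fst"][("a", "b")]
            if f is not None:
                vals.append(abs(f))
        assert np.mean(vals) < 0.02

    def test_pi_invariances(self, rng):
        gt = rng.integers(0, 2, size=(40, 6, 2)).astype(np.int8)
        gm = _gm(gt)
        w = Window("c", 0, 40)
        base = winstats.window_diversity(gm, {"p": gm.samples}, w)["pi"]["p"]
        # sample reordering
        perm = list(np.array(gm.samples)[[3, 1, 5, 0, 2, 4]])
        assert winstats.window_diversity(gm, {"p": perm}, w)["pi"]["p"] == \
            pytest.approx(base)
        # allele relabeling 0 <-> 1
        flipped = _gm(np.where(gt >= 0, 1 - gt, gt))
        assert winstats.window_diversity(flipped, {"p": gm.samples},
                                         w)["pi"]["p"] == pytest.approx(base)

    def test_empty_window_is_null(self):
        gm = _gm(np.zeros((1, 4, 2), np.int8), pos=[500])
        res = winstats.window_diversity(gm, {"p": gm.samples},
                                        Window("c", 0, 10))
        assert res["pi"]["p"] is None


class TestHetDensity:
    def test_arithmetic(self):
        gt = np.zeros((5, 1, 2), np.int8)
        gt[:, 0, 1] = 1  # five heterozygous calls
        gm = _gm(gt, pos=[1, 2, 3, 4, 5], includes_invariant=False)
        w = Window("c", 0, 100_000)
        assert winstats.het_density(gm, "S0", w) == pytest.approx(5e-5)

    def test_haploid_coded_rejected(self):
        gt = np.zeros((2, 1, 2), np.int8)
        gt[0, 0, 1] = -1
        gm = _gm(gt)
        with pytest.raises(ValueError, match="haploid"):
            winstats.het_density(gm, "S0", Window("c", 0, 10))

    def test_equals_two_hap_pi(self, default_cohort):
        """A sample's het density is the pi of its two true haplotypes."""
        _, _, res = default_cohort
        gm = res.gm
        s = res.truth.samples[0]
        w = Window("chr15", 0, 100_000)
        hs = res.truth.haplotype_set("chr15", gm)
        i0 = hs.labels.index(f"{s}_h0")
        i1 = hs.labels.index(f"{s}_h1")
        sl = hs.site_slice("chr15", 0, 100_000)
        diffs = np.sum(hs.alleles[i0, sl] != hs.alleles[i1, sl])
        assert winstats.het_density(gm, s, w) == pytest.approx(
            diffs / 100_000)


class TestGenomeScan:
    def test_row_count_and_min_sites(self):
        layout = GenomeLayout({"c": 1_000_000})
        gt = np.zeros((4, 3, 2), np.int8)
        gt[:, 1, 1] = 1
        gm = _gm(gt, pos=[100, 200, 300, 400], includes_invariant=False)
        df = winstats.genome_scan(gm, {"p": gm.samples}, layout, "pi",
                                  min_sites=20_000)
        assert len(df) == 46
        assert df.pass_min_sites.all()  # span denominator = 100 kb
        strict = winstats.genome_scan(gm, {"p": gm.samples}, layout, "pi",
                                      min_sites=200_000)
        assert not strict.pass_min_sites.any()
        assert strict.value.isna().all()

    def test_region_bound(self):
        layout = GenomeLayout({"c": 1_000_000})
        gm = _gm(np.zeros((1, 2, 2), np.int8), pos=[5], includes_invariant=False)
        df = winstats.genome_scan(gm, {"p": gm.samples}, layout, "pi",
                                  min_sites=0, start=600_000)
        assert df.start.min() >= 600_000

    def test_unknown_population_member(self):
        layout = GenomeLayout({"c": 1000})
        gm = _gm(np.zeros((1, 2, 2), np.int8))
        with pytest.raises(KeyError):
            winstats.genome_scan(gm, {"p": ["nope"]}, layout, "pi")

    def test_sweep_elevates_chr15_fst(self, default_cohort, cohort_groups):
        """After the sweep, contact-zone females are differentiated from an
        allopatric population more on chr15 than on the control autosome."""
        params, _, res = default_cohort
        pops = {"cz": cohort_groups["carriers"],
                "allo": cohort_groups["by_pop"]["chrysippus"]}
        layout = res.layout
        out = {}
        for chrom in ("chr15", "chr2"):
            df = winstats.genome_scan(res.gm, pops, layout, "fst",
                                      size=100_000, step=100_000,
                                      min_sites=0, chroms=[chrom])
            out[chrom] = df.value.astype(float).mean()
        assert out["chr15"] > out["chr2"]


class TestFourfoldPi:
    def _toy(self):
        # two glycine-codon genes (GGA GGC ...): every third base four-fold
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        seq = np.array([code[b] for b in "GGAGGCGGTGGG"], np.uint8)
        genes = pd.DataFrame([("g1", "c", 0, 12, "+")],
                             columns=["gene_id", "chrom", "start", "end",
                                      "strand"])
        return {"c": seq}, genes

    def test_glycine_third_positions(self):
        refseq, genes = self._toy()
        gm = _gm(np.zeros((1, 3, 2), np.int8), pos=[500])
        dm = classify_degeneracy(refseq, genes, gm)
        four = set(dm[dm.cls == "four-fold"].pos)
        assert four == {2, 5, 8, 11}

    def test_no_polymorphism_and_hand_enumeration(self):
        refseq, genes = self._toy()
        # one variant at four-fold position 5: genotypes 0/0, 0/1, 1/1
        gt = np.array([[[0, 0], [0, 1], [1, 1]]], np.int8)
        gm = _gm(gt, pos=[5])
        dm = classify_degeneracy(refseq, genes, gm)
        # hand enumeration: counts (3 ref, 3 alt) of 6 alleles ->
        # pi = 1 - (3*2 + 3*2)/(6*5) = 0.6 at one site of four classified
        assert winstats.fourfold_pi(gm, dm, gm.samples) == \
            pytest.approx(0.6 / 4)
        mono = _gm(np.zeros((1, 3, 2), np.int8), pos=[5])
        assert winstats.fourfold_pi(mono, classify_degeneracy(
            refseq, genes, mono), mono.samples) == 0.0


class TestDepthGenotype:
    @pytest.mark.parametrize("median,expect", [
        (0.98, "two copies"), (0.5, "one copy"), (0.05, "zero copies"),
        (0.3, "no-call"), (0.75, "no-call")])
    def test_anchors_and_band(self, median, expect):
        assert winstats.depth_genotype([median] * 11) == expect

    def test_empty_region(self):
        assert winstats.depth_genotype([]) is None
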
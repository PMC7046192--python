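"""The neo-W discovery chain: female-specific scan, diagnostic sites,
fragment-based haploid reconstruction, haploid diversity, divergence test
and moment dating."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_params
from neowsweep import neow, simulate as sim
from neowsweep.io_core import GenomeLayout, GenotypeMatrix
from neowsweep.simulate import FragmentSet


def _gm(gt, pos, samples, chrom="c"):
    gt = np.asarray(gt, np.int8)
    n = gt.shape[0]
    return GenotypeMatrix(samples, [chrom] * n, pos, ["A"] * n,
                          [["T"]] * n, gt)


class TestFemaleSpecificScan:
    def _toy(self):
        # 4 females + 2 males; site0: allele at 25% in females, absent in
        # males; site1: same but one male copy
        gt = np.zeros((2, 6, 2), np.int8)
        gt[0, 0, 1] = 1
        gt[0, 1, 1] = 1
        gt[1, 0, 1] = 1
        gt[1, 1, 1] = 1
        gt[1, 4, 1] = 1  # male copy
        samples = [f"F{i}" for i in range(4)] + ["M0", "M1"]
        return _gm(gt, [100, 200], samples), samples

    def test_threshold_and_male_absence(self):
        gm, samples = self._toy()
        layout = GenomeLayout({"c": 1000})
        df = neow.female_specific_scan(gm, samples[:4], samples[4:], layout,
                                       size=1000, step=1000)
        assert df["count"].sum() == 1  # only site0 qualifies

    def test_no_males_is_error(self):
        gm, samples = self._toy()
        with pytest.raises(ValueError, match="without males"):
            neow.female_specific_scan(gm, samples[:4], [],
                                      GenomeLayout({"c": 1000}))

    def test_counts_concentrate_on_chr15(self, default_cohort,
                                         cohort_groups):
        """Post-sweep, high-frequency female-specific mutations pile up on
        the fused chromosome and stay near zero on the control autosome.

        The outgroup-polarised mode is used: in a small focal deme, drift
        alone pushes rare variants past the frequency threshold, a floor
        that absence-in-allopatric-populations polarisation removes."""
        _, _, res = default_cohort
        s = res.samples
        outgroups = list(s[(s.population != "contact")
                           & (s.sex == "female")]["sample"])
        df = neow.female_specific_scan(res.gm, cohort_groups["females"],
                                       cohort_groups["males"], res.layout,
                                       outgroups=outgroups)
        per_chrom = df.groupby("chrom")["count"].sum()
        assert per_chrom["chr15"] >= 10 * max(per_chrom["chr2"], 1)
        # control autosome floor: < 5% of the chr15 signal
        assert per_chrom["chr2"] < 0.05 * per_chrom["chr15"]
        # the unpolarised scan still ranks chr15 far above the autosome
        plain = neow.female_specific_scan(
            res.gm, cohort_groups["females"], cohort_groups["males"],
            res.layout).groupby("chrom")["count"].sum()
        assert plain["chr15"] > 5 * plain["chr2"]


class TestDiagnosticSites:
    def _toy(self):
        # carriers C0,C1 het at sites 0 and 3; site 3 also appears in a
        # non-carrier; site 2 carrier-homozygous; site 4 not in all carriers
        samples = ["C0", "C1", "N0", "N1"]
        gt = np.zeros((5, 4, 2), np.int8)
        gt[0, 0, 1] = gt[0, 1, 1] = 1                     # qualifies
        gt[2, 0] = (1, 1)
        gt[2, 1, 1] = 1                                   # C0 homozygous
        gt[3, 0, 1] = gt[3, 1, 1] = 1
        gt[3, 2, 1] = 1                                   # leaks to N0
        gt[4, 0, 1] = 1                                   # only one carrier
        return _gm(gt, [10, 20, 30, 40, 50], samples), samples

    def test_exactly_one_qualifying_site(self):
        gm, samples = self._toy()
        d = neow.find_diagnostic_sites(gm, ["C0", "C1"], ["N0", "N1"])
        assert list(d.pos) == [10]
        assert neow.check_diagnostics(gm, d, ["N0", "N1"])

    def test_missing_non_carrier_policy(self):
        gm, samples = self._toy()
        gm.gt[0, 3] = (-1, -1)
        strict = neow.find_diagnostic_sites(gm, ["C0", "C1"], ["N0", "N1"])
        assert len(strict) == 0
        relaxed = neow.find_diagnostic_sites(gm, ["C0", "C1"], ["N0", "N1"],
                                             allow_missing_non_carriers=True)
        assert list(relaxed.pos) == [10]

    def test_precision_against_truth(self, default_cohort, cohort_groups,
                                     neow_chain):
        """>= 99% of reported diagnostic sites are genuinely borne by the
        fused haplotype in every carrier."""
        _, _, res = default_cohort
        carriers = cohort_groups["carriers"]
        d = neow_chain["diag"]
        assert len(d) >= 20
        fused = [set(res.truth.fused_hap_positions(s).tolist())
                 for s in carriers]
        on_all = set.intersection(*fused)
        hit = sum(int(p) in on_all for p in d.pos)
        assert hit / len(d) >= 0.99
        assert neow.check_diagnostics(res.gm, d,
                                      cohort_groups["non_carriers"])


def _toy_fragments(sample, frags):
    """FragmentSet from explicit (start, end, derived-positions) triples."""
    fs = FragmentSet()
    fs.frags[sample] = {"c": {
        "start": np.array([f[0] for f in frags], np.int64),
        "end": np.array([f[1] for f in frags], np.int64),
        "hap": np.zeros(len(frags), np.int64),
        "derived": [set(f[2]) for f in frags]}}
    return fs


class TestReconstruct:
    def _setup(self, n_support):
        # carrier het at diagnostic site 100 and linked SNP 140; one
        # non-carrier homozygous reference
        gt = np.zeros((2, 2, 2), np.int8)
        gt[0, 0, 1] = 1
        gt[1, 0, 1] = 1
        gm = _gm(gt, [100, 140], ["CAR", "N0"])
        frags = [(90, 160, {100, 140})] * n_support
        fs = _toy_fragments("CAR", frags)
        diag = neow.DiagnosticSiteSet(np.array(["c"], object),
                                      np.array([100]), np.array([1]),
                                      ["CAR"], 2)
        return gm, diag, fs

    def test_linked_snp_rescued_at_min_support(self):
        gm, diag, fs = self._setup(3)
        haps = neow.reconstruct_neow(gm, diag, fs, min_support=3, chrom="c")
        h = haps["CAR"]
        assert h.allele[list(h.pos).index(140)] == 1

    def test_below_support_is_missing(self):
        gm, diag, fs = self._setup(2)
        haps = neow.reconstruct_neow(gm, diag, fs, min_support=3, chrom="c")
        h = haps["CAR"]
        assert h.allele[list(h.pos).index(140)] == -1

    def test_no_attributed_fragments_flagged(self):
        gm, diag, fs = self._setup(3)
        fs.frags["CAR"]["c"]["derived"] = [set()] * 3  # carry ref allele
        haps = neow.reconstruct_neow(gm, diag, fs, min_support=3, chrom="c")
        assert haps["CAR"].flagged
        assert np.all(haps["CAR"].allele == -1)

    def test_accuracy_against_truth(self, default_cohort, cohort_groups,
                                    neow_chain):
        """Haploid calls match the true fused haplotype at >= 99% of called
        sites, and never contradict the carrier's diploid genotype."""
        _, _, res = default_cohort
        carriers = cohort_groups["carriers"]
        haps = neow_chain["haps"]
        sl = res.gm.site_slice("chr15")
        accs, n_called = [], []
        for s in carriers:
            h = haps[s]
            truth_alleles = np.isin(
                h.pos, res.truth.fused_hap_positions(s)).astype(np.int8)
            called = h.allele >= 0
            n_called.append(int(called.sum()))
            if called.any():
                accs.append(np.mean(h.allele[called]
                                    == truth_alleles[called]))
            j = res.gm.sample_index([s])[0]
            gt = res.gm.gt[sl, j, :]
            contradiction = called & ~np.any(
                gt == h.allele[:, None], axis=1) & ~np.any(gt == -1, axis=1)
            assert not contradiction.any()
        assert np.mean(n_called) > 100
        assert np.mean(accs) >= 0.99


class TestHaploidPi:
    def _hap(self, name, alleles, pos, covered):
        return neow.NeoWHaplotype(name, "c", np.asarray(pos),
                                  np.asarray(alleles, np.int8),
                                  np.full(len(pos), 5, np.int32), covered)

    def test_identical_haplotypes(self):
        pos = [10, 20, 30]
        a = self._hap("a", [1, 0, 1], pos, [(0, 100)])
        b = self._hap("b", [1, 0, 1], pos, [(0, 100)])
        assert neow.haploid_pi([a, b]) == 0.0

    def test_order_of_magnitude_arithmetic(self):
        # 7 differing sites over a 100,000-bp shared covered interval
        pos = list(range(0, 70_000, 10_000))
        a = self._hap("a", [1] * 7, pos, [(0, 100_000)])
        b = self._hap("b", [0] * 7, pos, [(0, 100_000)])
        assert neow.haploid_pi([a, b]) == pytest.approx(7e-5)

    def test_no_overlap_is_null(self):
        a = self._hap("a", [1], [10], [(0, 50)])
        b = self._hap("b", [1], [500], [(400, 600)])
        assert neow.haploid_pi([a, b]) is None

    def test_ratio_to_diploid_pi(self, default_cohort, cohort_groups,
                                 neow_chain):
        """Shortly after a completed sweep the haploid neo-W diversity sits
        at least two orders of magnitude below diploid chr15 diversity."""
        from neowsweep import winstats
        from neowsweep.io_core import Window
        params, _, res = default_cohort
        carriers = cohort_groups["carriers"]
        pi_h = neow_chain["pi"]
        vals = []
        L = params.chrom_lengths["chr15"]
        for start in range(0, L - 100_000 + 1, 100_000):
            r = winstats.window_diversity(
                res.gm, {"cz": carriers}, Window("chr15", start,
                                                 start + 100_000))
            if r["pi"]["cz"] is not None:
                vals.append(r["pi"]["cz"])
        pi_d = float(np.mean(vals))
        assert pi_h is not None and pi_h > 0
        assert pi_d / pi_h >= 100


class TestDivergenceTest:
    def test_identical_groups_p_one(self, default_cohort, cohort_groups):
        params, _, res = default_cohort
        g = cohort_groups["carriers"][:4]
        rep = neow.divergence_test(res.gm, g, g, res.layout,
                                   region_start=params.colinear_start,
                                   size=50_000, step=50_000, min_sites=0)
        assert rep.test.p == 1.0

    def test_no_divergence_shortly_after_fusion(self):
        """Right after the sweep the neo-W females' heterozygosity in the
        colinear region is not yet distinguishable from wild type
        (6 scaled replicates; most must be non-significant)."""
        non_sig = 0
        reps = 6
        for r in range(reps):
            p = small_params(run_generations=25)
            state = sim.run_simulation(p, seed=300 + r)
            res = sim.sample_cohort(
                state, design={"contact": {"n_f": 12, "n_m": 0,
                                           "carriers_first": True}},
                coverage=0)
            s = res.samples
            car = list(s[s.neoW == "yes"]["sample"])[:5]
            wt = list(s[s.neoW == "no"]["sample"])[:5]
            if len(car) < 2 or len(wt) < 2:
                non_sig += 1  # sweep complete or absent: no contrast
                continue
            rep_ = neow.divergence_test(res.gm, car, wt, res.layout,
                                        region_start=p.colinear_start,
                                        size=10_000, step=10_000,
                                        min_sites=0)
            if rep_.test is None or rep_.test.p > 0.05:
                non_sig += 1
        assert non_sig >= reps - 1

    def test_synthetic_divergence_detected(self):
        """Positive control: doubled heterozygosity in one group across 48
        paired windows drives the Wilcoxon p small."""
        rng = np.random.default_rng(4)
        het_wt = rng.uniform(0.008, 0.012, 48)
        het_neo = het_wt * 2
        from neowsweep.stattests import wilcoxon_signed_rank
        assert wilcoxon_signed_rank(het_neo, het_wt).p < 1e-6


class TestRootAge:
    def test_unit_conversions(self):
        assert neow.years_to_generations(2_200, 12) == 26_400
        assert neow.generations_to_years(26_400, 12) == 2_200

    def test_zero_pi_zero_age(self):
        age = neow.root_age(0.0, 2.9e-9)
        assert age.generations == 0 and age.years == 0

    def test_null_pi_null_age(self):
        age = neow.root_age(None, 2.9e-9)
        assert age.generations is None

    def test_unbiased_on_star_genealogy(self, rng):
        """On star trees (every pair diverges 2T generations) the moment
        estimator is unbiased within 10% over 200 replicates."""
        mu, L, T, n = 1e-6, 200_000, 400, 10
        est = []
        for _ in range(200):
            privates = rng.poisson(mu * L * T, size=n)
            pairs = [(privates[i] + privates[j]) / L
                     for i in range(n) for j in range(i + 1, n)]
            est.append(neow.root_age(float(np.mean(pairs)), mu).generations)
        assert 0.9 <= np.mean(est) / T <= 1.1

    # replicate-based recovery of the true root age lives in the
    # acceptance suite (test_acceptance.py), where the full star-regime
    # simulation is run
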
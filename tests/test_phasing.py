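"""Five-group AS phasing, MAPQ phasing, and distribution diagnostics."""

import numpy as np
import pytest
from scipy import stats as sps

from karyokit.db import KaryokitError
from karyokit.phasing import (
    ASDistributionComparison,
    HapAlignment,
    MapqPhase,
    PairAlignmentSummary,
    PhaseGroup,
    compare_as_distributions,
    fit_exponential,
    ks_2sample,
    ks_2sample_d,
    phase_pair_as,
    phase_pair_mapq,
    phase_pairs_as,
    phase_summary,
    summarize_pairs,
)
from karyokit.simulate import (
    make_diploid,
    make_reference,
    pair_het_overlap,
    score_pairs,
    simulate_pairs,
    ToyGenomeSpec,
    write_alignments_sam,
)


def _pair(pid, p1, as1, p2, as2, refs1=("chr1", "chr1"), refs2=("chr1", "chr1")):
    return PairAlignmentSummary(
        pid,
        HapAlignment(p1, as1, refs1, (60, 60)),
        HapAlignment(p2, as2, refs2, (60, 60)),
    )


class TestASRules:
    @pytest.mark.parametrize(
        "summary,expected",
        [
            (_pair("a", True, 302, True, 291), PhaseGroup.HAP1),
            (_pair("b", True, 291, True, 302), PhaseGroup.HAP2),
            (_pair("c", True, 300, True, 300), PhaseGroup.HOMOZYGOUS),
            (_pair("d", False, None, True, 280), PhaseGroup.HAP2),
            (_pair("e", True, 280, False, None), PhaseGroup.HAP1),
            (_pair("f", False, None, False, None), PhaseGroup.NOT_PROPERLY_MAPPED),
            (_pair("g", False, 100, False, 90), PhaseGroup.NOT_PROPERLY_MAPPED),
        ],
    )
    def test_assignment_cascade(self, summary, expected):
        assert phase_pair_as(summary) is expected

    def test_sex_chromosome_trumps_as(self):
        s = _pair("x", True, 302, True, 291, refs1=("chrX", "chr1"))
        assert phase_pair_as(s, {"chrX", "chrY"}) is PhaseGroup.SEX_CHROMOSOME
        # checked on either haplotype's alignments
        s2 = _pair("y", True, 302, True, 291, refs2=("chr1", "chrY"))
        assert phase_pair_as(s2, {"chrX", "chrY"}) is PhaseGroup.SEX_CHROMOSOME

    def test_groups_exhaustive_and_conserved(self, toy_diploid):
        pairs = simulate_pairs(toy_diploid, 500, error_rate=0.002, seed=8)
        summaries = score_pairs(pairs, toy_diploid)
        assigns = phase_pairs_as(summaries)
        assert len(assigns) == 500
        summ = phase_summary(assigns)
        assert sum(summ.counts.values()) == summ.total == 500

    def test_haplotype_swap_symmetry(self, toy_diploid):
        pairs = simulate_pairs(toy_diploid, 400, error_rate=0.005, seed=9)
        summaries = score_pairs(pairs, toy_diploid)
        swapped = [
            PairAlignmentSummary(s.pair_id, s.hap2, s.hap1) for s in summaries
        ]
        c1 = phase_summary(phase_pairs_as(summaries)).counts
        c2 = phase_summary(phase_pairs_as(swapped)).counts
        assert c1[PhaseGroup.HAP1] == c2[PhaseGroup.HAP2]
        assert c1[PhaseGroup.HAP2] == c2[PhaseGroup.HAP1]
        for g in (
            PhaseGroup.NOT_PROPERLY_MAPPED,
            PhaseGroup.SEX_CHROMOSOME,
            PhaseGroup.HOMOZYGOUS,
        ):
            assert c1[g] == c2[g]

    def test_het0_all_mapped_pairs_homozygous(self, toy_ref):
        dip = make_diploid(toy_ref, het_rate=0.0, seed=1)
        pairs = simulate_pairs(dip, 300, seed=2)
        assigns = phase_pairs_as(score_pairs(pairs, dip))
        assert all(g is PhaseGroup.HOMOZYGOUS for g in assigns.values())
        assert phase_summary(assigns).phased_fraction == 0.0

    def test_truth_recovery_on_error_free_het_pairs(self, toy_diploid):
        pairs = simulate_pairs(toy_diploid, 1500, error_rate=0.0, seed=10)
        summaries = score_pairs(pairs, toy_diploid)
        assigns = phase_pairs_as(summaries)
        by_id = {p.pair_id: p for p in pairs}
        checked = 0
        for pid, group in assigns.items():
            p = by_id[pid]
            if group in (PhaseGroup.HAP1, PhaseGroup.HAP2) and pair_het_overlap(
                toy_diploid, p, 100
            ):
                checked += 1
                assert (group is PhaseGroup.HAP1) == (p.hap == 1)
        assert checked > 30

    def test_phased_fraction_increases_with_het_rate(self):
        ref = make_reference(ToyGenomeSpec(seed=21, n_chrom=2))
        rates = [0.0, 1e-4, 1e-3, 1e-2]
        means = []
        for rate in rates:
            fracs = []
            for seed in range(5):
                dip = make_diploid(ref, rate, seed=seed)
                pairs = simulate_pairs(dip, 400, seed=seed + 50)
                fracs.append(
                    phase_summary(phase_pairs_as(score_pairs(pairs, dip))).phased_fraction
                )
            means.append(np.mean(fracs))
        assert means[0] == 0.0
        assert all(b > a for a, b in zip(means, means[1:]))


class TestMapqRules:
    def test_confident_single_haplotype(self):
        assert (
            phase_pair_mapq(("hap1_chr1", "hap1_chr1"), (60, 60)) is MapqPhase.HAP1
        )
        assert (
            phase_pair_mapq(("hap2_chr1", "hap2_chr2"), (20, 10)) is MapqPhase.HAP2
        )

    def test_low_mapq_and_split_pairs_unphased(self):
        assert phase_pair_mapq(("hap1_chr1", "hap1_chr1"), (0, 60)) is MapqPhase.UNPHASED
        assert phase_pair_mapq(("hap1_chr1", "hap2_chr1"), (60, 60)) is MapqPhase.UNPHASED
        assert phase_pair_mapq(("hap1_chr1", None), (60, None)) is MapqPhase.UNPHASED

    def test_unattributable_reference_is_an_error(self):
        with pytest.raises(KaryokitError, match="scaffold7"):
            phase_pair_mapq(("scaffold7", "hap1_chr1"), (60, 60))


class TestSamCollation:
    def test_fixture_sam_round_trip(self, toy_diploid, tmp_path):
        pairs = simulate_pairs(toy_diploid, 100, seed=5)
        expected = score_pairs(pairs, toy_diploid)
        h1, h2 = tmp_path / "h1.sam", tmp_path / "h2.sam"
        write_alignments_sam(pairs, toy_diploid, str(h1), str(h2))
        got = summarize_pairs(str(h1), str(h2))
        assert len(got) == 100
        exp_by_id = {s.pair_id: s for s in expected}
        for s in got:
            e = exp_by_id[s.pair_id]
            assert (s.hap1.as_sum, s.hap2.as_sum) == (e.hap1.as_sum, e.hap2.as_sum)
            assert (s.hap1.proper_pair, s.hap2.proper_pair) == (
                e.hap1.proper_pair, e.hap2.proper_pair,
            )

    def test_absent_from_one_stream_and_missing_as(self, tmp_path, caplog):
        header = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        line = (
            "{name}\t{flag}\tchr1\t{pos}\t60\t10M\t=\t{pnext}\t{tlen}\tACGTACGTAC\t*{tags}\n"
        )
        h1 = header
        h1 += line.format(name="p1", flag=99, pos=1, pnext=100, tlen=109, tags="\tAS:i:10")
        h1 += line.format(name="p1", flag=147, pos=100, pnext=1, tlen=-109, tags="\tAS:i:9")
        h1 += line.format(name="p2", flag=99, pos=1, pnext=100, tlen=109, tags="\tAS:i:10")
        h1 += line.format(name="p2", flag=147, pos=100, pnext=1, tlen=-109, tags="")
        h1 += line.format(name="orphan", flag=99, pos=5, pnext=5, tlen=0, tags="\tAS:i:8")
        p1 = tmp_path / "h1.sam"
        p1.write_text(h1)
        p2 = tmp_path / "h2.sam"
        p2.write_text(header)
        summaries = summarize_pairs(str(p1), str(p2))
        by_id = {s.pair_id: s for s in summaries}
        assert set(by_id) == {"p1", "p2"}  # orphan excluded with a warning
        assert by_id["p1"].hap1.as_sum == 19
        assert by_id["p1"].hap2.proper_pair is False
        assert by_id["p1"].hap2.as_sum is None
        # missing AS on an aligned mate: treated as unaligned
        assert by_id["p2"].hap1.as_sum is None
        assert by_id["p2"].hap1.proper_pair is False


class TestDistributions:
    def test_ks_d_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(2, 400)))
            b = rng.normal(0.3, 1.2, int(rng.integers(2, 400)))
            # brute-force ECDF comparison at every observed point
            d_oracle = 0.0
            for v in np.concatenate([a, b]):
                d_oracle = max(
                    d_oracle, abs((a <= v).mean() - (b <= v).mean())
                )
            assert abs(ks_2sample_d(a, b) - d_oracle) < 1e-12
            d_scipy = sps.ks_2samp(a, b, method="asymp").statistic
            assert ks_2sample_d(a, b) == pytest.approx(d_scipy, abs=1e-12)

    def test_identical_samples_d_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d, p = ks_2sample(a, a.copy())
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_toy_quarter_shift(self):
        d = ks_2sample_d(np.array([1, 2, 3, 4.0]), np.array([2, 3, 4, 5.0]))
        assert d == pytest.approx(0.25)

    def test_exponential_fit_matches_scipy_mle(self, rng):
        sample = rng.exponential(7.0, 500) + 3.0
        loc, scale = fit_exponential(sample)
        s_loc, s_scale = sps.expon.fit(sample)
        assert loc == pytest.approx(s_loc)
        assert scale == pytest.approx(s_scale)

    def test_concordant_dominates_discordant(self, toy_diploid):
        pairs = simulate_pairs(toy_diploid, 800, seed=13)
        summaries = score_pairs(pairs, toy_diploid)
        assigns = phase_pairs_as(summaries)
        comp = compare_as_distributions(assigns, summaries)
        assert isinstance(comp, ASDistributionComparison)
        assert len(comp.concordant) == len(comp.discordant)
        assert (comp.concordant >= comp.discordant).all()  # per-pair dominance
        assert comp.median_concordant >= comp.median_discordant
        assert comp.ks_d > 0
        assert comp.ks_p < 0.01

    def test_insufficient_sample_is_an_error(self):
        with pytest.raises(KaryokitError):
            compare_as_distributions({}, [])
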
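import math
import random

import numpy as np
import pytest

from exonkit.models import GeneModel, GenomicInterval, Transcript
from exonkit.sequence_features import (
    ACCEPTOR_WINDOW,
    DEFAULT_CASSETTE_CLUSTERS,
    DONOR_WINDOW,
    PWM,
    ArchitectureFeatures,
    BranchPointConfig,
    PPTConfig,
    SREMotifSet,
    architecture,
    extract_site_window,
    find_branch_point,
    find_ppt,
    gc_fraction,
    is_symmetric,
    reverse_complement,
    scan_sre,
    score_site,
    site_window,
    train_pwm,
)
from oracles import oracle_branch_point, oracle_ppt, oracle_score, oracle_sre_count


def plus_gene():
    c = "chr1"
    exons = (
        GenomicInterval(c, 50, 100, "+"),
        GenomicInterval(c, 200, 300, "+"),
        GenomicInterval(c, 400, 450, "+"),
    )
    return GeneModel("g", (Transcript("t", "g", exons),))


class TestSiteWindows:
    def test_donor_window_spans_boundary(self):
        # exon ...CAG | GTAAGT... intron
        seq = "A" * 97 + "CAG" + "GTAAGT" + "A" * 50
        genome = {"chr1": seq}
        tx = Transcript("t", "g", (GenomicInterval("chr1", 50, 100, "+"),
                                   GenomicInterval("chr1", 200, 220, "+")))
        assert extract_site_window(genome, tx, 0, "donor") == "CAGGTAAGT"

    def test_donor_window_is_9nt(self, worked_gene, worked_genome):
        w = extract_site_window(worked_genome, worked_gene.transcript("i0"), 0, "donor")
        assert len(w) == DONOR_WINDOW == 9

    def test_acceptor_window_is_23nt(self, worked_gene, worked_genome):
        w = extract_site_window(worked_genome, worked_gene.transcript("i0"), 1, "acceptor")
        assert len(w) == ACCEPTOR_WINDOW == 23
        assert w[17:20] == "CAG"  # planted acceptor consensus ends intron ...AG

    def test_minus_strand_mirror_identical(self, worked_genome):
        seq = worked_genome["chrT"]
        L = len(seq)
        mirror = {"chrT": reverse_complement(seq)}
        tx_plus = Transcript(
            "t", "g",
            (GenomicInterval("chrT", 100, 200, "+"), GenomicInterval("chrT", 400, 500, "+")),
        )
        tx_minus = Transcript(
            "t", "g",
            (
                GenomicInterval("chrT", L - 500, L - 400, "-"),
                GenomicInterval("chrT", L - 200, L - 100, "-"),
            ),
        )
        for side in ("donor", "acceptor"):
            k_plus = 0 if side == "donor" else 1
            k_minus = 1 if side == "donor" else 0
            assert extract_site_window(worked_genome, tx_plus, k_plus, side) == \
                extract_site_window(mirror, tx_minus, k_minus, side)

    def test_terminal_boundary_rejected(self, worked_gene, worked_genome):
        i0 = worked_gene.transcript("i0")
        with pytest.raises(ValueError, match="no splice site"):
            extract_site_window(worked_genome, i0, 0, "acceptor")
        with pytest.raises(ValueError, match="no splice site"):
            extract_site_window(worked_genome, i0, 3, "donor")

    def test_window_off_contig(self):
        genome = {"chr1": "ACGT" * 5}
        with pytest.raises(ValueError, match="beyond contig"):
            site_window(genome, "chr1", 18, "+", "donor")


class TestTrainPWM:
    def test_identical_windows_indicator(self):
        pwm = train_pwm(["CAGGTAAGT"] * 100, "donor", pseudocount=0)
        assert pwm.consensus() == "CAGGTAAGT"
        assert np.allclose(np.sort(pwm.frequencies, axis=1)[:, -1], 1.0)

    def test_uniform_rotations(self):
        windows = [b * 9 for b in "ACGT"]
        pwm = train_pwm(windows, "donor", pseudocount=0)
        assert np.allclose(pwm.frequencies, 0.25)

    def test_pseudocount_arithmetic(self):
        # n=3, alpha=1: f = (count+1)/7; position 0 counts: C=2, A=1
        windows = ["CAGGTAAGT", "CAGGTAAGT", "AAGGTAAGT"]
        pwm = train_pwm(windows, "donor", pseudocount=1)
        assert math.isclose(pwm.frequencies[0, 1], 3 / 7)  # C
        assert math.isclose(pwm.frequencies[0, 0], 2 / 7)  # A
        assert math.isclose(pwm.frequencies[0, 2], 1 / 7)  # G
        assert np.allclose(pwm.frequencies.sum(axis=1), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch|must be"):
            train_pwm(["CAGGTAAGT", "CAGGT"], "donor")

    def test_wrong_length_for_site_kind(self):
        with pytest.raises(ValueError):
            train_pwm(["ACGT"], "donor")

    def test_empty_input(self):
        with pytest.raises(ValueError, match="zero"):
            train_pwm([], "donor")

    def test_save_load_round_trip(self, tmp_path):
        pwm = train_pwm(["CAGGTAAGT", "AAGGTAAGT", "CAGGTAAGA"], "donor")
        p = tmp_path / "pwm.tsv"
        pwm.save(p)
        back = PWM.load(p)
        assert back.site_kind == "donor"
        assert np.allclose(back.frequencies, pwm.frequencies)
        assert np.allclose(back.background, pwm.background)


class TestScoreSite:
    def test_indicator_consensus_is_18_bits(self):
        pwm = train_pwm(["CAGGTAAGT"] * 10, "donor", pseudocount=0)
        assert math.isclose(score_site(pwm, "CAGGTAAGT"), 9 * math.log2(4))
        assert math.isclose(score_site(pwm, "CAGGTAAGT"), 18.0)

    def test_uniform_pwm_scores_zero(self):
        pwm = train_pwm([b * 9 for b in "ACGT"], "donor", pseudocount=0)
        for window in ("CAGGTAAGT", "AAAAAAAAA", "TTTTTTTTT"):
            assert math.isclose(score_site(pwm, window), 0.0, abs_tol=1e-12)

    def test_against_positionwise_oracle(self):
        rng = random.Random(7)
        windows = ["".join(rng.choice("ACGT") for _ in range(9)) for _ in range(40)]
        pwm = train_pwm(windows, "donor", pseudocount=1)
        for w in windows[:5]:
            assert math.isclose(
                score_site(pwm, w),
                oracle_score(pwm.frequencies, pwm.background, w),
            )

    def test_additivity_over_random_windows(self):
        rng = random.Random(11)
        train = ["".join(rng.choice("ACGT") for _ in range(9)) for _ in range(30)]
        pwm = train_pwm(train, "donor")
        for _ in range(100):
            w = "".join(rng.choice("ACGT") for _ in range(9))
            single = sum(
                math.log2(pwm.frequencies[i, "ACGT".index(b)] / 0.25)
                for i, b in enumerate(w)
            )
            assert math.isclose(score_site(pwm, w), single)

    def test_consensus_maximality(self):
        rng = random.Random(3)
        for trial in range(20):
            train = ["".join(rng.choice("ACGT") for _ in range(9)) for _ in range(25)]
            pwm = train_pwm(train, "donor")
            best = score_site(pwm, pwm.consensus())
            assert math.isclose(best, pwm.max_score())
            for _ in range(50):
                w = "".join(rng.choice("ACGT") for _ in range(9))
                assert score_site(pwm, w) <= best + 1e-9

    def test_n_window_gives_missing(self):
        pwm = train_pwm(["CAGGTAAGT"] * 3, "donor")
        assert score_site(pwm, "CAGGTANGT") is None

    def test_alphabet_violation(self):
        pwm = train_pwm(["CAGGTAAGT"] * 3, "donor")
        with pytest.raises(ValueError):
            score_site(pwm, "CAGGTAXGT")


class TestBranchPoint:
    def test_planted_match_at_30(self):
        # CTAAC matches YTNAY (C,T,A,A,C)
        intron = "G" * 200
        intron = intron[: 200 - 30] + "CTAAC" + intron[200 - 25 :]
        hit = find_branch_point(intron)
        assert hit is not None
        assert hit.distance == 30
        assert hit.motif == "CTAAC"

    def test_beyond_350_not_found(self):
        intron = "G" * 400
        intron = intron[: 400 - 351] + "CTAAC" + intron[400 - 346 :]
        assert find_branch_point(intron) is None

    def test_at_exactly_350_found(self):
        intron = "G" * 400
        intron = intron[: 400 - 350] + "CTAAC" + intron[400 - 345 :]
        hit = find_branch_point(intron)
        assert hit is not None and hit.distance == 350

    def test_g_only_intron(self):
        assert find_branch_point("G" * 120) is None

    def test_closer_match_wins(self):
        intron = "G" * 120
        intron = intron[:40] + "CTAAC" + intron[45:]
        intron = intron[:100] + "CTAAC" + intron[105:]
        hit = find_branch_point(intron)
        assert hit.distance == 20  # 120 - 100

    def test_below_min_distance_ignored(self):
        intron = "G" * 110 + "CTAAC" + "G" * 5  # distance 10 < 14
        assert find_branch_point(intron) is None

    def test_matches_exhaustive_oracle_on_random_introns(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(30, 420)
            intron = "".join(rng.choice("ACGT") for _ in range(n))
            hit = find_branch_point(intron)
            expected = oracle_branch_point(intron)
            assert (hit.distance if hit else None) == expected


class TestPPT:
    def test_poly_t_tract_reported(self):
        intron = "G" * 60 + "T" * 20 + "CC" + "AG"
        hit = find_ppt(intron)
        assert hit is not None
        assert hit.length >= 20
        assert hit.pyrimidine_fraction >= 0.7

    def test_purine_only_intron(self):
        assert find_ppt("AG" * 40) is None

    def test_exactly_ten_pyrimidines(self):
        # boundary case: the searchable region is exactly the min length
        intron = "T" * 10 + "CC" + "AG"
        hit = find_ppt(intron)
        assert hit is not None
        assert hit.length == 10
        assert hit.start == 0
        assert oracle_ppt(intron)[:2] == (0, 10)

    def test_short_intron_none(self):
        assert find_ppt("ACGTAC") is None

    def test_matches_sliding_window_oracle(self):
        rng = random.Random(9)
        for _ in range(200):
            n = rng.randint(12, 120)
            intron = "".join(
                rng.choice("ACGT" if rng.random() < 0.5 else "CTTT") for _ in range(n)
            )
            hit = find_ppt(intron)
            expected = oracle_ppt(intron)
            got = (hit.start, hit.length, hit.pyrimidine_fraction) if hit else None
            if expected is None:
                assert got is None
            else:
                assert got[0] == expected[0] and got[1] == expected[1]
                assert math.isclose(got[2], expected[2])


class TestScanSRE:
    def test_default_cluster_set_is_the_six_motifs(self):
        assert set(DEFAULT_CASSETTE_CLUSTERS) == {
            "TCTCT", "TGCATG", "TGCT", "TGTGT", "TTTT", "AGGG",
        }
        assert len(DEFAULT_CASSETTE_CLUSTERS) == 6

    def test_match_positions_with_overlap_rule(self):
        # "TGCATGCATG" holds two overlapping TGCATG occurrences (0 and 4)
        scans = scan_sre("TGCATGCATG", ["TGCATG"])
        assert scans["TGCATG"].count == oracle_sre_count("TGCATGCATG", "TGCATG") == 2
        assert scans["TGCATG"].positions == (0, 4)
        scans = scan_sre("TGCATGAATG", ["TGCATG"])
        assert scans["TGCATG"].count == 1
        assert scans["TGCATG"].positions == (0,)

    def test_overlapping_matches_counted(self):
        scans = scan_sre("TTTTT", ["TTTT"])
        assert scans["TTTT"].count == 2
        assert scans["TTTT"].positions == (0, 1)

    def test_empty_motif_set(self):
        assert scan_sre("ACGTACGT", []) == {}

    def test_rna_motifs_accepted_as_dna(self):
        scans = scan_sre("TGCATG", ["UGCAUG"])
        assert scans["TGCATG"].count == 1

    def test_density_per_100nt(self):
        scans = scan_sre("TTTT" + "A" * 46, ["TTTT"])
        assert math.isclose(scans["TTTT"].density_per_100nt, 2.0)

    def test_region_restriction(self):
        scans = scan_sre("TTTTAAAATTTT", ["TTTT"], region=(8, 12))
        assert scans["TTTT"].positions == (8,)

    def test_counts_match_oracle(self):
        rng = random.Random(5)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 200)))
            scans = scan_sre(seq, SREMotifSet())
            for motif, scan in scans.items():
                assert scan.count == oracle_sre_count(seq, motif)

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            SREMotifSet(ese=("TGXAT",))


class TestArchitecture:
    def test_symmetry_divisor(self):
        assert is_symmetric(99) and not is_symmetric(100)
        flagged = [n for n in range(96, 103) if is_symmetric(n)]
        assert flagged == [96, 99, 102]

    def test_intron_to_exon_ratio(self):
        c = "chr1"
        exons = (
            GenomicInterval(c, 0, 50, "+"),
            GenomicInterval(c, 450, 550, "+"),   # introns 400 and 600
            GenomicInterval(c, 1150, 1200, "+"),
        )
        gene = GeneModel("g", (Transcript("t", "g", exons),))
        feats = architecture(gene)[exons[1]]
        assert feats.upstream_intron_length == 400
        assert feats.downstream_intron_length == 600
        assert math.isclose(feats.intron_to_exon_ratio, 5.0)

    def test_terminal_exons_have_missing_flank(self):
        gene = plus_gene()
        feats = architecture(gene)
        first, _, last = gene.exon_units
        assert feats[first].upstream_intron_length is None
        assert feats[first].downstream_intron_length is not None
        assert feats[last].downstream_intron_length is None

    def test_minus_strand_swaps_flanks(self):
        c = "chr1"
        exons = (
            GenomicInterval(c, 0, 50, "-"),
            GenomicInterval(c, 450, 550, "-"),
            GenomicInterval(c, 1150, 1200, "-"),
        )
        gene = GeneModel("g", (Transcript("t", "g", exons),))
        feats = architecture(gene)[exons[1]]
        # genomic-left gap (400) is the transcription-downstream intron on '-'
        assert feats.downstream_intron_length == 400
        assert feats.upstream_intron_length == 600

    def test_gc_of_exon(self):
        genome = {"chr1": "A" * 10 + "GGCC" + "A" * 10}
        exons = (GenomicInterval("chr1", 10, 14, "+"),)
        gene = GeneModel("g", (Transcript("t", "g", exons),))
        assert architecture(gene, genome)[exons[0]].exon_gc == 1.0

    def test_gc_none_without_genome(self):
        gene = plus_gene()
        for f in architecture(gene).values():
            assert f.exon_gc is None

    def test_symmetric_field(self):
        gene = plus_gene()  # exon lengths 50, 100, 50
        feats = architecture(gene)
        assert not any(f.symmetric for f in feats.values())


class TestGCHelpers:
    def test_concatenation_weighted_mean(self):
        rng = random.Random(1)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 50)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 50)))
            whole = gc_fraction(a + b)
            parts = (gc_fraction(a) * len(a) + gc_fraction(b) * len(b)) / (len(a) + len(b))
            assert math.isclose(whole, parts)

    def test_n_gives_missing(self):
        assert gc_fraction("ACGN") is None


class TestConfigValidation:
    def test_bp_config_ordering(self):
        with pytest.raises(ValueError):
            BranchPointConfig(min_distance=60, typical_max=50)

    def test_ppt_fraction_range(self):
        with pytest.raises(ValueError):
            PPTConfig(min_pyrimidine_fraction=1.5)
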
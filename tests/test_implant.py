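import numpy as np
import pytest

from enhancerkit.implant import (
    ImplantPlacement,
    background_robustness,
    flank_preference,
    iterative_implant,
    minimal_enhancer,
    scan_implant,
    spacing_analysis,
)
from enhancerkit.oracle import (
    FLY_SITES,
    HUMAN_SITES,
    WEAK_HUMAN_SITES,
    score_sequences,
)
from enhancerkit.seqcore import (
    Sequence,
    ValidationError,
    decode,
    default_profile,
    encode,
    generate_random_sequences,
    reverse_complement,
)


class TestScanImplant:
    def test_site_equal_to_sequence_length(self, fly):
        site = FLY_SITES["Onecut"]
        seq = Sequence(id="s", residues="GGGGGG")
        arrays, placement, modified = scan_implant(seq, site, fly, "KC")
        assert placement.start == 0
        assert modified.residues in (site, reverse_complement(site))

    def test_best_matches_brute_force(self, fly):
        seq = generate_random_sequences(default_profile(60), 1, seed=7)[0]
        site = FLY_SITES["Mef2"]
        arrays, placement, _ = scan_implant(seq, site, fly, "KC")
        # independent exhaustive re-scan
        best = None
        codes = encode(seq.residues)
        for rank, strand in enumerate("+-"):
            written = encode(site if strand == "+" else reverse_complement(site))
            for o in range(len(seq) - len(site) + 1):
                v = codes.copy()
                v[o : o + len(site)] = written
                s = score_sequences(fly, [Sequence(id="v", residues=decode(v))], "KC")[0]
                cand = (-s, o, rank)
                if best is None or cand < best:
                    best = cand
        assert (placement.start, placement.strand) == (best[1], "+-"[best[2]])
        assert placement.score_after == -best[0]

    def test_activator_site_raises_score(self, fly, random500):
        seq = random500[3]
        before = score_sequences(fly, [seq], "KC")[0]
        _, placement, _ = scan_implant(seq, FLY_SITES["Ey"], fly, "KC")
        assert placement.score_after > before

    def test_site_longer_than_sequence_rejected(self, fly):
        with pytest.raises(ValidationError):
            scan_implant(Sequence(id="s", residues="ACGT"), FLY_SITES["Ey"], fly, "KC")

    def test_mask_excludes_offsets(self, fly):
        seq = generate_random_sequences(default_profile(40), 1, seed=8)[0]
        site = FLY_SITES["Onecut"]
        arrays, placement, _ = scan_implant(
            seq, site, fly, "KC", mask_intervals=[(0, 20)]
        )
        assert placement.start >= 20
        assert np.isnan(arrays["+"][:15]).all()


class TestIterativeImplant:
    def test_order_invariance_for_non_overlapping_sites(self, fly, random500):
        seq = random500[4]
        ab = iterative_implant(
            seq, [("Ey", FLY_SITES["Ey"]), ("Mef2", FLY_SITES["Mef2"])], fly, "KC"
        )
        ba = iterative_implant(
            seq, [("Mef2", FLY_SITES["Mef2"]), ("Ey", FLY_SITES["Ey"])], fly, "KC"
        )
        pa = {(p.motif, p.start) for p in ab[1]}
        pb = {(p.motif, p.start) for p in ba[1]}
        if pa == pb:  # same final arrangement -> identical final scores
            assert ab[2][-1] == pytest.approx(ba[2][-1], abs=1e-12)

    def test_random_policy_reproducible(self, fly, random500):
        seq = random500[5]
        sites = [("Ey", FLY_SITES["Ey"])]
        a = iterative_implant(seq, sites, fly, "KC", policy="random", seed=3)
        b = iterative_implant(seq, sites, fly, "KC", policy="random", seed=3)
        assert a[1] == b[1]

    def test_best_policy_trajectory_non_decreasing(self, fly, random500):
        seq = random500[6]
        sites = [(n, s) for n, s in FLY_SITES.items()]
        _, placements, trajectory = iterative_implant(seq, sites, fly, "KC")
        assert all(b >= a - 1e-12 for a, b in zip(trajectory, trajectory[1:]))

    def test_no_overlap_by_default(self, fly, random500):
        seq = random500[7]
        sites = [(n, s) for n, s in FLY_SITES.items()]
        _, placements, _ = iterative_implant(seq, sites, fly, "KC")
        for i, a in enumerate(placements):
            for b in placements[i + 1 :]:
                assert max(a.start, b.start) >= min(a.end, b.end)

    def test_closest_positive_needs_anchor(self, fly, random500):
        with pytest.raises(ValidationError):
            iterative_implant(
                random500[8],
                [("Ey", FLY_SITES["Ey"])],
                fly,
                "KC",
                policy="closest_positive",
            )

    def test_closest_positive_lands_near_anchor(self, human, random500):
        seq = random500[9]
        final, placements, _ = iterative_implant(
            seq,
            [("SOX10", HUMAN_SITES["SOX10"]), ("MITF", HUMAN_SITES["MITF"])],
            human,
            "MEL",
            policy=["best", "closest_positive"],
        )
        anchor, partner = placements
        gap = max(anchor.start, partner.start) - min(anchor.end, partner.end)
        assert gap <= 100  # near the anchor, not anywhere in the 500 bp


class TestWeakSites:
    def test_weak_sites_score_below_strong_at_same_positions(self, human, random500):
        seq = random500[10]
        strong_sites = [("SOX10", HUMAN_SITES["SOX10"]), ("MITF", HUMAN_SITES["MITF"])]
        final, placements, _ = iterative_implant(seq, strong_sites, human, "MEL")
        strong_score = placements[-1].score_after
        codes = encode(final.residues)
        weak = {"SOX10": WEAK_HUMAN_SITES["SOX10_1"], "MITF": WEAK_HUMAN_SITES["MITF_1"]}
        for p in placements:
            written = weak[p.motif] if p.strand == "+" else reverse_complement(weak[p.motif])
            codes[p.start : p.end] = encode(written)
        weak_score = score_sequences(
            human, [Sequence(id="w", residues=decode(codes))], "MEL"
        )[0]
        assert weak_score < strong_score


class TestSpacing:
    def test_gap_arithmetic_example(self):
        sets = [
            [
                ImplantPlacement("Ey", 100, 117, "+", 0.5),
                ImplantPlacement("Mef2", 122, 132, "+", 0.6),
            ]
        ]
        hists, skipped = spacing_analysis(sets, "Ey", "Mef2")
        assert hists["same_strand"] == {5: 1}
        assert skipped == 0

    def test_upstream_partner_negative_and_opposite_strand_keyed(self):
        sets = [
            [
                ImplantPlacement("Ey", 100, 117, "+", 0.5),
                ImplantPlacement("Mef2", 90, 96, "-", 0.6),
            ]
        ]
        hists, _ = spacing_analysis(sets, "Ey", "Mef2")
        assert hists["opposite_strand"] == {-4: 1}

    def test_fixed_offset_population_single_bin(self):
        sets = [
            [
                ImplantPlacement("A", 10, 16, "+", 0.1),
                ImplantPlacement("B", 20, 26, "+", 0.1),
            ]
            for _ in range(50)
        ]
        hists, _ = spacing_analysis(sets, "A", "B")
        assert hists["same_strand"] == {4: 50}

    def test_random_placements_roughly_flat(self):
        rng = np.random.default_rng(4)
        sets = []
        for _ in range(2000):
            a = int(rng.integers(0, 100))
            b = int(rng.integers(0, 100))
            sets.append(
                [
                    ImplantPlacement("A", a, a + 1, "+", 0.1),
                    ImplantPlacement("B", b, b + 1, "+", 0.1),
                ]
            )
        hists, skipped = spacing_analysis(sets, "A", "B")
        counts = hists["same_strand"]
        n = sum(counts.values())
        # gaps of two uniform points form a triangular distribution; compare
        # each bin against 3x its triangular-null expectation
        for gap, c in counts.items():
            expected = n * (100 - abs(gap) - 1) * 2 / (100 * 99)
            assert c <= max(3 * expected, 6)

    def test_missing_partner_skipped_and_counted(self):
        sets = [[ImplantPlacement("A", 0, 5, "+", 0.1)]]
        hists, skipped = spacing_analysis(sets, "A", "B")
        assert skipped == 1 and sum(hists["same_strand"].values()) == 0


class TestFlankPreference:
    def test_fixed_flanks_hit_three_quarters(self):
        seqs, placements = [], []
        for i in range(10):
            seqs.append(Sequence(id=f"s{i}", residues="TT" + "ACGT" + "AA"))
            placements.append(ImplantPlacement("m", 2, 6, "+", 0.5))
        fp = flank_preference(seqs, placements, window=2)
        assert fp.matrix[0, 3] == pytest.approx(0.75)  # T at first flank position
        assert fp.matrix[-1, 0] == pytest.approx(0.75)  # A at last
        assert np.allclose(fp.matrix.sum(axis=1), 0.0, atol=1e-9)

    def test_uniform_flanks_near_zero(self):
        rng = np.random.default_rng(5)
        seqs, placements = [], []
        for i in range(4000):
            flanks = "".join("ACGT"[b] for b in rng.integers(0, 4, 12))
            seqs.append(Sequence(id=f"s{i}", residues=flanks[:6] + "ATCGAT" + flanks[6:]))
            placements.append(ImplantPlacement("m", 6, 12, "+", 0.5))
        fp = flank_preference(seqs, placements, window=6)
        flank_rows = np.r_[fp.matrix[:6], fp.matrix[-6:]]
        assert np.abs(flank_rows).max() < 0.03

    def test_edge_placements_skipped(self):
        seqs = [Sequence(id="s", residues="ACGTACGT")]
        placements = [ImplantPlacement("m", 0, 4, "+", 0.5)]
        with pytest.raises(ValidationError):
            flank_preference(seqs, placements, window=2)


class TestMinimalEnhancer:
    def test_interval_arithmetic_49bp(self):
        seq = Sequence(id="s", residues="A" * 200)
        placements = [
            ImplantPlacement("Ey", 104, 121, "+", 0.5),
            ImplantPlacement("Mef2", 126, 136, "+", 0.6),
            ImplantPlacement("Onecut", 139, 145, "+", 0.7),
        ]
        cut = minimal_enhancer(seq, placements, flank=4)
        assert len(cut) == 49
        assert cut.source == ("s", 100, 149, "+")

    def test_single_placement_zero_flank(self):
        seq = Sequence(id="s", residues="GGGG" + "ATCGAT" + "CCCC")
        cut = minimal_enhancer(seq, [ImplantPlacement("Onecut", 4, 10, "+", 0.5)], flank=0)
        assert cut.residues == "ATCGAT"

    def test_multi_site_zero_flank_spans_placements(self):
        seq = Sequence(id="s", residues="A" * 60)
        pls = [
            ImplantPlacement("a", 10, 16, "+", 0.1),
            ImplantPlacement("b", 30, 40, "+", 0.2),
        ]
        assert len(minimal_enhancer(seq, pls, flank=0)) == 30


class TestBackgroundRobustness:
    def test_identity_replacement_keeps_score(self, fly):
        seq = Sequence(id="s", residues="A" * 50)
        out = background_robustness(seq, (10, 30), fly, "KC", n_backgrounds=50, seed=1)
        assert out.baseline == pytest.approx(
            score_sequences(fly, [seq], "KC")[0]
        )

    def test_window_outside_hits_leaves_score_unchanged(self, fly):
        from enhancerkit.fixtures import implanted_positive_fixture

        seqs, placements = implanted_positive_fixture(1, seed=6, oracle=fly)
        seq = seqs[0]
        # a window far from every placement; any stray hit created inside the
        # window only changes the score through that window, so compare to
        # re-scoring: untouched hits guarantee equality when no new hit forms
        spans = sorted((p.start, p.end) for p in placements[0])
        gap_start = 0
        for s, e in spans:
            if s - gap_start >= 40:
                break
            gap_start = e
        window = (gap_start + 5, gap_start + 25)
        out = background_robustness(
            seq, window, fly, "KC", n_backgrounds=200, seed=2,
            placements=placements[0], keep_scores=True,
        )
        # scores never exceed baseline contributions from untouched sites by
        # more than newly created hits allow; the majority of draws create no
        # hit at all and reproduce the baseline exactly
        assert np.median(out.scores) == pytest.approx(out.baseline, abs=1e-9)

    def test_window_overlapping_site_requires_flag(self, fly):
        from enhancerkit.fixtures import implanted_positive_fixture

        seqs, placements = implanted_positive_fixture(1, seed=6, oracle=fly)
        p = placements[0][0]
        with pytest.raises(ValidationError):
            background_robustness(
                seqs[0], (p.start, p.end), fly, "KC", n_backgrounds=5, seed=3,
                placements=placements[0],
            )
        out = background_robustness(
            seqs[0], (p.start, p.end), fly, "KC", n_backgrounds=500, seed=3,
            placements=placements[0], allow_site_overlap=True, keep_scores=True,
        )
        # destroying an activator site shifts the distribution left
        assert out.mean < out.baseline
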
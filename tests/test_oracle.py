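import numpy as np
import pytest
from scipy.stats import spearmanr

from enhancerkit.fixtures import (
    ablate_repressor_hits,
    implanted_positive_fixture,
    near_enhancer_fixture,
)
from enhancerkit.motifs import motif_from_consensus
from enhancerkit.oracle import (
    FLY_SITES,
    PairBonus,
    SurrogateClassSpec,
    SurrogateMotif,
    SurrogateOracle,
    contribution_scores,
    fly_surrogate,
    load_surrogate_toml,
    save_surrogate_toml,
    score_sequences,
)
from enhancerkit.seqcore import (
    Sequence,
    ValidationError,
    default_profile,
    encode,
    generate_random_sequences,
)


def _activator_only(weight=1.0, intercept=2.0):
    return SurrogateOracle(
        {
            "A": SurrogateClassSpec(
                motifs=[
                    SurrogateMotif(
                        motif_from_consensus("Ey", FLY_SITES["Ey"], "activator"), weight
                    )
                ],
                intercept=intercept,
            )
        }
    )


class TestScoring:
    def test_empty_motif_set_constant_score(self, random500):
        b = 1.7
        orc = SurrogateOracle({"A": SurrogateClassSpec(motifs=[], intercept=b)})
        scores = score_sequences(orc, random500[:5], "A")
        assert np.allclose(scores, 1.0 / (1.0 + np.exp(b)))

    def test_embedded_activator_site_scores_higher(self, random500):
        orc = _activator_only()
        background = random500[0]
        site = FLY_SITES["Ey"]
        embedded = Sequence(
            id="emb",
            residues=background.residues[:200] + site + background.residues[200 + len(site):],
        )
        lo, hi = score_sequences(orc, [background, embedded], "A")
        assert hi > lo

    def test_scores_in_unit_interval(self, fly, random500):
        scores = fly.score_batch(random500)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_batch_equals_elementwise(self, fly, random500):
        batch = fly.score_batch(random500[:6])
        singles = np.vstack([fly.score_batch([s]) for s in random500[:6]])
        assert np.array_equal(batch, singles)

    def test_unknown_class_and_length_mismatch(self, fly, random500):
        with pytest.raises(ValidationError):
            score_sequences(fly, random500[:1], "no_such_class")
        orc = _activator_only()
        orc.input_length = 100
        with pytest.raises(ValidationError):
            score_sequences(orc, random500[:1], "A")

    def test_both_strands_scanned(self):
        orc = _activator_only()
        site = FLY_SITES["Ey"]
        from enhancerkit.seqcore import reverse_complement

        fwd = Sequence(id="f", residues="A" * 20 + site + "A" * 20)
        rev = Sequence(id="r", residues="A" * 20 + reverse_complement(site) + "A" * 20)
        s = score_sequences(orc, [fwd, rev], "A")
        assert s[0] == pytest.approx(s[1], abs=1e-12)


class TestCalibration:
    """Fixed packaged parameters must separate random from designed sequences."""

    def test_random_sequences_score_low(self, fly, profile500):
        seqs = generate_random_sequences(profile500, 200, seed=31)
        assert score_sequences(fly, seqs, "KC").mean() < 0.1

    def test_fully_implanted_repressor_free_scores_high(self, fly):
        seqs, _ = implanted_positive_fixture(5, seed=32, oracle=fly)
        assert score_sequences(fly, seqs, "KC").mean() > 0.9


class TestPairBonus:
    def test_adjacent_hits_earn_bonus(self):
        ey = motif_from_consensus("Ey", "TGCTCACT", "activator")
        mef = motif_from_consensus("Mef2", "CTATTTAT", "activator")
        base_spec = dict(
            motifs=[SurrogateMotif(ey, 1.0), SurrogateMotif(mef, 1.0)], intercept=0.0
        )
        plain = SurrogateOracle({"A": SurrogateClassSpec(**base_spec)})
        bonus = SurrogateOracle(
            {
                "A": SurrogateClassSpec(
                    **base_spec,
                    pairs=[PairBonus("Ey", "Mef2", max_gap=5, bonus=2.0)],
                )
            }
        )
        seq = Sequence(id="s", residues="TGCTCACT" + "AAA" + "CTATTTAT" + "AAAA")
        far = Sequence(id="f", residues="TGCTCACT" + "A" * 30 + "CTATTTAT")
        r_plain = plain.raw_scores(encode(seq.residues)[None, :], ["A"])[0, 0]
        r_bonus = bonus.raw_scores(encode(seq.residues)[None, :], ["A"])[0, 0]
        assert r_bonus == pytest.approx(r_plain + 2.0)
        r_far_plain = plain.raw_scores(encode(far.residues)[None, :], ["A"])[0, 0]
        r_far_bonus = bonus.raw_scores(encode(far.residues)[None, :], ["A"])[0, 0]
        assert r_far_bonus == pytest.approx(r_far_plain)


class TestContributions:
    def test_constant_oracle_zero_track(self, constant_oracle, short_random):
        track = contribution_scores(constant_oracle, short_random[0], "flat")
        assert np.allclose(track.values, 0.0)

    def test_exact_additivity_reconstructs_raw_score(self, fly):
        seqs, _ = implanted_positive_fixture(3, seed=41, oracle=fly)
        for seq in seqs:
            track = contribution_scores(fly, seq, "KC", method="surrogate_exact")
            raw = fly.raw_scores(encode(seq.residues)[None, :], ["KC"])[0, 0]
            assert abs(track.values.sum() - raw) < 1e-9

    def test_positions_outside_hits_are_zero(self, fly):
        seqs, placements = implanted_positive_fixture(1, seed=42, oracle=fly)
        track = contribution_scores(fly, seqs[0], "KC", method="surrogate_exact")
        hit_cover = np.zeros(len(seqs[0]), dtype=bool)
        for h in fly.hits(seqs[0], "KC"):
            hit_cover[h.start : h.end] = True
        assert np.all(track.values[~hit_cover] == 0.0)

    def test_exact_refused_with_pair_bonus(self):
        ey = motif_from_consensus("Ey", "TGCTCACT", "activator")
        orc = SurrogateOracle(
            {
                "A": SurrogateClassSpec(
                    motifs=[SurrogateMotif(ey, 1.0)],
                    intercept=0.0,
                    pairs=[PairBonus("Ey", "Ey", 5, 1.0)],
                )
            }
        )
        with pytest.raises(ValidationError):
            contribution_scores(
                orc, Sequence(id="s", residues="A" * 30), "A", method="surrogate_exact"
            )

    def test_ism_correlates_with_exact_on_hit_positions(self, fly):
        rs = []
        for seq in near_enhancer_fixture(10, seed=43, oracle=fly):
            exact = contribution_scores(fly, seq, "KC", method="surrogate_exact").values
            ism = contribution_scores(fly, seq, "KC", method="ism_mean_delta").values
            mask = exact != 0
            if mask.sum() >= 10:
                rs.append(spearmanr(ism[mask], exact[mask]).statistic)
        assert np.mean(rs) > 0.7


class TestSerialization:
    def test_toml_round_trip_preserves_scores(self, tmp_path, fly, random500):
        path = tmp_path / "surrogate.toml"
        save_surrogate_toml(fly, path)
        back = load_surrogate_toml(path)
        assert back.class_names == fly.class_names
        a = fly.score_batch(random500[:5])
        b = back.score_batch(random500[:5])
        assert np.allclose(a, b, atol=1e-9)


def test_repressor_ablation_removes_all_repressor_hits(fly, random500):
    spec = fly.classes["KC"]
    roles = {sm.motif.name: sm.motif.role for sm in spec.motifs}
    seq = ablate_repressor_hits(random500[0], fly, "KC")
    remaining = [h for h in fly.hits(seq, "KC") if roles[h.motif] == "repressor"]
    assert remaining == []
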
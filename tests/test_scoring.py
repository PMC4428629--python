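"""Conservation scoring against the neutral-retention null."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, stats

from slimcons.errors import InputError
from slimcons.motifs import PATTERNS, MotifMatch, parse_pattern
from slimcons.orthologs import read_species_tree
from slimcons.scoring import (
    NullModel,
    PhyloRetentionNull,
    SpeciesEvidence,
    background_composition,
    combine_fisher,
    expected_matches,
    match_retention_evidence,
    motif_match_prob,
    poisson_upper_tail,
    protein_motif_score,
    retention_null_tail,
    score_match,
)

from conftest import make_group

DOCKING = PATTERNS["docking"]
UNIFORM = np.full(20, 0.05)


class TestBackgroundComposition:
    def test_pseudocount_rule(self):
        f = background_composition("AAAA")
        assert f[0] == pytest.approx(4.5 / 14)
        assert f[1] == pytest.approx(0.5 / 14)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_long_uniform_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100_000))
        f = background_composition(seq)
        assert np.all(np.abs(f - 0.05) < 0.01)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            background_composition("")


class TestMatchProbability:
    def test_docking_under_uniform(self):
        assert motif_match_prob(DOCKING, UNIFORM) == pytest.approx(2.5e-4)

    def test_consensus_under_uniform(self):
        assert motif_match_prob(PATTERNS["consensus"], UNIFORM) == pytest.approx(5e-4)

    def test_all_wildcard_is_certain(self):
        assert motif_match_prob(parse_pattern("xxx"), UNIFORM) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "length, expected", [(1000, 997 * 2.5e-4), (4, 2.5e-4), (3, 0.0)]
    )
    def test_expected_matches(self, length, expected):
        assert expected_matches(4, length, 2.5e-4) == pytest.approx(expected)


class TestPoissonUpperTail:
    @pytest.mark.parametrize(
        "m, lam, expected",
        [
            (0, 5.0, 1.0),
            (1, 0.25, 1 - math.exp(-0.25)),
            (2, 0.1, 1 - math.exp(-0.1) * 1.1),
            (1, 0.3, 1 - math.exp(-0.3)),
        ],
    )
    def test_closed_forms(self, m, lam, expected):
        assert poisson_upper_tail(m, lam) == pytest.approx(expected, rel=1e-9)


class TestCombineFisher:
    def test_all_ones(self):
        assert combine_fisher([1.0, 1.0, 1.0]) == (0.0, 1.0)

    def test_single_p_is_identity(self):
        _, p = combine_fisher([0.3])
        assert p == pytest.approx(0.3, rel=1e-9)

    def test_two_tenths(self):
        x, p = combine_fisher([0.1, 0.1])
        assert x == pytest.approx(-4 * math.log(0.1))
        assert p == pytest.approx(math.exp(-4.6052) * (1 + 4.6052), rel=1e-3)

    def test_domain_error(self):
        with pytest.raises(InputError):
            combine_fisher([0.0, 0.5])

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 10])
    def test_matches_chi_square_integral(self, n):
        rng = np.random.default_rng(n)
        ps = rng.uniform(0.01, 1.0, size=n)
        x, p = combine_fisher(ps)
        numeric, _ = integrate.quad(stats.chi2(2 * n).pdf, x, np.inf)
        assert p == pytest.approx(numeric, abs=1e-6)


def evidence_group(n_diff: int, retained: bool = True):
    """One ortholog pair: FKFP at columns 5-8, n_diff mismatched background
    columns among the 10 comparable in a 14-column window."""
    ref = "AAAAA" + "FKFP" + "AAAAA"
    other = list(ref)
    background = [0, 1, 2, 3, 4, 9, 10, 11, 12, 13]
    for i in background[:n_diff]:
        other[i] = "C"
    if not retained:
        other[7] = "A"  # break the F at the third motif position
    return make_group({"Scer": ref, "Sbay": "".join(other)})


class TestRetentionEvidence:
    def make_null(self, group, window=14):
        return NullModel.from_group(group, DOCKING, window=window)

    def make_match(self, group):
        return MotifMatch("P0001", 5, 9, "FKFP", "docking")

    def test_identical_species_contributes_nothing(self):
        group = evidence_group(0)
        ev = match_retention_evidence(self.make_match(group), DOCKING, group,
                                      self.make_null(group))
        (e,) = ev
        assert e.retained and e.local_identity == 1.0
        assert e.null_retention == 1.0 and e.p_value == 1.0

    def test_retained_discounted_by_local_identity(self):
        # 8 of 10 background columns identical: I = 0.8, r = 0.8^3 = 0.512
        group = evidence_group(2)
        ev = match_retention_evidence(self.make_match(group), DOCKING, group,
                                      self.make_null(group))
        (e,) = ev
        assert e.retained
        assert e.local_identity == pytest.approx(0.8)
        assert e.null_retention == pytest.approx(0.512)
        assert -math.log(e.p_value) == pytest.approx(0.669, abs=5e-3)

    def test_lost_match_is_unsurprising(self):
        group = evidence_group(2, retained=False)
        ev = match_retention_evidence(self.make_match(group), DOCKING, group,
                                      self.make_null(group))
        (e,) = ev
        assert not e.retained and e.p_value == 1.0

    def test_gap_in_match_columns_breaks_retention(self):
        ref = "AAAAA" + "FKFP" + "AAAAA"
        other = ref[:6] + "-" + ref[7:]
        group = make_group({"Scer": ref, "Sbay": other})
        ev = match_retention_evidence(self.make_match(group), DOCKING, group,
                                      self.make_null(group))
        assert not ev[0].retained

    def test_retention_floored_at_window_match_probability(self):
        # every background column differs: identity 0, r falls to q_s
        group = evidence_group(10)
        null = self.make_null(group)
        ev = match_retention_evidence(self.make_match(group), DOCKING, group, null)
        (e,) = ev
        assert e.null_retention == pytest.approx(null.q["Sbay"])

    def test_score_decreases_as_background_identity_rises(self):
        scores = []
        for n_diff in (6, 4, 2):
            group = evidence_group(n_diff)
            null = self.make_null(group)
            match = self.make_match(group)
            scores.append(score_match(match, DOCKING, group, null).score)
        assert scores[0] > scores[1] > scores[2]

    def test_adding_retaining_species_increases_score(self):
        ref = "AAAAA" + "FKFP" + "AAAAA"
        far = "CC" + ref[2:]
        two = make_group({"Scer": ref, "Sbay": far})
        three = make_group({"Scer": ref, "Sbay": far, "Klac": far})
        match = MotifMatch("P0001", 5, 9, "FKFP", "docking")
        s2 = score_match(match, DOCKING, two, NullModel.from_group(two, DOCKING, window=14))
        s3 = score_match(match, DOCKING, three, NullModel.from_group(three, DOCKING, window=14))
        assert s3.score > s2.score

    def test_non_retaining_species_leaves_score_unchanged(self):
        ref = "AAAAA" + "FKFP" + "AAAAA"
        far = "CC" + ref[2:]
        lost = far[:7] + "A" + far[8:]
        base = make_group({"Scer": ref, "Sbay": far})
        extra = make_group({"Scer": ref, "Sbay": far, "Klac": lost})
        match = MotifMatch("P0001", 5, 9, "FKFP", "docking")
        s1 = score_match(match, DOCKING, base, NullModel.from_group(base, DOCKING, window=14))
        s2 = score_match(match, DOCKING, extra, NullModel.from_group(extra, DOCKING, window=14))
        assert s2.score == pytest.approx(s1.score)
        assert s2.n_species_retained == s1.n_species_retained

    def test_fully_conserved_group_scores_zero(self):
        ref = "GGGGG" + "FKFP" + "GGGHGRKKSTGG"
        group = make_group({sp: ref for sp in ("Scer", "Sbay", "Klac", "Kwal")})
        for pattern in (DOCKING, PATTERNS["consensus"]):
            null = NullModel.from_group(group, pattern)
            ps = protein_motif_score(group, pattern, null)
            if ps is not None:
                assert ps.best_score == pytest.approx(0.0)
                assert ps.best.combined_p == pytest.approx(1.0, abs=0.5)


class TestRetentionNullTail:
    def one_species(self, r, retained):
        return [SpeciesEvidence("Sbay", retained, r ** (1 / 3), r, r if retained else 1.0)]

    def test_single_retained_species(self):
        p_exact = retention_null_tail(self.one_species(0.4, True), mid_p=False)
        p_mid = retention_null_tail(self.one_species(0.4, True))
        assert p_exact == pytest.approx(0.4)
        assert p_mid == pytest.approx(0.2)

    def test_single_lost_species(self):
        assert retention_null_tail(self.one_species(0.4, False), mid_p=False) == pytest.approx(1.0)
        assert retention_null_tail(self.one_species(0.4, False)) == pytest.approx(0.7)

    def test_two_species_tail(self):
        ev = [
            SpeciesEvidence("A", True, 0.0, 0.5, 0.5),
            SpeciesEvidence("B", True, 0.0, 0.25, 0.25),
        ]
        # observed S is the maximum atom: exact tail = 0.5 * 0.25
        assert retention_null_tail(ev, mid_p=False) == pytest.approx(0.125)


class TestProteinScore:
    def test_best_score_and_tie_break(self):
        ref = "AA" + "FKFP" + "CCCCC" + "FKFP" + "AA"
        other = "GG" + "FKFP" + "CCCCC" + "FKFP" + "GG"
        group = make_group({"Scer": ref, "Sbay": other})
        ps = protein_motif_score(group, DOCKING)
        assert ps is not None
        assert ps.best_match.start == 2  # equal scores: smaller start wins

    def test_no_match_returns_none(self):
        group = make_group({"Scer": "GGGGGG", "Sbay": "GGGGGG"})
        assert protein_motif_score(group, DOCKING) is None


class TestPhyloRetentionNull:
    TREE = "((Scer:0.1,Sbay:0.1):0.2,(Klac:0.15,Kwal:0.15):0.2);"

    def make(self, **kw):
        return PhyloRetentionNull(read_species_tree(self.TREE), "Scer", **kw)

    def evidence(self, retained_species):
        return [
            SpeciesEvidence(sp, sp in retained_species, 0.6, 0.216,
                            0.216 if sp in retained_species else 1.0)
            for sp in ("Sbay", "Klac", "Kwal")
        ]

    def null_model(self):
        freqs = {sp: UNIFORM for sp in ("Scer", "Sbay", "Klac", "Kwal")}
        return NullModel(
            freqs=freqs,
            q={sp: 2.5e-4 for sp in freqs},
            global_identity={"Sbay": 0.8, "Klac": 0.7, "Kwal": 0.7},
        )

    def test_probability_bounds_and_monotonicity(self):
        null = self.make()
        nm = self.null_model()
        p_none = null.combined_p(self.evidence(set()), DOCKING, nm)
        p_some = null.combined_p(self.evidence({"Sbay"}), DOCKING, nm)
        p_all = null.combined_p(self.evidence({"Sbay", "Klac", "Kwal"}), DOCKING, nm)
        assert 0 < p_all < p_some < p_none <= 1

    def test_species_missing_from_tree_falls_back(self):
        null = self.make()
        ev = self.evidence(set()) + [SpeciesEvidence("Spom", True, 0.5, 0.125, 0.125)]
        assert null.combined_p(ev, DOCKING, self.null_model()) is None

    def test_too_many_species_falls_back(self):
        null = self.make(max_species=2)
        assert null.combined_p(self.evidence(set()), DOCKING, self.null_model()) is None

    def test_reference_must_be_a_leaf(self):
        with pytest.raises(InputError):
            PhyloRetentionNull(read_species_tree(self.TREE), "Spom")
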
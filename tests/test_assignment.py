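from __future__ import annotations

import numpy as np
import pytest

import barcodeval as bv
from barcodeval.assignment import (
    CORRECT,
    INCORRECT,
    NO_ASSIGNMENT,
    UNSCORABLE,
    VACUOUS,
    assign_from_identities,
    free_end_alignment_score,
    pairwise_identity,
)

from .oracles import oracle_assign, oracle_free_end, oracle_identity_aligned


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "q, s, expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("ACGT", "ACGA", 0.75),
            ("AC-T", "ACGT", 1.0),  # gap column dropped in aligned mode
            ("ACNT", "ACGT", 1.0),
        ],
    )
    def test_aligned_mode(self, q, s, expected):
        score = pairwise_identity(q, s, "aligned")
        assert score.identity == pytest.approx(expected)

    def test_aligned_mode_no_scorable_columns(self):
        score = pairwise_identity("----", "AC--", "aligned")
        assert score.identity is None and score.scored_sites == 0

    def test_aligned_mode_requires_equal_lengths(self):
        with pytest.raises(bv.ValidationError):
            pairwise_identity("ACGT", "ACG", "aligned")

    def test_free_end_substring_scores_full_identity(self):
        score = pairwise_identity("ACGTACGT", "GTACG", "free_end_global")
        assert score.identity == 1.0 and score.scored_sites == 5

    @pytest.mark.parametrize(
        "q, s",
        [
            ("ACGTAC", "ACAC"),
            ("AAAA", "TTTT"),
            ("ACGT", "ACGT"),
            ("GATTACA", "GCATGCA"),
            ("ACGTACGT", "GTACG"),
            ("TTGACC", "TGCC"),
        ],
    )
    def test_free_end_matches_exhaustive_oracle(self, q, s):
        best_score, identities = oracle_free_end(q, s)
        assert free_end_alignment_score(q, s) == best_score
        score = pairwise_identity(q, s, "free_end_global")
        assert score.identity in identities

    def test_aligned_matches_simple_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = "".join(rng.choice(list("ACGTN-"), 30))
            s = "".join(rng.choice(list("ACGTN-"), 30))
            ours = pairwise_identity(q, s, "aligned").identity
            assert ours == oracle_identity_aligned(q.upper(), s.upper())


class TestAssignmentRule:
    def run(self, identities, species, recorded, threshold=0.95):
        genera = [s.split("_")[0] for s in species]
        return assign_from_identities(
            "q", identities, species, genera, recorded, recorded.split("_")[0],
            threshold,
        )

    def test_rule_satisfied(self):
        res = self.run([0.99, 0.98, 0.90], ["g_A", "g_A", "g_B"], "g_A")
        assert res.outcome == CORRECT and res.assigned_species == "g_A"

    def test_threshold_boundary_is_no_assignment(self):
        res = self.run([0.94, 0.90], ["g_A", "g_B"], "g_A")
        assert res.outcome == NO_ASSIGNMENT

    def test_dominance_violated(self):
        res = self.run([0.96, 0.97], ["g_A", "g_B"], "g_A")
        assert res.outcome == INCORRECT

    def test_tie_counts_as_incorrect(self):
        res = self.run([0.96, 0.96], ["g_A", "g_B"], "g_A")
        assert res.outcome == INCORRECT

    def test_unscorable(self):
        res = self.run([None, None], ["g_A", "g_B"], "g_A")
        assert res.outcome == UNSCORABLE

    def test_vacuous_when_species_absent(self):
        res = self.run([0.99], ["g_B"], "g_A")
        assert res.outcome == VACUOUS

    def test_genus_outcome_derived_from_assigned_species(self):
        # wrong species, right genus: the classic congeneric miss
        res = assign_from_identities(
            "q", [0.99, 0.90], ["Alpha one", "Alpha two"],
            ["Alpha", "Alpha"], "Alpha two", "Alpha", 0.95,
        )
        assert res.genus_outcome == CORRECT
        assert res.assigned_genus == "Alpha"
        # species level: best conspecific is only 0.90 -> below threshold
        assert res.outcome == NO_ASSIGNMENT

    def test_species_correct_implies_genus_correct(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(2, 15))
            sp = [f"g{int(rng.integers(1, 3))} s{int(rng.integers(1, 4))}" for _ in range(n)]
            gn = [s.split()[0] for s in sp]
            idents = [float(np.round(rng.uniform(0.9, 1.0), 3)) for _ in range(n)]
            rec = f"g{int(rng.integers(1, 3))} s{int(rng.integers(1, 4))}"
            res = assign_from_identities("q", idents, sp, gn, rec, rec.split()[0], 0.95)
            if res.outcome == CORRECT:
                assert res.genus_outcome == CORRECT

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_literal_oracle_on_random_databases(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        species = [f"g{int(rng.integers(1, 4))}_s{int(rng.integers(1, 5))}" for _ in range(n)]
        identities = [
            None if rng.random() < 0.1 else float(np.round(rng.uniform(0.8, 1.0), 3))
            for _ in range(n)
        ]
        recorded = f"g{int(rng.integers(1, 4))}_s{int(rng.integers(1, 5))}"
        res = self.run(identities, species, recorded)
        assert res.outcome == oracle_assign(identities, species, recorded, 0.95)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            species = [f"g_s{int(rng.integers(1, 4))}" for _ in range(n)]
            idents = [float(np.round(rng.uniform(0.85, 1.0), 3)) for _ in range(n)]
            recorded = f"g_s{int(rng.integers(1, 4))}"
            lo = self.run(idents, species, recorded, threshold=0.90).outcome
            hi = self.run(idents, species, recorded, threshold=0.97).outcome
            if hi == CORRECT:
                assert lo == CORRECT
            if lo == NO_ASSIGNMENT:
                assert hi == NO_ASSIGNMENT


class TestAssignQuery:
    def test_explicit_database(self):
        db = [
            ("s1", "AAAAAAAAAA", "Alpha one", "Alpha"),
            ("s2", "AAAAAAAAAT", "Alpha one", "Alpha"),
            ("s3", "CCCCCCCCCC", "Beta two", "Beta"),
        ]
        res = bv.assign_query("q", "AAAAAAAAAA", db, "Alpha one", "Alpha")
        assert res.outcome == CORRECT and res.best_identity == 1.0

    def test_empty_database_rejected(self):
        with pytest.raises(bv.ValidationError):
            bv.assign_query("q", "ACGT", [], "A", "A")


def separated_dataset(n_species=4, per=3, length=300, seed=0):
    """Species differ at >5% of sites; conspecifics identical."""
    rng = np.random.default_rng(seed)
    recs, members, rows = [], [], []
    for si in range(n_species):
        base = "".join(rng.choice(list("ACGT"), length))
        genus = f"Gen{si // 2}"
        for k in range(per):
            sid = f"s{si}_{k}"
            recs.append(
                bv.SpecimenRecord(sid, f"{genus} sp{si}", genus, "Fam", "BB")
            )
            members.append(sid)
            rows.append(base)
    return bv.Dataset(recs, {"rbcL": bv.LocusAlignment("rbcL", members, rows)})


class TestLeaveOneOut:
    def test_separated_limit_is_perfect(self):
        ds = separated_dataset()
        rep = bv.evaluate_leave_one_out(ds, ["rbcL"])
        assert rep.species_rate == 100.0 and rep.genus_rate == 100.0

    def test_all_singletons_denominator_zero(self):
        ds = separated_dataset(per=1)
        rep = bv.evaluate_leave_one_out(ds, ["rbcL"])
        assert rep.species_denominator == 0
        assert rep.species_rate is None

    def test_species_rate_never_exceeds_genus_rate(self):
        for seed in range(5):
            cfg = bv.SimConfig(
                n_families=2, genera_per_family=2, species_per_genus=3,
                samples_per_species=2,
                loci=(bv.LocusConfig("rbcL", 400,
                                     inter_species_height=0.02,
                                     intra_species_height=0.003),),
                misid_rate=0.0, between_plot_extra=0.0, seed=seed,
            )
            ds, _ = bv.generate_dataset(cfg)
            rep = bv.evaluate_leave_one_out(ds, ["rbcL"])
            if rep.species_rate is not None and rep.genus_rate is not None:
                assert rep.species_rate <= rep.genus_rate

    def test_empty_combination_rejected(self):
        ds = separated_dataset()
        with pytest.raises(bv.ValidationError):
            bv.evaluate_leave_one_out(ds, [])


class TestCrossPlot:
    def two_plot_dataset(self):
        rng = np.random.default_rng(3)
        recs, members, rows = [], [], []
        for si in range(3):
            base = rng.choice(list("ACGT"), 300)
            for k, plot in enumerate(["BB", "BB", "JJYL"]):
                sid = f"s{si}_{k}"
                recs.append(
                    bv.SpecimenRecord(sid, f"Gen{si} sp", f"Gen{si}", "Fam", plot)
                )
                members.append(sid)
                rows.append("".join(base))
        return bv.Dataset(recs, {"rbcL": bv.LocusAlignment("rbcL", members, rows)})

    def test_db_equals_query_plot_reduces_to_loo(self):
        ds = self.two_plot_dataset()
        bb_only = ds.subset([s.sample_id for s in ds.specimens if s.plot == "BB"])
        loo = bv.evaluate_leave_one_out(bb_only, ["rbcL"])
        (cross,) = bv.evaluate_cross_plot(ds, "BB", ["BB"], ["rbcL"])
        assert cross.species_rate == loo.species_rate
        assert cross.species_denominator == loo.species_denominator

    def test_zero_shared_species_flagged_empty(self):
        rng = np.random.default_rng(4)
        recs, members, rows = [], [], []
        for si, plot in enumerate(["BB", "JJYL"]):
            base = "".join(rng.choice(list("ACGT"), 100))
            for k in range(2):
                sid = f"p{si}_{k}"
                recs.append(
                    bv.SpecimenRecord(sid, f"Gen{si} sp", f"Gen{si}", "Fam", plot)
                )
                members.append(sid)
                rows.append(base)
        ds = bv.Dataset(recs, {"rbcL": bv.LocusAlignment("rbcL", members, rows)})
        (rep,) = bv.evaluate_cross_plot(ds, "BB", ["JJYL"], ["rbcL"])
        assert rep.n_shared_species == 0
        assert rep.species_denominator == 0

    def test_unknown_plot_rejected(self):
        ds = self.two_plot_dataset()
        with pytest.raises(bv.ValidationError, match="unknown plot"):
            bv.evaluate_cross_plot(ds, "NOPE", ["BB"], ["rbcL"])
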
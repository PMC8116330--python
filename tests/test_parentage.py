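from __future__ import annotations

import numpy as np
import pytest

from conftest import mlg
from parthenotrace.errors import SchemaError, UsageError
from parthenotrace.genotypes_io import LocusGenotype
from parthenotrace.parentage import (
    Evidence,
    Verdict,
    assign_paternity,
    classify_offspring,
    locus_parthenote_consistent,
)
from parthenotrace.synthetic_data import (
    default_locus_models,
    simulate_offspring,
    simulate_parthenote,
    simulate_population,
)


class TestLocusEvidence:
    @pytest.mark.parametrize(
        "off,dam,expected",
        [
            ((286, 286), (266, 286), Evidence.HOM_MATERNAL),
            ((289, 289), (289, None), Evidence.HOM_MATERNAL),  # half-missing dam
            ((289, 289), (None, None), Evidence.HOM_MATERNAL),  # unknown dam
            ((200, 202), (200, 202), Evidence.HET),
            ((301, 301), (266, 286), Evidence.NON_MATERNAL_ALLELE),
            ((200, 301), (200, 202), Evidence.NON_MATERNAL_ALLELE),
            ((200, 301), (200, None), Evidence.HET),  # wildcard absorbs
            ((None, None), (266, 286), Evidence.MISSING),
        ],
    )
    def test_cases(self, off, dam, expected):
        assert locus_parthenote_consistent(
            LocusGenotype(*off), LocusGenotype(*dam)
        ) is expected

    def test_half_offspring_cannot_confirm_homozygosity(self):
        assert locus_parthenote_consistent(
            LocusGenotype(194, None), LocusGenotype(194, 200)
        ) is Evidence.HET


LOCI = ("A", "B", "C")


def trio(off_cells, dam_cells=None, sire_cells=None):
    off = mlg("off", dict(zip(LOCI, off_cells)))
    dam = mlg("dam", dict(zip(LOCI, dam_cells))) if dam_cells else None
    sire = mlg("sire", dict(zip(LOCI, sire_cells))) if sire_cells else None
    return off, dam, sire


class TestClassifyOffspring:
    def test_ai_p3_is_parthenote(self, offspring15, known_dams):
        call = classify_offspring(offspring15["AI-P3"], known_dams["307"])
        assert call.verdict is Verdict.PARTHENOTE
        assert call.n_scored == 9
        assert set(call.per_locus.values()) == {Evidence.HOM_MATERNAL}

    def test_p8_consistent_unconfirmed(self, offspring15):
        call = classify_offspring(offspring15["P8"])
        assert call.verdict is Verdict.CONSISTENT_UNCONFIRMED
        assert call.n_scored == 5

    def test_one_missing_locus_still_confirms_by_default(self, offspring15):
        call = classify_offspring(offspring15["P9"])
        assert call.n_scored == 8
        assert call.verdict is Verdict.PARTHENOTE

    def test_strict_mode_demotes_any_missing_locus(self, offspring15):
        call = classify_offspring(offspring15["P9"], max_missing=0)
        assert call.verdict is Verdict.CONSISTENT_UNCONFIRMED

    def test_non_maternal_allele_blocks_parthenote(self):
        off, dam, _ = trio(
            [(1, 1), (2, 2), (9, 9)], [(1, 1), (2, 2), (3, 4)]
        )
        call = classify_offspring(off, dam)
        assert call.verdict is Verdict.MISMATCH  # no sire: allele 9 unexplainable
        assert call.per_locus["C"] is Evidence.NON_MATERNAL_ALLELE

    def test_sexual_with_sire(self):
        off, dam, sire = trio(
            [(1, 5), (2, 6), (3, 7)],
            [(1, 1), (2, 2), (3, 3)],
            [(5, 5), (6, 6), (7, 7)],
        )
        call = classify_offspring(off, dam, sire)
        assert call.verdict is Verdict.SEXUAL
        assert call.n_exclusions == 0
        assert set(call.per_locus.values()) == {Evidence.PATERNAL_MATCH}

    def test_paternal_exclusion_counts(self):
        off, dam, sire = trio(
            [(1, 5), (2, 9), (3, 3)],
            [(1, 1), (2, 2), (3, 3)],
            [(5, 5), (6, 6), (3, 3)],
        )
        call = classify_offspring(off, dam, sire)
        assert call.n_exclusions == 1  # allele 9 not in sire
        assert call.per_locus["B"] is Evidence.PATERNAL_EXCLUSION
        assert call.verdict is Verdict.MISMATCH

    def test_tolerance_forgives_one_exclusion(self):
        off, dam, sire = trio(
            [(1, 5), (2, 9), (3, 3)],
            [(1, 1), (2, 2), (3, 3)],
            [(5, 5), (6, 6), (3, 3)],
        )
        call = classify_offspring(off, dam, sire, tolerance=1)
        assert call.verdict is Verdict.SEXUAL

    def test_panel_mismatch_raises(self):
        off = mlg("off", {"A": (1, 2)})
        dam = mlg("dam", {"B": (1, 2)})
        with pytest.raises(SchemaError):
            classify_offspring(off, dam)

    def test_simulated_sexual_offspring_1000(self, locus_models, rng):
        pop = simulate_population(1, 1, locus_models, rng)
        dam, sire = pop
        for _ in range(1000):
            off = simulate_offspring(dam, sire, rng)
            call = classify_offspring(off, dam, sire)
            # a Mendelian offspring can (rarely) be homozygous everywhere
            assert call.verdict in (Verdict.SEXUAL, Verdict.PARTHENOTE)
            assert call.n_exclusions == 0


class TestInvariants:
    def test_parthenote_soundness_sample(self, locus_models, rng):
        # full soundness at 10,000 draws runs in the acceptance suite
        pop = simulate_population(5, 0, locus_models, rng)
        for dam in pop:
            for _ in range(200):
                off = simulate_parthenote(dam, rng)
                assert classify_offspring(off, dam).verdict is Verdict.PARTHENOTE

    def test_non_maternal_never_parthenote(self, rng):
        dam = mlg("dam", dict(zip(LOCI, [(1, 2), (3, 4), (5, 6)])))
        for _ in range(200):
            cells = {l: (int(rng.integers(1, 7)),) * 2 for l in LOCI}
            bad_locus = str(rng.choice(LOCI))
            cells[bad_locus] = (99, 99)
            call = classify_offspring(mlg("o", cells), dam)
            assert call.verdict not in (
                Verdict.PARTHENOTE,
                Verdict.CONSISTENT_UNCONFIRMED,
            )

    def test_verdict_partition_sums_to_batch(self, locus_models, rng):
        pop = simulate_population(1, 1, locus_models, rng)
        dam, sire = pop
        batch = [simulate_offspring(dam, sire, rng) for _ in range(50)]
        batch += [simulate_parthenote(dam, rng) for _ in range(50)]
        calls = [classify_offspring(o, dam, sire) for o in batch]
        counts = {v: sum(1 for c in calls if c.verdict is v) for v in Verdict}
        assert sum(counts.values()) == len(batch)

    def test_false_positive_rate_matches_closed_form(self):
        # For a fixed parent pair, P(Mendelian offspring PARTHENOTE) is the
        # product over loci of P(maternal draw == paternal draw), computable
        # exactly from the genotypes; it is non-increasing in panel depth.
        from parthenotrace.synthetic_data import LocusModel

        rng = np.random.default_rng(2718)
        models = [LocusModel.equifrequent(f"L{i}", (10, 20)) for i in range(9)]
        dam, sire = simulate_population(1, 1, models, rng)

        def closed_form(loci):
            p = 1.0
            for locus in loci:
                d = dam.genotypes[locus].known_alleles
                s = sire.genotypes[locus].known_alleles
                p *= sum(a == b for a in d for b in s) / 4.0
            return p

        observed = {}
        n = 4000
        for n_loci in (3, 6, 9):
            loci = [m.name for m in models[:n_loci]]
            sub_dam = mlg("d", {l: dam.genotypes[l].known_alleles for l in loci})
            sub_sire = mlg("s", {l: sire.genotypes[l].known_alleles for l in loci})
            fp = sum(
                classify_offspring(
                    simulate_offspring(sub_dam, sub_sire, rng), sub_dam
                ).verdict
                is Verdict.PARTHENOTE
                for _ in range(n)
            )
            p = closed_form(loci)
            sd = np.sqrt(n * p * (1 - p))
            assert abs(fp - n * p) < 5 * sd + 1, n_loci
            observed[n_loci] = fp / n
        # closed form is monotone non-increasing in the number of loci
        ps = [closed_form([m.name for m in models[:k]]) for k in (3, 6, 9)]
        assert ps[0] >= ps[1] >= ps[2]


class TestAssignPaternity:
    def test_true_sire_ranks_first(self, locus_models):
        rng = np.random.default_rng(7)
        wins = 0
        trials = 500
        for _ in range(trials):
            pop = simulate_population(1, 5, locus_models, rng)
            dam, sires = pop[0], pop[1:]
            true = sires[2]
            off = simulate_offspring(dam, true, rng)
            ranked = assign_paternity(off, dam, sires)
            wins += (
                ranked[0].sire_id == true.individual_id
                and ranked[0].n_exclusions == 0
                and ranked[0].accepted
            )
        assert wins / trials >= 0.99  # observed 499/500 at this seed

    def test_parthenote_excludes_no_sire_sharing_alleles(self, locus_models, rng):
        dam, _ = simulate_population(1, 1, locus_models, rng)
        off = simulate_parthenote(dam, rng)
        clone = dam.with_role("sire")
        (res,) = assign_paternity(off, dam, [clone])
        assert res.n_exclusions == 0
        # but the parthenote verdict takes precedence in reporting
        assert classify_offspring(off, dam).verdict is Verdict.PARTHENOTE

    def test_orphan_allele_counts_one_exclusion(self):
        off, dam, sire = trio(
            [(1, 9), (2, 2), (3, 3)],
            [(1, 1), (2, 2), (3, 3)],
            [(4, 4), (2, 2), (3, 3)],
        )
        ranked = assign_paternity(off, dam, [sire])
        assert ranked[0].n_exclusions == 1

    def test_tie_break_is_lexicographic(self):
        off, dam, _ = trio([(1, 5), (2, 2), (3, 3)], [(1, 1), (2, 2), (3, 3)])
        s1 = mlg("zed", dict(zip(LOCI, [(5, 5), (2, 2), (3, 3)])), "sire")
        s2 = mlg("abe", dict(zip(LOCI, [(5, 5), (2, 2), (3, 3)])), "sire")
        ranked = assign_paternity(off, dam, [s1, s2])
        assert [r.sire_id for r in ranked] == ["abe", "zed"]

    def test_empty_candidates(self):
        off, dam, _ = trio([(1, 1), (2, 2), (3, 3)], [(1, 1), (2, 2), (3, 3)])
        with pytest.raises(UsageError):
            assign_paternity(off, dam, [])
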
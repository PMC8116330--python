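"""Classification of offspring against putative parents.

An offspring is called a parthenote when every scored locus is homozygous
for an allele the dam could have supplied.  Offspring with too many failed
loci are demoted to a consistent-but-unconfirmed call.  With a candidate
sire supplied, loci whose non-maternal allele cannot be drawn from the sire
count as paternal exclusions.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import SchemaError, UsageError
from .genotypes_io import MISSING_GENOTYPE, LocusGenotype, MultilocusGenotype

#: default number of failed offspring loci still compatible with a confirmed
#: parthenote call.  One failed locus does not prevent confirmation; more do
#: and demote the verdict to CONSISTENT_UNCONFIRMED.
DEFAULT_MAX_MISSING = 1


class Evidence(str, Enum):
    HOM_MATERNAL = "hom_maternal"
    HET = "het"
    NON_MATERNAL_ALLELE = "non_maternal_allele"
    PATERNAL_MATCH = "paternal_match"
    PATERNAL_EXCLUSION = "paternal_exclusion"
    MISSING = "missing"


class Verdict(str, Enum):
    PARTHENOTE = "PARTHENOTE"
    SEXUAL = "SEXUAL"
    CONSISTENT_UNCONFIRMED = "CONSISTENT_UNCONFIRMED"
    MISMATCH = "MISMATCH"


@dataclass(frozen=True)
class OffspringCall:
    """Classification verdict with per-locus evidence."""

    offspring_id: str
    verdict: Verdict
    per_locus: Mapping[str, Evidence]
    n_scored: int
    n_exclusions: int
    n_dam_exclusions: int = 0


def locus_parthenote_consistent(off: LocusGenotype, dam: LocusGenotype) -> Evidence:
    """Per-locus evidence of parthenote consistency against the dam.

    ``hom_maternal``: offspring is a full homozygote whose allele the dam
    carries (a wildcard slot in a half-missing or missing dam genotype
    matches any allele).  ``non_maternal_allele``: the offspring carries an
    allele absent from the dam's known alleles while the dam has no
    wildcard slot.  ``missing``: offspring locus failed.  ``het``
    otherwise (including half-called offspring loci, which cannot confirm
    homozygosity).  Total function; never raises.
    """
    if off.is_missing:
        return Evidence.MISSING
    if off.is_homozygous:
        if dam.contains(off.a1) or dam.has_wildcard:
            return Evidence.HOM_MATERNAL
        return Evidence.NON_MATERNAL_ALLELE
    # heterozygous or half-called offspring locus
    if not dam.has_wildcard and any(
        a not in dam.known_alleles for a in off.known_alleles
    ):
        return Evidence.NON_MATERNAL_ALLELE
    return Evidence.HET


def _dam_side_exclusion(off: LocusGenotype, dam: LocusGenotype) -> bool:
    """True when the dam could not have donated *any* allele at this locus."""
    if off.is_missing or not off.is_full or dam.has_wildcard:
        return False
    return all(a not in dam.known_alleles for a in off.known_alleles)


def _paternal_evidence(
    off: LocusGenotype, dam: LocusGenotype, sire: LocusGenotype
) -> Evidence:
    """Resolve a non-maternal-allele locus against a candidate sire."""
    non_maternal = [a for a in off.known_alleles if a not in dam.known_alleles]
    if sire.has_wildcard:
        return Evidence.PATERNAL_MATCH
    if all(a in sire.known_alleles for a in set(non_maternal)):
        return Evidence.PATERNAL_MATCH
    return Evidence.PATERNAL_EXCLUSION


def _wildcard_dam(loci) -> dict[str, LocusGenotype]:
    return {locus: MISSING_GENOTYPE for locus in loci}


def classify_offspring(
    off: MultilocusGenotype,
    dam: Optional[MultilocusGenotype] = None,
    sire: Optional[MultilocusGenotype] = None,
    *,
    tolerance: int = 0,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> OffspringCall:
    """Classify one offspring against its putative dam (and optional sire).

    With ``dam=None`` the dam is treated as entirely unknown (every locus a
    wildcard) and the call reduces to a genome-wide homozygosity test, the
    situation for offspring collected from a group habitat.

    Verdicts:

    * ``PARTHENOTE`` — every scored locus ``hom_maternal`` and at most
      ``max_missing`` failed loci.
    * ``CONSISTENT_UNCONFIRMED`` — same evidence but too many failed loci
      to confirm.
    * ``SEXUAL`` — at least one locus shows a heterozygote or a
      non-maternal allele, no locus excludes the dam, and (with a sire
      supplied) at most ``tolerance`` paternal exclusions.
    * ``MISMATCH`` — more unexplainable loci than ``tolerance`` allows.
    """
    if tolerance < 0:
        raise UsageError("tolerance must be non-negative")
    if dam is not None and set(dam.genotypes) != set(off.genotypes):
        raise SchemaError("offspring and dam are genotyped on different panels")
    if sire is not None and set(sire.genotypes) != set(off.genotypes):
        raise SchemaError("offspring and sire are genotyped on different panels")

    loci = list(off.genotypes)
    dam_g = dam.genotypes if dam is not None else _wildcard_dam(loci)

    per_locus: dict[str, Evidence] = {}
    for locus in loci:
        per_locus[locus] = locus_parthenote_consistent(off.genotypes[locus], dam_g[locus])

    n_scored = sum(1 for ev in per_locus.values() if ev is not Evidence.MISSING)
    n_missing = len(loci) - n_scored

    scored = [ev for ev in per_locus.values() if ev is not Evidence.MISSING]
    if all(ev is Evidence.HOM_MATERNAL for ev in scored):
        # fully parthenote-consistent (vacuously so when nothing scored)
        if n_scored > 0 and n_missing <= max_missing:
            verdict = Verdict.PARTHENOTE
        else:
            verdict = Verdict.CONSISTENT_UNCONFIRMED
        return OffspringCall(off.individual_id, verdict, per_locus, n_scored, 0, 0)

    n_dam_exclusions = sum(
        1
        for locus in loci
        if _dam_side_exclusion(off.genotypes[locus], dam_g[locus])
    )

    n_exclusions = 0
    if sire is not None:
        for locus in loci:
            if per_locus[locus] is not Evidence.NON_MATERNAL_ALLELE:
                continue
            if _dam_side_exclusion(off.genotypes[locus], dam_g[locus]):
                continue  # unexplainable regardless of the sire
            ev = _paternal_evidence(off.genotypes[locus], dam_g[locus], sire.genotypes[locus])
            per_locus[locus] = ev
            if ev is Evidence.PATERNAL_EXCLUSION:
                n_exclusions += 1

    if n_dam_exclusions + n_exclusions > tolerance:
        verdict = Verdict.MISMATCH
    else:
        verdict = Verdict.SEXUAL
    return OffspringCall(
        off.individual_id, verdict, per_locus, n_scored, n_exclusions, n_dam_exclusions
    )


@dataclass(frozen=True)
class PaternityCandidate:
    sire_id: str
    n_exclusions: int
    accepted: bool


def assign_paternity(
    off: MultilocusGenotype,
    dam: Optional[MultilocusGenotype],
    candidate_sires: Sequence[MultilocusGenotype],
    *,
    tolerance: int = 0,
) -> list[PaternityCandidate]:
    """Rank candidate sires by paternal-exclusion count.

    Candidates are sorted ascending by exclusions, ties broken
    lexicographically by sire id; a candidate is *accepted* when its
    exclusion count does not exceed ``tolerance``.
    """
    candidates = list(candidate_sires)
    if not candidates:
        raise UsageError("assign_paternity requires at least one candidate sire")
    scored = []
    for sire in candidates:
        call = classify_offspring(off, dam, sire, tolerance=tolerance)
        scored.append((call.n_exclusions, sire.individual_id))
    scored.sort()
    return [
        PaternityCandidate(sid, n_excl, n_excl <= tolerance) for n_excl, sid in scored
    ]
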
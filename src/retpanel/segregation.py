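"""Family cosegregation checks and patient-level diagnostic classification.

Cosegregation assumes full penetrance and no phenocopies: under a given
inheritance model, every affected genotyped relative must carry the
genotype the model requires and no unaffected one may.  This matches how
small diagnostic pedigrees are read qualitatively; it is not a linkage
statistic.

Diagnostic classes partition a cohort:

definite      candidate validated and cosegregating in the family
potential     plausible candidate but no family confirmation possible
              (also digenic two-gene hypotheses pending functional work)
questionable  family evidence contradicts or cannot support the candidate
unsolved      no supportable candidate
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from math import floor

GENOTYPES = ("ref", "het", "hom", "hemi")

EVIDENCE_CATEGORIES = (
    "cosegregates",
    "family_unavailable",
    "digenic_candidate",
    "reported_dominant_unconfirmed",
    "healthy_carrier_relative",
    "non_segregating",
    "single_het_recessive",
    "none_found",
)

DIAGNOSTIC_CLASSES = ("definite", "potential", "questionable", "unsolved")

#: Evidence category → diagnostic class decision table.
CLASSIFICATION_RULES: dict[str, str] = {
    "cosegregates": "definite",
    "family_unavailable": "potential",
    "digenic_candidate": "potential",
    "reported_dominant_unconfirmed": "questionable",
    "healthy_carrier_relative": "questionable",
    "non_segregating": "unsolved",
    "single_het_recessive": "unsolved",
    "none_found": "unsolved",
}


class MendelianInconsistencyWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PedMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # 'M' or 'F'
    affected: bool


@dataclass
class Pedigree:
    members: list[PedMember]
    #: (sample_id, variant_key) -> genotype; absent key means missing
    genotypes: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        ids = {m.sample_id for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValueError(f"{m.sample_id}: parent {pid} not in pedigree")
        for (sid, _), g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValueError(f"{sid}: unknown genotype {g!r}")

    def member(self, sample_id: str) -> PedMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def genotype(self, sample_id: str, variant_key: str) -> str | None:
        return self.genotypes.get((sample_id, variant_key))

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]


@dataclass
class PatientEvidence:
    sample_id: str
    candidates: list  # (variant, gene, inheritance_mode, zygosity, validated)
    evidence_category: str

    def __post_init__(self):
        if self.evidence_category not in EVIDENCE_CATEGORIES:
            raise ValueError(f"unknown evidence category {self.evidence_category!r}")
        if self.evidence_category == "none_found" and self.candidates:
            raise ValueError("none_found requires an empty candidate list")


def _carries(g: str) -> bool:
    return g in ("het", "hom", "hemi")


def check_mendelian(pedigree: Pedigree, variant_key: str) -> list[str]:
    """Sample ids whose genotype is impossible given genotyped parents.

    Only the clear-cut autosomal case is checked: a hom child with a
    genotyped ref parent, or a carrier child of two genotyped ref parents.
    """
    bad = []
    for m in pedigree.members:
        g = pedigree.genotype(m.sample_id, variant_key)
        if g is None:
            continue
        pg = [pedigree.genotype(p, variant_key)
              for p in (m.father_id, m.mother_id) if p is not None]
        pg = [x for x in pg if x is not None]
        if g == "hom" and "ref" in pg:
            bad.append(m.sample_id)
        elif _carries(g) and len(pg) == 2 and all(x == "ref" for x in pg):
            bad.append(m.sample_id)
    return bad


def cosegregates(variant_key: str, pedigree: Pedigree, mode: str,
                 proband: str | None = None) -> str:
    """Does the variant cosegregate with disease under ``mode``?

    Returns 'yes', 'no', or 'unknown' (no informative relative genotyped).
    Rules, assuming full penetrance:

    AD : every genotyped affected carries the variant (het or more) and no
         genotyped unaffected carries it.
    AR : every genotyped affected is hom and no genotyped unaffected is hom
         (het carriers among the healthy are expected).
    XL : affected males hemi; unaffected males ref; affected females must
         carry; unaffected females may be het (carriers) but not hom/hemi.
    """
    if mode not in ("AD", "AR", "XL"):
        raise ValueError(f"unknown inheritance mode {mode!r}")
    genotyped = [m for m in pedigree.members
                 if pedigree.genotype(m.sample_id, variant_key) is not None]
    informative = [m for m in genotyped if m.sample_id != proband]
    if not informative:
        return "unknown"
    if check_mendelian(pedigree, variant_key):
        warnings.warn(f"{variant_key}: mendelian inconsistency in pedigree",
                      MendelianInconsistencyWarning, stacklevel=2)
    for m in genotyped:
        g = pedigree.genotype(m.sample_id, variant_key)
        if mode == "AD":
            if m.affected and not _carries(g):
                return "no"
            if not m.affected and _carries(g):
                return "no"
        elif mode == "AR":
            if m.affected and g != "hom":
                return "no"
            if not m.affected and g == "hom":
                return "no"
        else:  # XL
            if m.sex == "M":
                if m.affected and g != "hemi":
                    return "no"
                if not m.affected and g != "ref":
                    return "no"
            else:
                if m.affected and not _carries(g):
                    return "no"
                if not m.affected and g in ("hom", "hemi"):
                    return "no"
    return "yes"


def compound_het_cosegregates(variant_keys: tuple[str, str], pedigree: Pedigree,
                              proband: str | None = None) -> str:
    """Recessive cosegregation for a compound-heterozygote pair (phase unknown).

    'yes' iff every genotyped affected carries both alleles and no genotyped
    unaffected does.
    """
    a, b = variant_keys
    genotyped = [m for m in pedigree.members
                 if pedigree.genotype(m.sample_id, a) is not None
                 and pedigree.genotype(m.sample_id, b) is not None]
    informative = [m for m in genotyped if m.sample_id != proband]
    if not informative:
        return "unknown"
    for m in genotyped:
        both = (_carries(pedigree.genotype(m.sample_id, a))
                and _carries(pedigree.genotype(m.sample_id, b)))
        if m.affected and not both:
            return "no"
        if not m.affected and both:
            return "no"
    return "yes"


def classify_patient(evidence: PatientEvidence) -> str:
    """Map a patient's evidence category to the diagnostic class."""
    try:
        return CLASSIFICATION_RULES[evidence.evidence_category]
    except KeyError:  # pragma: no cover - PatientEvidence validates already
        raise ValueError(f"unknown evidence category {evidence.evidence_category!r}")


def _round_half_away(x: float) -> int:
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


def cohort_yield(classes: list[str]) -> tuple[dict[str, int], dict[str, int]]:
    """Counts and integer percentages per diagnostic class.

    Percentages round half away from zero.
    """
    if not classes:
        raise ValueError("empty cohort")
    counts = Counter(classes)
    n = len(classes)
    count_map = {c: counts.get(c, 0) for c in DIAGNOSTIC_CLASSES}
    pct_map = {c: _round_half_away(100.0 * count_map[c] / n) for c in DIAGNOSTIC_CLASSES}
    return count_map, pct_map
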
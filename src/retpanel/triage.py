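"""The variant triage cascade: coding → known-SNP removal → protein-changing
→ read-fraction threshold → prioritization.

The read-fraction threshold separates real heterozygous calls (~50% of
reads) from pyrosequencing artifacts that typically sit at low allele
balance.  Three policies are supported: a fixed 20% cutoff, a stringent 35%
cutoff (low-fraction calls repeatedly failed confirmatory Sanger
sequencing), and a dynamic descent that starts high (50%) and relaxes in 5%
steps until one or two candidates survive, never dropping below the 20%
floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import Consequence, VariantCall, default_deleteriousness

PROTEIN_CHANGING = frozenset({"missense", "nonsense", "frameshift", "inframe_indel"})


@dataclass(frozen=True)
class AnnotatedVariant:
    call: VariantCall
    consequence: Consequence
    gene_symbol: str
    known_snp: bool = False
    known_reported: bool = False
    zygosity: str | None = None  # inferred from fraction when not given

    @property
    def fraction(self) -> float:
        return self.call.fraction

    def inferred_zygosity(self, hom_cutoff: float = 0.8) -> str:
        if self.zygosity is not None:
            return self.zygosity
        return "hom" if self.fraction >= hom_cutoff else "het"


@dataclass(frozen=True)
class ThresholdPolicy:
    mode: str = "fixed"  # fixed | stringent | dynamic
    fixed_value: float = 0.20
    stringent_value: float = 0.35
    dynamic_start: float = 0.50
    dynamic_step: float = 0.05
    dynamic_floor: float = 0.20
    dynamic_target: tuple[int, int] = (1, 2)

    def __post_init__(self):
        if self.mode not in ("fixed", "stringent", "dynamic"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.dynamic_floor > self.dynamic_start:
            raise ValueError("dynamic_floor > dynamic_start")
        if self.dynamic_step <= 0:
            raise ValueError("dynamic_step must be > 0")


@dataclass
class FilterTrace:
    n_total: int
    n_coding: int
    n_after_snp_removal: int
    n_protein_changing: int
    n_after_fraction: int
    n_prioritized: int
    threshold_used: float
    survivors: list[AnnotatedVariant] = field(default_factory=list)

    def counts(self) -> tuple[int, ...]:
        return (self.n_total, self.n_coding, self.n_after_snp_removal,
                self.n_protein_changing, self.n_after_fraction, self.n_prioritized)

    def __post_init__(self):
        c = self.counts()
        if any(a < b for a, b in zip(c, c[1:])):
            raise ValueError(f"filter trace counts increase along stages: {c}")


def dynamic_threshold(variants: list[AnnotatedVariant],
                      policy: ThresholdPolicy) -> tuple[float, list[AnnotatedVariant]]:
    """Descend from ``dynamic_start`` in ``dynamic_step`` decrements until the
    survivor count reaches the target band (>= 1), clamping at the floor.

    If a step jumps straight past the band (0 survivors at one threshold,
    more than two at the next) the first threshold with any survivor wins.
    """
    if policy.mode != "dynamic":
        raise ValueError("dynamic_threshold requires a dynamic policy")
    t = policy.dynamic_start
    while True:
        t = round(t, 10)
        survivors = [v for v in variants if v.fraction >= t]
        if len(survivors) >= policy.dynamic_target[0]:
            return t, survivors
        if t - policy.dynamic_step < policy.dynamic_floor - 1e-9:
            return policy.dynamic_floor, [v for v in variants
                                          if v.fraction >= policy.dynamic_floor]
        t -= policy.dynamic_step


def _threshold_for(policy: ThresholdPolicy) -> float:
    return policy.fixed_value if policy.mode == "fixed" else policy.stringent_value


def prioritize(survivors: list[AnnotatedVariant],
               inheritance_hint: str | None = None,
               scorer=default_deleteriousness) -> list[AnnotatedVariant]:
    """Rank candidates: known reported mutations first, then inheritance
    compatibility with the family's mode, then predicted deleteriousness,
    then read fraction; ties break on genomic position."""
    het_per_gene: dict[str, int] = {}
    for v in survivors:
        if v.inferred_zygosity() == "het":
            het_per_gene[v.gene_symbol] = het_per_gene.get(v.gene_symbol, 0) + 1

    def compat(v: AnnotatedVariant) -> int:
        if inheritance_hint is None:
            return 1
        z = v.inferred_zygosity()
        if inheritance_hint == "AR":
            return int(z == "hom" or het_per_gene.get(v.gene_symbol, 0) >= 2)
        return int(z in ("het", "hemi"))  # AD / XL

    return sorted(
        survivors,
        key=lambda v: (-int(v.known_reported), -compat(v), -scorer(v.consequence),
                       -v.fraction, v.call.contig, v.call.position))


def inheritance_compatible(v: AnnotatedVariant, hint: str | None,
                           het_per_gene: dict[str, int]) -> bool:
    if hint is None:
        return True
    z = v.inferred_zygosity()
    if hint == "AR":
        return z == "hom" or het_per_gene.get(v.gene_symbol, 0) >= 2
    return z in ("het", "hemi")


def filter_cascade(variants: list[AnnotatedVariant],
                   policy: ThresholdPolicy | None = None,
                   inheritance_hint: str | None = None,
                   scorer=default_deleteriousness) -> FilterTrace:
    """Apply the full cascade and record per-stage survivor counts."""
    policy = policy or ThresholdPolicy()
    coding = [v for v in variants if v.consequence.region == "coding"]
    novel = [v for v in coding if not v.known_snp]
    protein = [v for v in novel if v.consequence.effect in PROTEIN_CHANGING]

    if policy.mode == "dynamic":
        threshold, after_fraction = dynamic_threshold(protein, policy)
    else:
        threshold = _threshold_for(policy)
        after_fraction = [v for v in protein if v.fraction >= threshold]

    ranked = prioritize(after_fraction, inheritance_hint, scorer)
    het_per_gene: dict[str, int] = {}
    for v in after_fraction:
        if v.inferred_zygosity() == "het":
            het_per_gene[v.gene_symbol] = het_per_gene.get(v.gene_symbol, 0) + 1
    prioritized = [v for v in ranked
                   if inheritance_compatible(v, inheritance_hint, het_per_gene)]

    return FilterTrace(
        n_total=len(variants),
        n_coding=len(coding),
        n_after_snp_removal=len(novel),
        n_protein_changing=len(protein),
        n_after_fraction=len(after_fraction),
        n_prioritized=len(prioritized),
        threshold_used=threshold,
        survivors=prioritized,
    )
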
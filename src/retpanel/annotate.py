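"""Variant annotation: coding consequence, known-SNP membership, repeat context.

Consequences are computed by mutating the spliced coding sequence and
comparing the reference and alternate translations, which handles both
strands, multi-base substitutions and in-frame/frameshift indels uniformly
and naturally right-aligns duplications the way protein-level nomenclature
does.  Protein changes use the short panel style ``p.<GENE>-<ref><pos><alt>``
with ``X`` for a stop gained, and ``del``/``dup``/``ins``/``fs`` suffixes
for indels.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .grantham import MAX_GRANTHAM, grantham_distance
from .panel import GeneModel

REGIONS = ("coding", "utr5", "utr3", "promoter", "intronic_flank")
EFFECTS = ("synonymous", "missense", "nonsense", "frameshift",
           "inframe_indel", "stoploss", "none")


@dataclass(frozen=True)
class VariantCall:
    """One called sequence difference with its read support.

    ``position`` is 0-based; ``ref_allele`` is empty for a pure insertion
    (inserted before ``position``) and ``alt_allele`` empty for a pure
    deletion.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    total_reads: int
    variant_reads: int
    sample_id: str = ""

    def __post_init__(self):
        if not 0 <= self.variant_reads <= self.total_reads:
            raise ValueError("variant_reads outside [0, total_reads]")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def fraction(self) -> float:
        return self.variant_reads / self.total_reads if self.total_reads else 0.0

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref_allele or '-'}>{self.alt_allele or '-'}"


@dataclass(frozen=True)
class Consequence:
    region: str
    effect: str
    protein_change: str = ""
    grantham: int | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect != "none" and self.region != "coding":
            raise ValueError("a protein effect requires a coding region")


@dataclass(frozen=True)
class SnpCatalogEntry:
    contig: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    identifier: str = ""

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(cds: str) -> str:
    usable = cds[: len(cds) // 3 * 3]
    return str(Seq(usable).translate())


def _spliced_offset(intervals, pos: int) -> int | None:
    """Offset of genomic pos in the concatenated (plus-orientation) intervals."""
    acc = 0
    for s, e in intervals:
        if s <= pos < e:
            return acc + (pos - s)
        acc += e - s
    return None


def _span_in_one_interval(intervals, start: int, end: int) -> bool:
    """[start, end) lies in a single interval; a point (start==end) must be interior."""
    for s, e in intervals:
        if start == end:
            if s < start < e:
                return True
        elif s <= start and end <= e:
            return True
    return False


def _overlaps(intervals, start: int, end: int) -> bool:
    pe = end if end > start else start + 1
    return any(min(e, pe) > max(s, start) for s, e in intervals)


def classify_consequence(v: VariantCall, gene: GeneModel,
                         reference: dict[str, str],
                         promoter_bp: int = 1000) -> Consequence:
    """Classify a variant's region and protein-level effect on one gene."""
    contig_seq = reference[gene.contig]
    ref_len = len(v.ref_allele)
    if ref_len and contig_seq[v.position:v.position + ref_len] != v.ref_allele:
        raise ValueError(
            f"reference mismatch at {gene.contig}:{v.position + 1}: expected "
            f"{v.ref_allele!r}, reference has "
            f"{contig_seq[v.position:v.position + ref_len]!r}")

    span = (v.position, v.position + ref_len)

    # region: promoter window upstream of the transcription start
    if gene.strand == "+":
        pstart, pend = gene.exons[0][0] - promoter_bp, gene.exons[0][0]
    else:
        pstart, pend = gene.exons[-1][1], gene.exons[-1][1] + promoter_bp
    pstart = max(0, pstart)

    in_one_exon = _span_in_one_interval(gene.exons, *span)
    touches_exon = _overlaps(gene.exons, *span)

    if touches_exon and not in_one_exon:
        # spans a splice (exon) boundary
        return Consequence("intronic_flank", "none")
    if not touches_exon:
        if _overlaps([(pstart, pend)], *span):
            return Consequence("promoter", "none")
        return Consequence("intronic_flank", "none")

    if gene.cds and _span_in_one_interval(gene.cds, *span):
        return _coding_consequence(v, gene, contig_seq)
    if _overlaps(gene.utr5, *span):
        return Consequence("utr5", "none")
    if _overlaps(gene.utr3, *span):
        return Consequence("utr3", "none")
    if gene.cds and _overlaps(gene.cds, *span):
        # partially coding (crosses a CDS edge inside the exon)
        return Consequence("coding", "none")
    # exonic but not annotated as CDS or UTR
    return Consequence("coding", "none") if not gene.cds else Consequence("intronic_flank", "none")


def _coding_consequence(v: VariantCall, gene: GeneModel, contig_seq: str) -> Consequence:
    plus = "".join(contig_seq[s:e] for s, e in gene.cds)
    n = len(plus)
    a = _spliced_offset(gene.cds, v.position)
    if a is None:  # insertion point at an interval edge
        return Consequence("intronic_flank", "none")
    b = a + len(v.ref_allele)
    alt_plus = plus[:a] + v.alt_allele + plus[b:]
    if gene.strand == "+":
        ref_cds, alt_cds = plus, alt_plus
        aa_hint = a // 3
    else:
        ref_cds = _revcomp(plus)
        alt_cds = ref_cds[: n - b] + _revcomp(v.alt_allele) + ref_cds[n - a:]
        aa_hint = (n - b) // 3 if b > a else max(0, (n - a - 1)) // 3
    p_ref, p_alt = _translate(ref_cds), _translate(alt_cds)
    g = gene.gene_symbol
    dlen = len(v.alt_allele) - len(v.ref_allele)

    if dlen == 0:
        diffs = [i for i, (x, y) in enumerate(zip(p_ref, p_alt)) if x != y]
        if not diffs:
            aa = p_ref[aa_hint] if aa_hint < len(p_ref) else "?"
            return Consequence("coding", "synonymous",
                               f"p.{g}-{_aa(aa)}{aa_hint + 1}{_aa(aa)}")
        i = diffs[0]
        ref_aa, alt_aa = p_ref[i], p_alt[i]
        change = f"p.{g}-{_aa(ref_aa)}{i + 1}{_aa(alt_aa)}"
        if alt_aa == "*":
            return Consequence("coding", "nonsense", change, MAX_GRANTHAM)
        if ref_aa == "*":
            return Consequence("coding", "stoploss", change)
        return Consequence("coding", "missense", change,
                           grantham_distance(ref_aa, alt_aa))

    if dlen % 3 != 0:
        i = 0
        while i < min(len(p_ref), len(p_alt)) and p_ref[i] == p_alt[i]:
            i += 1
        aa = p_ref[i] if i < len(p_ref) else "*"
        return Consequence("coding", "frameshift", f"p.{g}-{_aa(aa)}{i + 1}fs",
                           MAX_GRANTHAM)

    return Consequence("coding", "inframe_indel",
                       _inframe_label(g, p_ref, p_alt), None)


def _aa(x: str) -> str:
    return "X" if x == "*" else x


def _inframe_label(g: str, p_ref: str, p_alt: str) -> str:
    pre = 0
    while pre < min(len(p_ref), len(p_alt)) and p_ref[pre] == p_alt[pre]:
        pre += 1
    suf = 0
    while (suf < min(len(p_ref), len(p_alt)) - pre
           and p_ref[len(p_ref) - 1 - suf] == p_alt[len(p_alt) - 1 - suf]):
        suf += 1
    ref_mid = p_ref[pre:len(p_ref) - suf]
    alt_mid = p_alt[pre:len(p_alt) - suf]
    if alt_mid and not ref_mid:
        k = len(alt_mid)
        if pre >= k and p_alt[pre - k:pre] == alt_mid:  # tandem duplication
            first, last = pre - k + 1, pre
            if k == 1:
                return f"p.{g}-{_aa(alt_mid[0])}{first}dup"
            return f"p.{g}-{_aa(alt_mid[0])}{first}_{_aa(alt_mid[-1])}{last}dup"
        left = f"{_aa(p_ref[pre - 1])}{pre}" if pre else "0"
        right = f"{_aa(p_ref[pre])}{pre + 1}" if pre < len(p_ref) else "ter"
        return f"p.{g}-{left}_{right}ins{''.join(_aa(x) for x in alt_mid)}"
    if ref_mid and not alt_mid:
        first, last = pre + 1, pre + len(ref_mid)
        if len(ref_mid) == 1:
            return f"p.{g}-{_aa(ref_mid[0])}{first}del"
        return f"p.{g}-{_aa(ref_mid[0])}{first}_{_aa(ref_mid[-1])}{last}del"
    if ref_mid and alt_mid:
        first, last = pre + 1, pre + len(ref_mid)
        return (f"p.{g}-{_aa(ref_mid[0])}{first}_{_aa(ref_mid[-1])}{last}"
                f"delins{''.join(_aa(x) for x in alt_mid)}")
    return f"p.{g}-(=)"


def is_known_snp(v: VariantCall, catalog: set) -> bool:
    """Exact (contig, position, ref, alt) membership in the SNP catalog.

    Positional-only matches do not count: a novel allele at a polymorphic
    site must survive the known-SNP filter.
    """
    keys = {e.key() if isinstance(e, SnpCatalogEntry) else tuple(e) for e in catalog}
    return (v.contig, v.position, v.ref_allele, v.alt_allele) in keys


def repeat_flag(v: VariantCall, reference: dict[str, str], max_run: int = 6) -> bool:
    """True if the variant lies in or immediately adjoins a homopolymer run
    of length >= max_run (the pyrosequencing error context)."""
    seq = reference[v.contig]
    span_start = v.position
    span_end = v.position + max(len(v.ref_allele), 1)
    w0 = max(0, span_start - 2 * max_run)
    w1 = min(len(seq), span_end + 2 * max_run)
    window = seq[w0:w1]
    i = 0
    while i < len(window):
        j = i
        while j < len(window) and window[j] == window[i]:
            j += 1
        if j - i >= max_run:
            rs, re = w0 + i, w0 + j
            if rs <= span_end and re >= span_start:  # overlap or touch
                return True
        i = j
    return False


def default_deleteriousness(consequence: Consequence) -> float:
    """Pluggable scorer default: Grantham for missense, maximal for
    truncating changes, 0 otherwise."""
    if consequence.effect in ("nonsense", "frameshift"):
        return float(MAX_GRANTHAM)
    if consequence.effect == "missense":
        return float(consequence.grantham or 0)
    if consequence.effect == "inframe_indel":
        return float(MAX_GRANTHAM) / 2
    return 0.0


# --------------------------------------------------------------- exports

def write_annotated_tsv(rows, path) -> None:
    """TSV of (VariantCall, Consequence[, extra dict]) tuples."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["contig", "position", "ref_allele", "alt_allele", "total_reads",
                    "variant_reads", "fraction", "region", "effect", "protein_change",
                    "grantham"])
        for item in rows:
            v, c = item[0], item[1]
            w.writerow([v.contig, v.position + 1, v.ref_allele or "-",
                        v.alt_allele or "-", v.total_reads, v.variant_reads,
                        f"{v.fraction:.3f}", c.region, c.effect, c.protein_change,
                        "" if c.grantham is None else c.grantham])


def write_minimal_vcf(rows, path, reference_name: str = ".") -> None:
    """Minimal VCF 4.2 export with the consequence in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Gene region">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Protein effect">\n')
        fh.write('##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for item in rows:
            v, c = item[0], item[1]
            info = f"REGION={c.region};EFFECT={c.effect}"
            if c.protein_change:
                info += f";PCHANGE={c.protein_change}"
            fh.write(f"{v.contig}\t{v.position + 1}\t.\t{v.ref_allele or '.'}\t"
                     f"{v.alt_allele or '.'}\t.\t.\t{info}\n")
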
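import numpy as np
import pytest

from retpanel import GeneModel, build_targets
from retpanel.simulate import random_reference


@pytest.fixture(scope="session")
def toy_reference():
    """5 kb random contig, fixed seed."""
    return random_reference({"chr1": 5000}, seed=11)


@pytest.fixture
def make_cds_gene():
    """Factory: a single-exon gene whose exon equals its CDS, embedded in a
    reference contig at a given offset."""

    def _make(cds_seq: str, offset: int = 100, strand: str = "+",
              symbol: str = "TOY", pad: int = 100):
        if strand == "+":
            contig = "A" * offset + cds_seq + "A" * pad
            exon = (offset, offset + len(cds_seq))
        else:
            from Bio.Seq import Seq
            rc = str(Seq(cds_seq).reverse_complement())
            contig = "A" * offset + rc + "A" * pad
            exon = (offset, offset + len(cds_seq))
        gene = GeneModel(symbol, "ctg", strand, (exon,), cds=(exon,))
        return gene, {"ctg": contig}

    return _make


@pytest.fixture
def toy_multi_exon_gene(toy_reference):
    """5-exon plus-strand gene with CDS over all exons (600 bp)."""
    exons = tuple((1500 + i * 300, 1500 + i * 300 + 120) for i in range(5))
    gene = GeneModel("TOY", "chr1", "+", exons, cds=exons,
                     inheritance_modes=frozenset({"AD"}))
    panel = build_targets([gene], contig_lengths={"chr1": 5000})
    return gene, panel


def brute_force_union_bp(intervals_by_contig) -> int:
    """Base-set cardinality of a union of intervals (oracle)."""
    total = 0
    per_contig = {}
    for contig, s, e in intervals_by_contig:
        per_contig.setdefault(contig, set()).update(range(s, e))
    for bases in per_contig.values():
        total += len(bases)
    return total


@pytest.fixture
def union_oracle():
    return brute_force_union_bp
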
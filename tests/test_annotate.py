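import numpy as np
import pytest

from retpanel import (SnpCatalogEntry, VariantCall, classify_consequence,
                      is_known_snp, repeat_flag)
from retpanel.grantham import GRANTHAM, MAX_GRANTHAM, grantham_distance
from retpanel.simulate import random_reference

# Independent standard-genetic-code oracle (TCAG-order amino acid string).
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {b1 + b2 + b3: _AA[16 * i + 4 * j + k]
               for i, b1 in enumerate(_BASES)
               for j, b2 in enumerate(_BASES)
               for k, b3 in enumerate(_BASES)}


def _snv(contig, pos, ref, alt, total=100, var=50):
    return VariantCall(contig, pos, ref, alt, total, var)


class TestClassifyConsequence:
    def test_nonsense_example(self, make_cds_gene):
        gene, ref = make_cds_gene("ATGGAGGATTAA")
        # cds position 4 (1-based) G->T: codon GAG -> TAG, E2X
        v = _snv("ctg", 100 + 3, "G", "T")
        c = classify_consequence(v, gene, ref)
        assert c.effect == "nonsense"
        assert c.protein_change == "p.TOY-E2X"
        assert c.grantham == MAX_GRANTHAM

    def test_synonymous_stop(self, make_cds_gene):
        gene, ref = make_cds_gene("ATGGAGGATTAA")
        # cds position 12 A->G: TAA -> TAG, both stops
        v = _snv("ctg", 100 + 11, "A", "G")
        c = classify_consequence(v, gene, ref)
        assert c.effect == "synonymous"

    def test_inframe_duplication_named_dup(self, make_cds_gene):
        # ATG TTC GCC TAA; duplicate TTCGCC after it -> F2_A3dup
        gene, ref = make_cds_gene("ATGTTCGCCTAA")
        v = VariantCall("ctg", 100 + 9, "", "TTCGCC", 100, 50)
        c = classify_consequence(v, gene, ref)
        assert c.effect == "inframe_indel"
        assert c.protein_change == "p.TOY-F2_A3dup"

    def test_frameshift(self, make_cds_gene):
        gene, ref = make_cds_gene("ATGGAGGATCCGTAA")
        v = VariantCall("ctg", 100 + 4, "A", "", 100, 50)  # 1-bp deletion
        c = classify_consequence(v, gene, ref)
        assert c.effect == "frameshift"
        assert c.protein_change.endswith("fs")

    def test_reference_mismatch_names_position(self, make_cds_gene):
        gene, ref = make_cds_gene("ATGGAGGATTAA")
        wrong = "C" if ref["ctg"][103] != "C" else "G"
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_consequence(_snv("ctg", 103, wrong, "T"), gene, ref)

    def test_splice_boundary_spanning_variant(self, make_cds_gene):
        gene, ref = make_cds_gene("ATGGAGGATTAA")
        # deletion starting inside the exon and running past its end
        start = gene.exons[0][1] - 2
        refseq = ref["ctg"][start:start + 5]
        v = VariantCall("ctg", start, refseq, "", 100, 50)
        c = classify_consequence(v, gene, ref)
        assert (c.region, c.effect) == ("intronic_flank", "none")

    def test_promoter_and_flank_regions(self, make_cds_gene):
        gene, ref = make_cds_gene("ATGGAGGATTAA", offset=2000, pad=2000)
        up = _snv("ctg", 1500, ref["ctg"][1500], "T"
                  if ref["ctg"][1500] != "T" else "G")
        assert classify_consequence(up, gene, ref).region == "promoter"
        far = _snv("ctg", 100, ref["ctg"][100], "T" if ref["ctg"][100] != "T" else "G")
        assert classify_consequence(far, gene, ref).region == "intronic_flank"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_codon_changes_match_oracle(self, make_cds_gene, strand):
        """All 576 single-base codon substitutions agree with the independent
        codon table, on both strands."""
        from Bio.Seq import Seq
        n_checked = 0
        for codon, ref_aa in CODON_TABLE.items():
            gene, ref = make_cds_gene(codon, strand=strand)
            for i in range(3):
                for alt_base in "ACGT":
                    if alt_base == codon[i]:
                        continue
                    alt_codon = codon[:i] + alt_base + codon[i + 1:]
                    alt_aa = CODON_TABLE[alt_codon]
                    if strand == "+":
                        pos, r, a = 100 + i, codon[i], alt_base
                    else:
                        pos = 100 + (2 - i)
                        r = str(Seq(codon[i]).complement())
                        a = str(Seq(alt_base).complement())
                    c = classify_consequence(_snv("ctg", pos, r, a), gene, ref)
                    if ref_aa == alt_aa:
                        expected = "synonymous"
                    elif alt_aa == "*":
                        expected = "nonsense"
                    elif ref_aa == "*":
                        expected = "stoploss"
                    else:
                        expected = "missense"
                    assert c.effect == expected, (codon, i, alt_base, strand)
                    if expected in ("missense", "nonsense"):
                        # protein_change parses back
                        body = c.protein_change.split("-", 1)[1]
                        assert body[0] == ("X" if ref_aa == "*" else ref_aa)
                        assert body[-1] == ("X" if alt_aa == "*" else alt_aa)
                        assert int(body[1:-1]) == 1
                    n_checked += 1
        assert n_checked == 576

    def test_strand_symmetry_on_multicodon_cds(self, make_cds_gene):
        cds = "ATGGAGGATCGCTTTAAATAA"
        for i in range(3, len(cds) - 3):
            for alt in "ACGT":
                if alt == cds[i]:
                    continue
                gp, rp = make_cds_gene(cds, strand="+")
                cp = classify_consequence(_snv("ctg", 100 + i, cds[i], alt), gp, rp)
                from Bio.Seq import Seq
                gm, rm = make_cds_gene(cds, strand="-")
                pos_m = 100 + (len(cds) - 1 - i)
                cm = classify_consequence(
                    _snv("ctg", pos_m, str(Seq(cds[i]).complement()),
                         str(Seq(alt).complement())), gm, rm)
                assert cp == cm


class TestKnownSnp:
    def test_exact_match(self):
        cat = {SnpCatalogEntry("chr1", 10, "A", "G", "rs1")}
        assert is_known_snp(_snv("chr1", 10, "A", "G"), cat)

    def test_different_alt_is_not_known(self):
        cat = {SnpCatalogEntry("chr1", 10, "A", "G", "rs1")}
        assert not is_known_snp(_snv("chr1", 10, "A", "T"), cat)

    def test_random_against_set_intersection_oracle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        def rand_key():
            pos = int(rng.integers(0, 500))
            ref, alt = rng.choice(bases, size=2, replace=False)
            return ("chr1", pos, str(ref), str(alt))
        catalog_keys = {rand_key() for _ in range(300)}
        catalog = {SnpCatalogEntry(*k, identifier=f"rs{i}")
                   for i, k in enumerate(catalog_keys)}
        variants = [rand_key() for _ in range(1000)]
        n_match = sum(is_known_snp(_snv(*k), catalog) for k in variants)
        assert n_match == sum(k in catalog_keys for k in variants)
        assert n_match > 0  # the instance actually exercises both branches


class TestRepeatFlag:
    def test_homopolymer_indel_flagged(self):
        ref = {"c": "GGG" + "AAAAAAA" + "CTCTCT"}
        v = VariantCall("c", 5, "A", "", 100, 30)
        assert repeat_flag(v, ref, max_run=6)

    def test_mixed_context_not_flagged(self):
        ref = {"c": "ACGTACGTACGTACG"}
        assert not repeat_flag(_snv("c", 7, "T", "C"), ref, max_run=6)

    def test_scan_against_brute_force(self):
        ref = random_reference({"c": 10_000}, seed=9, gc=0.2)  # AT-rich -> runs
        seq = ref["c"]
        # brute-force: all maximal runs >= 6, flag positions touching them
        runs = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= 6:
                runs.append((i, j))
            i = j
        assert runs, "fixture must contain at least one long run"
        rng = np.random.default_rng(9)
        for pos in rng.integers(0, len(seq) - 1, size=2000):
            pos = int(pos)
            expected = any(rs <= pos + 1 and re >= pos for rs, re in runs)
            v = _snv("c", pos, seq[pos], "T" if seq[pos] != "T" else "G")
            assert repeat_flag(v, ref) == expected, pos


class TestGrantham:
    def test_symmetry_and_extremes(self):
        for (a, b), d in GRANTHAM.items():
            assert GRANTHAM[(b, a)] == d
        assert grantham_distance("L", "I") == 5
        assert grantham_distance("C", "W") == 215
        assert max(v for k, v in GRANTHAM.items() if k[0] != k[1]) == 215
        assert min(v for k, v in GRANTHAM.items() if k[0] != k[1]) == 5


def test_variant_call_invariants():
    with pytest.raises(ValueError):
        VariantCall("c", 0, "A", "A", 10, 5)
    with pytest.raises(ValueError):
        VariantCall("c", 0, "A", "G", 10, 11)
    assert VariantCall("c", 0, "A", "G", 0, 0).fraction == 0.0
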
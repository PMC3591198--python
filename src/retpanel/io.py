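"""Readers/writers for the tab-separated dialects used by the pipeline.

All on-disk positions are 1-based (mapper convention); in-memory coordinates
are 0-based half-open.  Conversion happens here and nowhere else.

Dialects
--------
variant table ("HCDiffs")
    header line starting with '>', then columns
    contig, start(1-based), end(1-based inclusive), ref_allele, alt_allele,
    total_reads, variant_reads, variant_pct.  '-' denotes an empty allele
    (pure insertion/deletion).
coverage file ("AlignmentInfo")
    columns contig, position(1-based), ref_base, avg_quality, unique_depth —
    depth is deliberately column 5 and quality column 4.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import pandas as pd

from .panel import GeneModel, TargetInterval, merge_plain_intervals

HCDIFFS_COLUMNS = ["contig", "start", "end", "ref_allele", "alt_allele",
                   "total_reads", "variant_reads", "variant_pct"]
ALIGNMENT_INFO_COLUMNS = ["contig", "position", "ref_base", "avg_quality", "unique_depth"]


# ---------------------------------------------------------------- variants

def write_hcdiffs(df: pd.DataFrame, path: str | Path, sample_id: str = "sample") -> None:
    """Write a variant table (0-based in memory → 1-based on disk)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{sample_id}\t" + "\t".join(HCDIFFS_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            ref = row.ref_allele or "-"
            alt = row.alt_allele or "-"
            start0, ref_len = int(row.position), len(row.ref_allele)
            start1 = start0 + 1
            end1 = start0 + ref_len if ref_len else start0  # insertion anchors before start1
            pct = 100.0 * row.variant_reads / row.total_reads if row.total_reads else 0.0
            fh.write(f"{row.contig}\t{start1}\t{end1}\t{ref}\t{alt}\t"
                     f"{int(row.total_reads)}\t{int(row.variant_reads)}\t{pct:.1f}\n")


def read_hcdiffs(path: str | Path) -> pd.DataFrame:
    """Read a variant table back to 0-based in-memory form."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(">"):
                continue
            c, s1, e1, ref, alt, tot, var, pct = line.split("\t")
            ref = "" if ref == "-" else ref
            alt = "" if alt == "-" else alt
            rows.append({
                "contig": c,
                "position": int(s1) - 1 if ref else int(e1),  # insertion point after end1
                "ref_allele": ref, "alt_allele": alt,
                "total_reads": int(tot), "variant_reads": int(var),
                "variant_pct": float(pct),
            })
    return pd.DataFrame(rows, columns=HCDIFFS_COLUMNS[:1] + ["position"] + HCDIFFS_COLUMNS[3:])


# ---------------------------------------------------------------- coverage

def write_alignment_info(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["position"] = out["position"].astype(int) + 1
    out[ALIGNMENT_INFO_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_alignment_info(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=ALIGNMENT_INFO_COLUMNS)
    df["position"] = df["position"].astype(int) - 1
    return df


# ---------------------------------------------------------------- gene models

_FEATURES = {"exon", "CDS", "5UTR", "3UTR"}


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from the one-row-per-feature TSV.

    Columns: gene_symbol, contig, strand, start(1-based), end(1-based
    inclusive), feature ∈ {exon, CDS, 5UTR, 3UTR}, inheritance (comma-joined
    subset of AD/AR/XL, '.' if unknown).  Rows with unknown strand are
    rejected with a warning.  Overlapping exon rows (alternative transcripts)
    are merged into their union.
    """
    acc: dict[str, dict] = {}
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sym = row["gene_symbol"]
            if row["strand"] not in ("+", "-"):
                warnings.warn(f"{sym}: unknown strand {row['strand']!r}; record rejected",
                              stacklevel=2)
                acc.pop(sym, None)
                continue
            g = acc.setdefault(sym, {"contig": row["contig"], "strand": row["strand"],
                                     "exon": [], "CDS": [], "5UTR": [], "3UTR": [],
                                     "modes": set()})
            feat = row["feature"]
            if feat not in _FEATURES:
                raise ValueError(f"{sym}: unknown feature {feat!r}")
            g[feat].append((int(row["start"]) - 1, int(row["end"])))
            inh = row.get("inheritance", "") or ""
            g["modes"].update(m for m in inh.replace(".", "").split(",") if m)
    genes = []
    for sym, g in acc.items():
        genes.append(GeneModel(
            gene_symbol=sym, contig=g["contig"], strand=g["strand"],
            exons=tuple(merge_plain_intervals(g["exon"])),
            cds=tuple(merge_plain_intervals(g["CDS"])),
            utr5=tuple(merge_plain_intervals(g["5UTR"])),
            utr3=tuple(merge_plain_intervals(g["3UTR"])),
            inheritance_modes=frozenset(g["modes"]),
        ))
    return sorted(genes, key=lambda g: g.gene_symbol)


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_symbol\tcontig\tstrand\tstart\tend\tfeature\tinheritance\n")
        for g in genes:
            inh = ",".join(sorted(g.inheritance_modes)) or "."
            for feat, ivs in (("exon", g.exons), ("CDS", g.cds),
                              ("5UTR", g.utr5), ("3UTR", g.utr3)):
                for s, e in ivs:
                    fh.write(f"{g.gene_symbol}\t{g.contig}\t{g.strand}\t{s + 1}\t{e}\t"
                             f"{feat}\t{inh}\n")


# ---------------------------------------------------------------- BED / panel

def write_bed(targets: list[TargetInterval], path: str | Path) -> None:
    """6-column BED: chrom, start, end, name=gene|origin, score=0, strand."""
    with Path(path).open("w") as fh:
        for t in targets:
            name = f"{t.gene_symbol}|{'+'.join(sorted(t.origin))}"
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{name}\t0\t+\n")


def read_bed(path: str | Path) -> list[TargetInterval]:
    targets = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            gene, _, origin = f[3].partition("|") if len(f) > 3 else (f[0], "", "")
            targets.append(TargetInterval(f[0], int(f[1]), int(f[2]), gene or ".",
                                          frozenset(origin.split("+")) - {""}))
    return targets


# ---------------------------------------------------------------- SNP catalog

def read_snp_catalog(path: str | Path) -> set[tuple[str, int, str, str]]:
    """(contig, 0-based position, ref, alt) keys from a snp131-style TSV."""
    catalog = set()
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            catalog.add((row["contig"], int(row["position"]) - 1,
                         row["ref"], row["alt"]))
    return catalog


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------- pedigree

def read_ped(path: str | Path):
    """PED-like TSV: family, sample, father, mother, sex(1=M,2=F), affected(2=yes).

    Optional extra header columns are genotype columns per variant key with
    values in {ref, het, hom, hemi, missing}.
    """
    from .segregation import Pedigree, PedMember
    members, genotypes = [], {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        var_keys = header[6:]
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sid = f[1]
            members.append(PedMember(
                sample_id=sid,
                father_id=f[2] if f[2] not in ("0", ".") else None,
                mother_id=f[3] if f[3] not in ("0", ".") else None,
                sex="M" if f[4] == "1" else "F",
                affected=f[5] == "2",
            ))
            for k, g in zip(var_keys, f[6:]):
                if g and g != "missing":
                    genotypes[(sid, k)] = g
    return Pedigree(members=members, genotypes=genotypes)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
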
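"""Cohort reporting: packaged run-table fixtures, per-patient rows and
cohort summary statistics.

Two fixtures ship with the package: the 63-gene panel table (gene symbols,
chromosomal spans, exon counts, inheritance spectrum) and the 23-patient run
synopsis (sequencing yield, read length, median coverage, per-stage variant
counts, candidate mutations, family cosegregation and the evidence category
each patient's family work-up ended in).  Both carry SHA-256 checksums so a
silently edited transcription fails loudly.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .panel import GeneModel
from .segregation import (EVIDENCE_CATEGORIES, DIAGNOSTIC_CLASSES, PatientEvidence,
                          classify_patient, cohort_yield)
from .triage import FilterTrace

_COUNT_CHAIN = ("n_validated", "n_tested", "n_prioritized_var", "n_filtered_var",
                "n_cds_var", "n_total_var")


@dataclass
class PatientRunSummary:
    patient_id: str
    total_seq_mb: float
    read_length_bp: float
    median_fold_cvg: float
    n_total_var: int
    n_cds_var: int
    n_filtered_var: int
    n_prioritized_var: int
    n_tested: int
    n_validated: int
    mutation_label: str           # ';'-joined, '' if none
    mut_cvg: float | None         # coverage at the (first) candidate mutation
    mut_read_pct: float | None
    cosegregate_family: str       # yes | no | ? | M het norm | ... (';'-joined)
    evidence_category: str

    def __post_init__(self):
        if self.evidence_category not in EVIDENCE_CATEGORIES:
            raise ValueError(f"{self.patient_id}: unknown evidence category "
                             f"{self.evidence_category!r}")
        vals = [getattr(self, f) for f in _COUNT_CHAIN]
        for (fa, a), (fb, b) in zip(zip(_COUNT_CHAIN, vals), zip(_COUNT_CHAIN[1:], vals[1:])):
            if a > b:
                raise ValueError(
                    f"{self.patient_id}: count invariant violated: {fa}={a} > {fb}={b}")

    @property
    def diagnostic_class(self) -> str:
        candidates = [] if self.evidence_category == "none_found" else [self.mutation_label]
        return classify_patient(PatientEvidence(self.patient_id, candidates,
                                                self.evidence_category))


@dataclass
class CohortSummary:
    n_patients: int
    mean_mb: float
    sd_mb: float
    mean_read_len: float
    sd_read_len: float
    mean_total_var: float
    sd_total_var: float
    min_total_var: int
    max_total_var: int
    mean_cds_var: float
    sd_cds_var: float
    mean_filtered_var: float
    sd_filtered_var: float
    class_counts: dict[str, int]
    class_percentages: dict[str, int]

    def __post_init__(self):
        if not self.min_total_var <= self.mean_total_var <= self.max_total_var:
            raise ValueError("min <= mean <= max violated for total variants")


# ---------------------------------------------------------------- fixtures

def _fixture_bytes(name: str) -> bytes:
    ref = importlib.resources.files("retpanel.data").joinpath(name)
    data = ref.read_bytes()
    checks = json.loads(importlib.resources.files("retpanel.data")
                        .joinpath("checksums.json").read_text())
    digest = hashlib.sha256(data).hexdigest()
    if digest != checks[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    return data


def load_panel_table() -> pd.DataFrame:
    """The packaged 63-gene panel table (exon counts, spans, inheritance)."""
    from io import BytesIO
    return pd.read_csv(BytesIO(_fixture_bytes("table1_genes.tsv")), sep="\t")


def _modes_from_pathology(pathology: str) -> frozenset[str]:
    modes = set()
    for token in str(pathology).replace("and ", "").replace(",", " ").split():
        if token.startswith("AD"):
            modes.add("AD")
        elif token.startswith("AR"):
            modes.add("AR")
        elif token.startswith("X"):
            modes.add("XL")
    return frozenset(modes)


def gene_models_from_panel_table(table: pd.DataFrame | None = None,
                                 exon_bp: int = 150) -> list[GeneModel]:
    """Deterministic gene models from the panel table.

    The table records exon *counts* and the genomic span of each gene, not
    exon coordinates, so fixed-width exons are spread evenly over the span.
    Gene and exon counts are exact; individual exon coordinates are synthetic
    placeholders sufficient for panel bookkeeping and interval arithmetic.
    """
    if table is None:
        table = load_panel_table()
    genes = []
    for row in table.itertuples(index=False):
        n, start, end = int(row.n_exons), int(row.start), int(row.end)
        span = end - start
        if n * exon_bp > span:  # degenerate span; shrink exons to fit
            exon_bp_eff = max(1, span // (2 * n))
        else:
            exon_bp_eff = exon_bp
        gap = (span - n * exon_bp_eff) // max(1, n)
        exons = []
        pos = start
        for _ in range(n):
            exons.append((pos, pos + exon_bp_eff))
            pos += exon_bp_eff + gap
        genes.append(GeneModel(
            gene_symbol=row.gene_symbol, contig=f"chr{row.chrom}",
            strand=row.strand, exons=tuple(exons),
            inheritance_modes=_modes_from_pathology(row.pathology)))
    return genes


def load_table3_fixture() -> list[PatientRunSummary]:
    """The packaged 23-patient run synopsis."""
    from io import BytesIO
    df = pd.read_csv(BytesIO(_fixture_bytes("table3_patients.tsv")), sep="\t",
                     dtype=str)
    rows = []
    for r in df.itertuples(index=False):
        def _first_float(cell):
            if cell in (".", "", None) or (isinstance(cell, float) and math.isnan(cell)):
                return None
            return float(str(cell).split(";")[0])
        rows.append(PatientRunSummary(
            patient_id=str(r.patient_id),
            total_seq_mb=float(r.total_seq_mb),
            read_length_bp=float(r.read_length_bp),
            median_fold_cvg=float(r.median_fold_cvg),
            n_total_var=int(r.n_total_var),
            n_cds_var=int(r.n_cds_var),
            n_filtered_var=int(r.n_filtered_var),
            n_prioritized_var=int(r.n_prioritized_var),
            n_tested=int(r.n_tested),
            n_validated=int(r.n_validated),
            mutation_label="" if r.mutation_label == "." else str(r.mutation_label),
            mut_cvg=_first_float(r.mut_cvg),
            mut_read_pct=_first_float(r.mut_read_pct),
            cosegregate_family="" if r.cosegregate_family == "." else str(r.cosegregate_family),
            evidence_category=str(r.evidence_category),
        ))
    return rows


# ---------------------------------------------------------------- summaries

def cohort_summary(rows: list[PatientRunSummary]) -> CohortSummary:
    """Cohort means (sample SD, n−1 denominator), ranges and diagnostic yield."""
    if len(rows) < 2:
        raise ValueError("cohort summary needs >= 2 patients")
    def col(name):
        return np.array([getattr(r, name) for r in rows], dtype=float)
    mb, rl = col("total_seq_mb"), col("read_length_bp")
    tv, cds, filt = col("n_total_var"), col("n_cds_var"), col("n_filtered_var")
    classes = [classify_patient(PatientEvidence(
        r.patient_id, [] if r.evidence_category == "none_found" else [r.mutation_label],
        r.evidence_category)) for r in rows]
    counts, pcts = cohort_yield(classes)
    return CohortSummary(
        n_patients=len(rows),
        mean_mb=float(mb.mean()), sd_mb=float(mb.std(ddof=1)),
        mean_read_len=float(rl.mean()), sd_read_len=float(rl.std(ddof=1)),
        mean_total_var=float(tv.mean()), sd_total_var=float(tv.std(ddof=1)),
        min_total_var=int(tv.min()), max_total_var=int(tv.max()),
        mean_cds_var=float(cds.mean()), sd_cds_var=float(cds.std(ddof=1)),
        mean_filtered_var=float(filt.mean()), sd_filtered_var=float(filt.std(ddof=1)),
        class_counts=counts, class_percentages=pcts,
    )


def exon_fraction_pct(n_exons: int, panel_exons: int, ndigits: int = 1) -> float:
    """Share of the panel's exons as a percentage, rounded for reporting."""
    if panel_exons <= 0:
        raise ValueError("panel_exons must be positive")
    return round(100.0 * n_exons / panel_exons, ndigits)


def patient_report(patient_id: str,
                   trace: FilterTrace,
                   median_fold_cvg: float,
                   evidence_category: str,
                   total_seq_mb: float = 0.0,
                   read_length_bp: float = 0.0,
                   n_tested: int | None = None,
                   n_validated: int | None = None,
                   mutation_label: str = "",
                   mut_cvg: float | None = None,
                   mut_read_pct: float | None = None,
                   cosegregate_family: str = "") -> PatientRunSummary:
    """Assemble one run-synopsis row from pipeline outputs.

    The count-chain invariant (validated <= tested <= prioritized <= filtered
    <= coding <= total) is enforced at construction; a violation raises and
    names the offending inequality.
    """
    n_tested = trace.n_prioritized if n_tested is None else n_tested
    n_validated = n_tested if n_validated is None else n_validated
    return PatientRunSummary(
        patient_id=patient_id,
        total_seq_mb=total_seq_mb,
        read_length_bp=read_length_bp,
        median_fold_cvg=median_fold_cvg,
        n_total_var=trace.n_total,
        n_cds_var=trace.n_coding,
        n_filtered_var=trace.n_protein_changing,
        n_prioritized_var=trace.n_prioritized,
        n_tested=n_tested,
        n_validated=n_validated,
        mutation_label=mutation_label,
        mut_cvg=mut_cvg,
        mut_read_pct=mut_read_pct,
        cosegregate_family=cosegregate_family,
        evidence_category=evidence_category,
    )


def summary_to_dict(s: CohortSummary) -> dict:
    return asdict(s)
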
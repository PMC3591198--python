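"""Per-exon and per-patient coverage statistics and coverage-based deletion
detection.

A multi-exon germline deletion is invisible to a variant caller on a
targeted panel — no reads means no calls — but leaves an unmistakable
footprint in the per-base depth: a run of consecutive exons with zero
coverage in the carrier that the rest of the cohort covers well.  The
converse pattern, an exon that no sample ever covers, points at capture
failure (GC-rich or repetitive probe context) and is reported separately as
a technical failure of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GeneModel


@dataclass(frozen=True)
class ExonCoverageSummary:
    gene_symbol: str
    exon_index: int       # 1-based, transcription order
    n_bp: int
    mean_depth: float
    median_depth: float
    zero_covered: bool

    def __post_init__(self):
        if self.zero_covered and self.mean_depth != 0:
            raise ValueError("zero_covered exon with nonzero mean depth")


@dataclass(frozen=True)
class DeletionCandidate:
    sample_id: str
    gene_symbol: str
    exon_span: tuple[int, int]  # 1-based inclusive, transcription order
    n_exons: int
    cohort_support: float

    def __post_init__(self):
        if self.n_exons < 1:
            raise ValueError("deletion candidate must span >= 1 exon")


def _depth_lookup(coverage: pd.DataFrame) -> dict[str, dict[int, int]]:
    out: dict[str, dict[int, int]] = {}
    for contig, sub in coverage.groupby("contig", sort=False):
        out[contig] = dict(zip(sub["position"].astype(int),
                               sub["unique_depth"].astype(int)))
    return out


def summarize_exons(coverage: pd.DataFrame,
                    genes: list[GeneModel]) -> list[ExonCoverageSummary]:
    """Mean/median depth per exon (flanks excluded) and the zero-coverage flag.

    ``coverage`` uses in-memory convention: 0-based ``position`` and
    ``unique_depth`` columns.  Target bases missing from the stream are
    treated as depth 0 with a warning.
    """
    lookup = _depth_lookup(coverage)
    summaries = []
    missing = 0
    for g in genes:
        contig_depths = lookup.get(g.contig, {})
        for idx, (s, e) in enumerate(g.exons_in_order(), start=1):
            depths = np.empty(e - s, dtype=int)
            for k, p in enumerate(range(s, e)):
                d = contig_depths.get(p)
                if d is None:
                    missing += 1
                    d = 0
                depths[k] = d
            summaries.append(ExonCoverageSummary(
                gene_symbol=g.gene_symbol, exon_index=idx, n_bp=e - s,
                mean_depth=float(depths.mean()),
                median_depth=float(np.median(depths)),
                zero_covered=bool((depths == 0).all()),
            ))
    if missing:
        warnings.warn(f"{missing} exon bp missing from coverage stream; treated as depth 0",
                      stacklevel=2)
    return summaries


def cumulative_curve(depths) -> list[tuple[int, float]]:
    """Cumulative coverage curve over targeted bp: (x, % bp with depth >= x).

    Starts at 100% for x = 0, is non-increasing, and reaches 0 one fold
    beyond the maximum observed depth.  Input must already be restricted to
    targeted bases.
    """
    d = np.asarray(depths, dtype=int)
    if d.size == 0:
        raise ValueError("empty depth stream")
    if (d < 0).any():
        raise ValueError("negative depth")
    max_d = int(d.max())
    curve = []
    for x in range(0, max_d + 2):
        curve.append((x, 100.0 * float((d >= x).mean())))
    return curve


def patient_median_depth(depths) -> float:
    """Median unique depth over all targeted bp of one patient."""
    d = np.asarray(depths, dtype=float)
    if d.size == 0:
        raise ValueError("empty depth stream")
    return float(np.median(d))


def pooled_median_depth(depth_streams: list) -> float:
    """Median over the pooled per-base depths of all patients."""
    return float(np.median(np.concatenate([np.asarray(d, float)
                                           for d in depth_streams])))


def median_of_patient_medians(depth_streams: list) -> float:
    return float(np.median([patient_median_depth(d) for d in depth_streams]))


def detect_deletions(cohort_summaries: dict[str, list[ExonCoverageSummary]],
                     sample_id: str,
                     min_support: float = 0.8,
                     min_cohort_depth: float = 5,
                     ) -> tuple[list[DeletionCandidate], list[tuple[str, int]]]:
    """Classify the focal sample's zero-covered exons.

    An exon zero-covered in the focal sample is a deletion-candidate exon iff
    at least ``min_support`` of the *other* samples have median exon depth
    >= ``min_cohort_depth`` there; exons zero-covered in every sample are
    technical failures of the panel.  Consecutive candidate exons of one gene
    merge into a single multi-exon candidate.
    """
    if len(cohort_summaries) < 2:
        raise ValueError("deletion/technical-failure classification needs >= 2 samples")
    if sample_id not in cohort_summaries:
        raise KeyError(sample_id)

    by_key: dict[tuple[str, int], dict[str, ExonCoverageSummary]] = {}
    for sid, summaries in cohort_summaries.items():
        for s in summaries:
            by_key.setdefault((s.gene_symbol, s.exon_index), {})[sid] = s

    technical = sorted(
        key for key, per_sample in by_key.items()
        if len(per_sample) == len(cohort_summaries)
        and all(s.zero_covered for s in per_sample.values()))
    technical_set = set(technical)

    candidate_exons: dict[tuple[str, int], float] = {}
    for key, per_sample in by_key.items():
        focal = per_sample.get(sample_id)
        if focal is None or not focal.zero_covered or key in technical_set:
            continue
        others = [s for sid, s in per_sample.items() if sid != sample_id]
        if not others:
            continue
        support = sum(s.median_depth >= min_cohort_depth for s in others) / len(others)
        if support >= min_support:
            candidate_exons[key] = support

    candidates = []
    by_gene: dict[str, list[int]] = {}
    for gene, idx in candidate_exons:
        by_gene.setdefault(gene, []).append(idx)
    for gene, idxs in sorted(by_gene.items()):
        idxs.sort()
        run_start = prev = idxs[0]
        for i in idxs[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            support = min(candidate_exons[(gene, j)]
                          for j in range(run_start, prev + 1))
            candidates.append(DeletionCandidate(
                sample_id=sample_id, gene_symbol=gene,
                exon_span=(run_start, prev), n_exons=prev - run_start + 1,
                cohort_support=support))
            if i is not None:
                run_start = prev = i
    return candidates, technical
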
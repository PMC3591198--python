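"""Pileup-level simulator for 454-style targeted panel sequencing.

The simulator emulates the statistical structure of a benchtop
pyrosequencing run over a capture panel — long reads (~408 ± 48 bp),
modest median depth (~17-fold), GC-driven capture dropout, homopolymer
indel artifacts, and binomial allele read fractions (~50% het, ~99%
hom/hemi) — at the level the downstream pipeline consumes: per-base unique
depth and a table of called sequence differences per sample.  No read
alignment is performed; the mapper's output dialects are generated
directly.

All randomness flows from one seed; each sample gets an independent
substream derived from (seed, sample index), so cohorts are reproducible
and per-sample output does not depend on cohort order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GeneModel, TargetInterval
from .segregation import Pedigree, PedMember
from . import io as rio

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Simulation parameters; defaults are the assay's reported run statistics."""

    seed: int = 0
    read_len_mean: float = 408.0     # bp
    read_len_sd: float = 48.0        # bp
    read_len_min: int = 50           # bp
    mean_exon_depth: float = 17.0    # fold
    depth_dispersion: float = 0.0    # 0 = pure Poisson; >0 gamma-mixed
    gc_dropout_threshold: float = 0.70
    gc_dropout_factor: float = 0.2
    sub_error_rate: float = 1e-4     # spurious substitution calls per target bp
    homopolymer_indel_slope: float = 0.01  # per-run error prob increment per bp
    hom_alt_fraction: float = 0.99
    het_alt_fraction: float = 0.5
    avg_quality: float = 30.0        # constant placeholder, column 4

    def __post_init__(self):
        for name in ("gc_dropout_threshold", "gc_dropout_factor", "sub_error_rate",
                     "hom_alt_fraction", "het_alt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.read_len_min > self.read_len_mean:
            raise ValueError("read_len_min > read_len_mean")


@dataclass(frozen=True)
class TruthVariant:
    contig: str
    position: int            # 0-based
    ref_allele: str
    alt_allele: str
    kind: str                # SNV | insertion | deletion | multi_exon_deletion
    zygosity: str            # het | hom | hemi
    carrier_samples: tuple[str, ...]
    gene_symbol: str | None = None
    exon_span: tuple[int, int] | None = None  # 1-based inclusive, multi_exon_deletion

    def key(self) -> str:
        if self.kind == "multi_exon_deletion":
            return f"g.{self.gene_symbol}-ex{self.exon_span[0]}-{self.exon_span[1]}del"
        return f"{self.contig}:{self.position}:{self.ref_allele or '-'}>{self.alt_allele or '-'}"


@dataclass
class TruthSet:
    variants: list[TruthVariant]
    pedigree: Pedigree
    config: SimulationConfig

    def __post_init__(self):
        ids = set(self.pedigree.sample_ids)
        for v in self.variants:
            missing = set(v.carrier_samples) - ids
            if missing:
                raise ValueError(f"{v.key()}: carriers {missing} not in pedigree")
        # populate pedigree genotypes from truth (non-carriers are ref)
        for v in self.variants:
            for sid in self.pedigree.sample_ids:
                key = (sid, v.key())
                self.pedigree.genotypes.setdefault(
                    key, v.zygosity if sid in v.carrier_samples else "ref")


def sample_read_lengths(n: int, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Integer read lengths from Normal(mean, sd) truncated at read_len_min."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = rng or np.random.default_rng(config.seed)
    if config.read_len_sd == 0:
        return np.full(n, int(round(config.read_len_mean)))
    out = rng.normal(config.read_len_mean, config.read_len_sd, size=n)
    bad = out < config.read_len_min
    while bad.any():  # resample the sub-minimum tail (negligible mass at defaults)
        out[bad] = rng.normal(config.read_len_mean, config.read_len_sd, size=bad.sum())
        bad = out < config.read_len_min
    return np.rint(out).astype(int)


def exon_lambda(gc_fraction: float, config: SimulationConfig) -> float:
    """Expected depth for an exon given its GC content (capture dropout)."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0,1]")
    lam = config.mean_exon_depth
    if gc_fraction > config.gc_dropout_threshold:
        lam *= config.gc_dropout_factor
    return lam


def sample_exon_depth(gc_fraction: float, config: SimulationConfig,
                      rng: np.random.Generator, size: int | None = None):
    """Depth draw(s) ~ Poisson(lambda) with GC dropout applied to lambda."""
    lam = exon_lambda(gc_fraction, config)
    if config.depth_dispersion > 0 and lam > 0:
        shape = 1.0 / config.depth_dispersion
        lam = rng.gamma(shape, lam / shape, size=size)
    return rng.poisson(lam, size=size)


def sample_variant_reads(depth: int, zygosity: str, config: SimulationConfig,
                         rng: np.random.Generator) -> tuple[int, int]:
    """(variant_reads, total_reads) at a variant site of given zygosity."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return (0, 0)
    p = config.het_alt_fraction if zygosity == "het" else config.hom_alt_fraction
    return (int(rng.binomial(depth, p)), depth)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_reference(contigs: dict[str, int], seed: int = 0,
                     gc: float = 0.45) -> dict[str, str]:
    """Random reference sequences with a given expected GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {name: "".join(rng.choice(BASES, size=length, p=p))
            for name, length in contigs.items()}


def _homopolymer_runs(seq: str, start: int, min_len: int = 2):
    """Maximal single-base runs >= min_len as (run_start, length), genomic coords."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((start + i, j - i))
        i = j
    return runs


def _deleted_bases(v: TruthVariant, genes: dict[str, GeneModel]) -> set[tuple[str, int]]:
    g = genes[v.gene_symbol]
    first, last = v.exon_span
    out = set()
    for i in range(first, last + 1):
        s, e = g.exon_number(i)
        out.update((g.contig, p) for p in range(s, e))
    return out


@dataclass
class SampleSim:
    sample_id: str
    coverage: pd.DataFrame   # contig, position(0-based), ref_base, avg_quality, unique_depth
    variants: pd.DataFrame   # contig, position(0-based), ref_allele, alt_allele, total_reads, variant_reads, variant_pct


def simulate_cohort(panel: list[TargetInterval], genes: list[GeneModel],
                    reference: dict[str, str], truth: TruthSet,
                    config: SimulationConfig | None = None,
                    out_dir: str | Path | None = None) -> dict[str, SampleSim]:
    """Simulate one coverage file and one variant table per pedigree sample.

    Coverage enumerates every target bp (depth-0 rows included).  Carried
    truth variants yield one variant row with binomially sampled read counts;
    spurious substitution rows are injected at ``sub_error_rate`` per target
    bp, and homopolymer indel rows per reference run of length L with
    probability min(0.5, slope·(L−1)).  Carriers of a multi-exon deletion get
    zero depth across the deleted exons and no variant row.
    """
    config = config or truth.config
    gene_map = {g.gene_symbol: g for g in genes}
    for v in truth.variants:
        if v.kind == "multi_exon_deletion":
            if v.gene_symbol not in gene_map:
                raise ValueError(f"{v.key()}: gene not in panel gene models")
            continue
        inside = any(t.contig == v.contig and t.start <= v.position < t.end
                     for t in panel)
        if not inside:
            raise ValueError(f"truth variant {v.key()} lies outside the panel")

    results: dict[str, SampleSim] = {}
    for idx, sid in enumerate(truth.pedigree.sample_ids):
        rng = np.random.default_rng([config.seed, idx])
        deleted: set[tuple[str, int]] = set()
        for v in truth.variants:
            if v.kind == "multi_exon_deletion" and sid in v.carrier_samples:
                deleted |= _deleted_bases(v, gene_map)

        cov_frames = []
        depth_at: dict[tuple[str, int], int] = {}
        for t in sorted(panel, key=lambda t: (t.contig, t.start)):
            seq = reference[t.contig][t.start:t.end]
            if len(seq) != t.length:
                raise ValueError(f"reference does not cover target {t.contig}:{t.start}-{t.end}")
            depths = sample_exon_depth(gc_fraction(seq), config, rng, size=t.length)
            positions = np.arange(t.start, t.end)
            if deleted:
                mask = np.fromiter(((t.contig, int(p)) in deleted for p in positions),
                                   dtype=bool, count=t.length)
                depths = np.where(mask, 0, depths)
            cov_frames.append(pd.DataFrame({
                "contig": t.contig, "position": positions,
                "ref_base": list(seq),
                "avg_quality": config.avg_quality,
                "unique_depth": depths,
            }))
            for p, d in zip(positions, depths):
                depth_at[(t.contig, int(p))] = int(d)
        coverage = pd.concat(cov_frames, ignore_index=True)

        var_rows = []
        for v in truth.variants:
            if v.kind == "multi_exon_deletion" or sid not in v.carrier_samples:
                continue
            depth = depth_at.get((v.contig, v.position), 0)
            vr, tr = sample_variant_reads(depth, v.zygosity, config, rng)
            if vr > 0:
                var_rows.append((v.contig, v.position, v.ref_allele, v.alt_allele, tr, vr))

        if config.sub_error_rate > 0:
            for t in sorted(panel, key=lambda t: (t.contig, t.start)):
                n_err = rng.binomial(t.length, config.sub_error_rate)
                for _ in range(n_err):
                    pos = int(rng.integers(t.start, t.end))
                    depth = depth_at.get((t.contig, pos), 0)
                    if depth == 0:
                        continue
                    ref = reference[t.contig][pos]
                    alt = str(rng.choice(BASES[BASES != ref]))
                    vr = max(1, int(rng.binomial(depth, 0.1)))
                    var_rows.append((t.contig, pos, ref, alt, depth, vr))

        if config.homopolymer_indel_slope > 0:
            for t in sorted(panel, key=lambda t: (t.contig, t.start)):
                seq = reference[t.contig][t.start:t.end]
                for run_start, run_len in _homopolymer_runs(seq, t.start):
                    p_err = min(0.5, config.homopolymer_indel_slope * (run_len - 1))
                    if rng.random() >= p_err:
                        continue
                    pos = run_start + run_len - 1
                    depth = depth_at.get((t.contig, pos), 0)
                    if depth == 0:
                        continue
                    base = reference[t.contig][run_start]
                    vr = max(1, int(rng.binomial(depth, 0.15)))
                    if rng.random() < 0.5:
                        var_rows.append((t.contig, pos, base, "", depth, vr))   # 1-bp del
                    else:
                        var_rows.append((t.contig, pos + 1, "", base, depth, vr))  # 1-bp ins

        variants = pd.DataFrame(
            var_rows, columns=["contig", "position", "ref_allele", "alt_allele",
                               "total_reads", "variant_reads"])
        variants["variant_pct"] = np.where(
            variants["total_reads"] > 0,
            100.0 * variants["variant_reads"] / variants["total_reads"].replace(0, 1), 0.0)
        variants = variants.sort_values(["contig", "position"]).reset_index(drop=True)
        results[sid] = SampleSim(sid, coverage, variants)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, sim in results.items():
            rio.write_alignment_info(sim.coverage, out / f"{sid}.alignment_info.tsv")
            rio.write_hcdiffs(sim.variants, out / f"{sid}.hcdiffs.tsv", sample_id=sid)
        write_truth_json(truth, out / "truth.json")
    return results


# ---------------------------------------------------------------- truth JSON

def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    doc = {
        "config": asdict(truth.config),
        "pedigree": {
            "members": [asdict(m) for m in truth.pedigree.members],
            "genotypes": [
                {"sample_id": sid, "variant": key, "genotype": g}
                for (sid, key), g in sorted(truth.pedigree.genotypes.items())
            ],
        },
        "variants": [asdict(v) for v in truth.variants],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_truth_json(path: str | Path) -> TruthSet:
    doc = json.loads(Path(path).read_text())
    config = SimulationConfig(**doc["config"])
    members = [PedMember(**m) for m in doc["pedigree"]["members"]]
    genotypes = {(g["sample_id"], g["variant"]): g["genotype"]
                 for g in doc["pedigree"]["genotypes"]}
    variants = []
    for v in doc["variants"]:
        v = dict(v)
        v["carrier_samples"] = tuple(v["carrier_samples"])
        if v.get("exon_span") is not None:
            v["exon_span"] = tuple(v["exon_span"])
        variants.append(TruthVariant(**v))
    return TruthSet(variants=variants,
                    pedigree=Pedigree(members=members, genotypes=genotypes),
                    config=config)
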
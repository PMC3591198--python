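"""Capture-panel target design for exon-based diagnostic gene panels.

A panel targets, for every gene, each exon plus short intronic flanks
(default 50 bp on both sides, so splice donor/acceptor regions are read),
the complete 3'-UTR (already inside the last exon of the model), and a
proximal promoter window (default 1000 bp) immediately 5' of the
transcription-start-most exon, which also covers the 5'-UTR.  Coordinates
are 0-based half-open throughout; 1-based formats convert at the I/O
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

Interval = tuple[int, int]

VALID_MODES = frozenset({"AD", "AR", "XL"})


def _check_sorted_disjoint(ivs: tuple[Interval, ...], label: str) -> None:
    for (s, e) in ivs:
        if not s < e:
            raise ValueError(f"{label}: empty or inverted interval [{s},{e})")
    for (a, b) in zip(ivs, ivs[1:]):
        if b[0] < a[1]:
            raise ValueError(f"{label}: intervals overlap or are unsorted: {a} vs {b}")


def _contained(inner: tuple[Interval, ...], outer: tuple[Interval, ...]) -> bool:
    """True if every inner interval lies within the base-set union of outer."""
    for s, e in inner:
        covered = 0
        for os, oe in outer:
            lo, hi = max(s, os), min(e, oe)
            if hi > lo:
                covered += hi - lo
        if covered != e - s:
            return False
    return True


@dataclass(frozen=True)
class GeneModel:
    """One gene: strand, exon structure and optional CDS/UTR annotation.

    Exons from alternative transcripts must be merged into a disjoint union
    before construction (see :func:`merge_plain_intervals`).
    """

    gene_symbol: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()
    inheritance_modes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_symbol}: unknown strand {self.strand!r}")
        object.__setattr__(self, "exons", tuple(tuple(iv) for iv in self.exons))
        object.__setattr__(self, "cds", tuple(tuple(iv) for iv in self.cds))
        object.__setattr__(self, "utr5", tuple(tuple(iv) for iv in self.utr5))
        object.__setattr__(self, "utr3", tuple(tuple(iv) for iv in self.utr3))
        _check_sorted_disjoint(self.exons, f"{self.gene_symbol} exons")
        _check_sorted_disjoint(self.cds, f"{self.gene_symbol} cds")
        for name, sub in (("cds", self.cds), ("utr5", self.utr5), ("utr3", self.utr3)):
            if sub and not _contained(sub, self.exons):
                raise ValueError(f"{self.gene_symbol}: {name} not within exons")
        bad = set(self.inheritance_modes) - VALID_MODES
        if bad:
            raise ValueError(f"{self.gene_symbol}: unknown inheritance modes {bad}")
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_symbol}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def exon_number(self, i: int) -> Interval:
        """Exon by 1-based number in transcription order (strand-aware)."""
        if not 1 <= i <= len(self.exons):
            raise IndexError(f"{self.gene_symbol}: exon {i} of {len(self.exons)}")
        return self.exons[i - 1] if self.strand == "+" else self.exons[-i]

    def exons_in_order(self) -> list[Interval]:
        """Exons in transcription (5'→3') order."""
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])


@dataclass(frozen=True)
class TargetInterval:
    contig: str
    start: int
    end: int
    gene_symbol: str
    origin: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty target [{self.start},{self.end})")
        object.__setattr__(self, "origin", frozenset(self.origin))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelStats:
    n_genes: int
    n_exons: int
    total_target_bp: int


def merge_plain_intervals(ivs: list[Interval]) -> list[Interval]:
    """Minimal sorted disjoint cover of plain (start, end) intervals."""
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def merge_intervals(intervals: list[TargetInterval]) -> list[TargetInterval]:
    """Merge overlapping/touching targets per contig; union origin labels.

    Gene symbols of merged intervals are joined with ',' (sorted, unique).
    """
    by_contig: dict[str, list[TargetInterval]] = {}
    for t in intervals:
        by_contig.setdefault(t.contig, []).append(t)
    out: list[TargetInterval] = []
    for contig in sorted(by_contig):
        cur = None
        for t in sorted(by_contig[contig], key=lambda t: (t.start, t.end)):
            if cur is None or t.start > cur["end"]:
                if cur is not None:
                    out.append(_finish(cur))
                cur = {"contig": contig, "start": t.start, "end": t.end,
                       "genes": set(t.gene_symbol.split(",")), "origin": set(t.origin)}
            else:
                cur["end"] = max(cur["end"], t.end)
                cur["genes"].update(t.gene_symbol.split(","))
                cur["origin"].update(t.origin)
        if cur is not None:
            out.append(_finish(cur))
    return out


def _finish(cur: dict) -> TargetInterval:
    return TargetInterval(cur["contig"], cur["start"], cur["end"],
                          ",".join(sorted(cur["genes"])), frozenset(cur["origin"]))


def build_targets(
    genes: list[GeneModel],
    flank_bp: int = 50,
    promoter_bp: int = 1000,
    contig_lengths: dict[str, int] | None = None,
) -> list[TargetInterval]:
    """Build merged capture targets from gene models.

    Each exon is extended by ``flank_bp`` on both sides; a promoter window of
    ``promoter_bp`` is placed immediately 5' of the transcription-start-most
    exon (lower coordinates on '+', higher on '-').  The 3'-UTR lies within
    the last exon so it is covered by construction.  Intervals are clipped to
    ``[0, contig_length)`` and merged per contig.
    """
    if flank_bp < 0 or promoter_bp < 0:
        raise ValueError("flank_bp and promoter_bp must be >= 0")
    raw: list[TargetInterval] = []
    for g in genes:
        clen = (contig_lengths or {}).get(g.contig)
        utr3_union = merge_plain_intervals(list(g.utr3))
        for s, e in g.exons:
            ts, te = s - flank_bp, e + flank_bp
            if ts < 0:
                warnings.warn(
                    f"{g.gene_symbol}: exon flank extends below 0; clipped", stacklevel=2
                )
                ts = 0
            if clen is not None:
                te = min(te, clen)
            origin = {"exon_flank"}
            if any(min(e, ue) > max(s, us) for us, ue in utr3_union):
                origin.add("utr3")
            raw.append(TargetInterval(g.contig, ts, te, g.gene_symbol, frozenset(origin)))
        if promoter_bp > 0:
            if g.strand == "+":
                ps, pe = g.exons[0][0] - promoter_bp, g.exons[0][0]
            else:
                ps, pe = g.exons[-1][1], g.exons[-1][1] + promoter_bp
            if ps < 0:
                warnings.warn(
                    f"{g.gene_symbol}: promoter extends below 0; clipped", stacklevel=2
                )
                ps = 0
            if clen is not None:
                pe = min(pe, clen)
            if pe > ps:
                raw.append(TargetInterval(g.contig, ps, pe, g.gene_symbol,
                                          frozenset({"promoter_5utr"})))
    return merge_intervals(raw)


def panel_stats(targets: list[TargetInterval], genes: list[GeneModel]) -> PanelStats:
    """Panel bookkeeping: gene count, exon count, merged target span in bp.

    The promoter windows count toward ``total_target_bp`` but not toward
    ``n_exons``.
    """
    return PanelStats(
        n_genes=len(genes),
        n_exons=sum(g.n_exons for g in genes),
        total_target_bp=sum(t.length for t in merge_intervals(targets)),
    )
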
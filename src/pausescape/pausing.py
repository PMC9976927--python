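"""Promoter-proximal pausing index: quantification, window optimization, filters.

The pausing index (PI, also called the traveling ratio) of a transcript is
the log2 ratio of length-normalized nascent-transcription coverage in a
short window centered on the TSS versus the remainder of the transcript span
(the gene body)::

    PI = log2((c_tss + a) / w_tss) - log2((c_body + a) / w_body)

with a pseudocount ``a`` (default one read) added to each raw window count
before length normalization. A high PI marks a transcript whose polymerase
accumulates at the promoter; a low PI marks efficient elongation.

The TSS window half-width is not fixed a priori: it is chosen by scanning a
grid and keeping the half-width whose PIs correlate most negatively with
transcript expression, on the rationale that strong pausing should suppress
mRNA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation import TranscriptModel
from .intervals import GenomicInterval, GenomeSequence, SignalTrack


@dataclass
class PIConfig:
    """Parameters of the pausing-index computation.

    tss_halfwidth ``h`` gives a centered, inclusive TSS window
    ``[TSS - h, TSS + h]`` of width ``2h + 1``; ``pseudocount`` is added to
    each raw window count; ``halfwidth_grid`` is scanned by
    :func:`optimize_tss_window`.
    """

    tss_halfwidth: int = 1
    pseudocount: float = 1.0
    halfwidth_grid: Tuple[int, ...] = (1, 2, 5, 10, 25, 50, 100, 250, 500, 1000)

    def __post_init__(self) -> None:
        if self.tss_halfwidth < 0:
            raise ValueError("tss_halfwidth must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def w_tss(self) -> int:
        return 2 * self.tss_halfwidth + 1


@dataclass
class PausingRecord:
    transcript_id: str
    c_tss: float
    c_body: float
    w_tss: int
    w_body: int
    pi: float


def window_signal(track: SignalTrack, iv: GenomicInterval, strand: str) -> float:
    """Sum of strand-specific coverage over a half-open interval."""
    if strand not in ("+", "-"):
        raise ValueError("strand must be + or -")
    return track.window_sum(iv.chrom, strand, iv.start, iv.end)


def _tss_body_windows(
    tx: TranscriptModel, h: int
) -> Tuple[GenomicInterval, GenomicInterval]:
    """Centered inclusive TSS window and the downstream remainder of the span."""
    t = tx.tss
    tss_iv = GenomicInterval(tx.chrom, t - h, t + h + 1, tx.strand)
    if tx.strand == "+":
        body_iv = GenomicInterval(tx.chrom, t + h + 1, tx.span.end, tx.strand)
    else:
        body_iv = GenomicInterval(tx.chrom, tx.span.start, t - h, tx.strand)
    return tss_iv, body_iv


def compute_pausing_index(
    track: SignalTrack, tx: TranscriptModel, cfg: PIConfig
) -> PausingRecord:
    """Pausing index of one transcript from strand-specific coverage."""
    h = cfg.tss_halfwidth
    w_tss = cfg.w_tss
    # body must be non-empty: the TSS window may hang upstream of the span,
    # but the downstream remainder needs at least one base
    if tx.length <= w_tss:
        raise ValueError(
            f"{tx.transcript_id}: length {tx.length} <= TSS window {w_tss}"
        )
    tss_iv, body_iv = _tss_body_windows(tx, h)
    c_tss = window_signal(track, tss_iv, tx.strand)
    c_body = window_signal(track, body_iv, tx.strand)
    w_body = tx.length - w_tss
    a = cfg.pseudocount
    pi = float(np.log2((c_tss + a) / w_tss) - np.log2((c_body + a) / w_body))
    return PausingRecord(tx.transcript_id, c_tss, c_body, w_tss, w_body, pi)


def compute_all_pi(
    track: SignalTrack, txs: Sequence[TranscriptModel], cfg: PIConfig
) -> Dict[str, PausingRecord]:
    return {t.transcript_id: compute_pausing_index(track, t, cfg) for t in txs}


def optimize_tss_window(
    track: SignalTrack,
    txs: Sequence[TranscriptModel],
    log10_fpkm: Mapping[str, float],
    grid: Sequence[int] | None = None,
    pseudocount: float = 1.0,
) -> Tuple[int, Dict[int, float]]:
    """Choose the TSS half-width whose PI anti-correlates best with expression.

    For every half-width in ``grid`` the PI of each usable transcript is
    computed and correlated (Pearson) with log10 FPKM; the half-width with the
    most negative correlation wins, ties going to the smallest half-width.
    Only transcripts long enough for the largest grid window enter, so the
    profile is computed on one common transcript set.
    """
    if grid is None:
        grid = PIConfig().halfwidth_grid
    grid = sorted(set(int(g) for g in grid))
    max_w = 2 * grid[-1] + 1
    usable = [
        t
        for t in txs
        if t.length > max_w
        and t.tss - grid[-1] >= 0
        and t.transcript_id in log10_fpkm
    ]
    if len(usable) < 3:
        raise ValueError("need >= 3 transcripts with PI and expression at all widths")
    expr = np.array([log10_fpkm[t.transcript_id] for t in usable])
    if np.std(expr) == 0:
        raise ValueError("zero expression variance; correlation undefined")

    profile: Dict[int, float] = {}
    for h in grid:
        cfg = PIConfig(tss_halfwidth=h, pseudocount=pseudocount, halfwidth_grid=tuple(grid))
        pis = np.array(
            [compute_pausing_index(track, t, cfg).pi for t in usable]
        )
        if np.std(pis) == 0:
            profile[h] = 0.0
        else:
            profile[h] = float(stats.pearsonr(pis, expr)[0])
    best = min(grid, key=lambda h: (profile[h], h))
    return best, profile


@dataclass
class ExclusionReport:
    """Per-reason exclusion counts; a transcript is counted once, under the
    first reason that fired (non-ACGT, then overlap, then zero signal)."""

    non_acgt: List[str] = field(default_factory=list)
    overlapping: List[str] = field(default_factory=list)
    no_signal: List[str] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        return {
            "non_acgt": len(self.non_acgt),
            "overlapping": len(self.overlapping),
            "no_signal": len(self.no_signal),
        }


_ACGT = frozenset("ACGT")


def apply_pi_filters(
    txs: Sequence[TranscriptModel],
    genome: GenomeSequence,
    track: SignalTrack,
    cfg: Optional[PIConfig] = None,
    stranded_overlap: bool = True,
) -> Tuple[List[TranscriptModel], ExclusionReport]:
    """Apply the transcript exclusions preceding PI modeling.

    Excluded are: transcripts whose span sequence contains any letter outside
    A/C/G/T (untrustworthy mapping); every member of a span-overlapping pair
    of protein-coding transcripts on the same strand (coverage cannot be
    attributed uniquely; set ``stranded_overlap=False`` for strand-agnostic
    overlap); and transcripts with zero coverage both at the TSS window and in
    the body.
    """
    cfg = cfg or PIConfig()
    report = ExclusionReport()
    excluded: set[str] = set()

    for t in txs:
        seq = genome.fetch(t.span)
        if not _ACGT.issuperset(seq):
            report.non_acgt.append(t.transcript_id)
            excluded.add(t.transcript_id)

    coding = [t for t in txs if t.is_coding() and t.transcript_id not in excluded]
    by_key: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in coding:
        key = (t.chrom, t.strand if stranded_overlap else ".")
        by_key.setdefault(key, []).append(t)
    overlapping: set[str] = set()
    for group in by_key.values():
        group.sort(key=lambda t: t.span.start)
        max_end = -1
        prev: List[TranscriptModel] = []
        for t in group:
            # sweep: compare against actives whose span still extends past start
            prev = [p for p in prev if p.span.end > t.span.start]
            for p in prev:
                overlapping.add(p.transcript_id)
                overlapping.add(t.transcript_id)
            prev.append(t)
    for t in txs:
        if t.transcript_id in overlapping:
            report.overlapping.append(t.transcript_id)
            excluded.add(t.transcript_id)

    kept: List[TranscriptModel] = []
    for t in txs:
        if t.transcript_id in excluded:
            continue
        if t.length <= cfg.w_tss:
            report.no_signal.append(t.transcript_id)
            continue
        tss_iv, body_iv = _tss_body_windows(t, cfg.tss_halfwidth)
        c_tss = window_signal(track, tss_iv, t.strand)
        c_body = window_signal(track, body_iv, t.strand)
        if c_tss == 0 and c_body == 0:
            report.no_signal.append(t.transcript_id)
            excluded.add(t.transcript_id)
        else:
            kept.append(t)
    return kept, report
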
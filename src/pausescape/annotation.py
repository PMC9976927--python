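"""Transcript models, derived gene regions, and transcript-level filters.

A transcript enters the pausing analysis only if it survives three gates:
RefSeq support (high-confidence structure), expression in both RNA-seq
replicates (FPKM > 0), and agreement of its annotated TSS with the dominant
CAGE-derived start site of a start-site cluster. The surviving transcripts
carry a log10 FPKM (mean of replicates) used later for TSS window-size
optimization, and their CAGE cluster for TSS-shape features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: List[GenomicInterval]  # ordered 5'->3' in transcription direction
    biotype: str = "protein_coding"
    refseq_supported: bool = False
    cds_span: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/-, got {self.strand!r}")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )
        for e in self.exons:
            if e.start < self.span.start or e.end > self.span.end:
                raise ValueError(f"{self.transcript_id}: exon {e} outside span")
        # canonical transcription order
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def length(self) -> int:
        return self.span.length

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass
class RegionSet:
    """The four derived regions of a transcript (genomic coordinates).

    ``five_prime``: exonic sequence 5' of the CDS start (all exonic sequence
    for non-coding transcripts); ``coding_exons``: exonic sequence within the
    CDS; ``three_prime``: exonic sequence 3' of the CDS end; ``introns``:
    span minus exons. Regions are mutually disjoint by construction.
    """

    five_prime: List[GenomicInterval] = field(default_factory=list)
    coding_exons: List[GenomicInterval] = field(default_factory=list)
    introns: List[GenomicInterval] = field(default_factory=list)
    three_prime: List[GenomicInterval] = field(default_factory=list)

    def by_name(self) -> Dict[str, List[GenomicInterval]]:
        return {
            "5prime": self.five_prime,
            "codingexon": self.coding_exons,
            "intron": self.introns,
            "3prime": self.three_prime,
        }


REGION_NAMES = ("5prime", "codingexon", "intron", "3prime")


@dataclass
class ExpressionRecord:
    transcript_id: str
    fpkm_rep1: float
    fpkm_rep2: float

    def __post_init__(self) -> None:
        if self.fpkm_rep1 < 0 or self.fpkm_rep2 < 0:
            raise ValueError("FPKM must be non-negative")

    @property
    def expressed(self) -> bool:
        return self.fpkm_rep1 > 0 and self.fpkm_rep2 > 0

    @property
    def log10_fpkm(self) -> float:
        return math.log10((self.fpkm_rep1 + self.fpkm_rep2) / 2.0)


@dataclass
class CTSSCluster:
    chrom: str
    strand: str
    positions: np.ndarray  # sorted member positions (0-based)
    tpms: np.ndarray
    dominant_position: int
    total_tpm: float

    @property
    def width(self) -> int:
        return int(self.positions.max() - self.positions.min() + 1)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, int(self.positions.min()), int(self.positions.max()) + 1,
            self.strand,
        )


def _subtract(iv: GenomicInterval, cut_start: int, cut_end: int) -> List[GenomicInterval]:
    """Parts of iv outside [cut_start, cut_end)."""
    out = []
    if iv.start < cut_start:
        out.append(
            GenomicInterval(iv.chrom, iv.start, min(iv.end, cut_start), iv.strand)
        )
    if iv.end > cut_end:
        out.append(
            GenomicInterval(iv.chrom, max(iv.start, cut_end), iv.end, iv.strand)
        )
    return out


def derive_regions(
    tx: TranscriptModel, cds_span: Optional[GenomicInterval] = None
) -> RegionSet:
    """Split a transcript into 5', coding-exon, intron and 3' regions."""
    if cds_span is None:
        cds_span = tx.cds_span
    rs = RegionSet()

    exons_genomic = sorted(tx.exons, key=lambda e: e.start)
    # introns: gaps between consecutive exons
    for a, b in zip(exons_genomic, exons_genomic[1:]):
        if b.start > a.end:
            rs.introns.append(GenomicInterval(tx.chrom, a.end, b.start, tx.strand))

    if cds_span is None:
        rs.five_prime = list(exons_genomic)
        return rs

    exon_union_start = exons_genomic[0].start
    exon_union_end = exons_genomic[-1].end
    if cds_span.start < exon_union_start or cds_span.end > exon_union_end:
        raise ValueError(f"{tx.transcript_id}: CDS {cds_span} outside exon span")

    for e in exons_genomic:
        inter = e.intersection(
            GenomicInterval(tx.chrom, cds_span.start, cds_span.end, tx.strand)
        )
        if inter is not None:
            rs.coding_exons.append(inter)
        for part in _subtract(e, cds_span.start, cds_span.end):
            upstream_of_cds = (
                part.end <= cds_span.start
                if tx.strand == "+"
                else part.start >= cds_span.end
            )
            if upstream_of_cds:
                rs.five_prime.append(part)
            else:
                rs.three_prime.append(part)
    return rs


def filter_high_confidence(
    txs: Sequence[TranscriptModel], refseq_ids: Iterable[str] = ()
) -> List[TranscriptModel]:
    """Keep transcripts flagged RefSeq-supported or listed by id."""
    ids = set(refseq_ids)
    return [t for t in txs if t.refseq_supported or t.transcript_id in ids]


def filter_expressed(
    txs: Sequence[TranscriptModel],
    expr: Mapping[str, ExpressionRecord],
) -> Tuple[List[TranscriptModel], Dict[str, float]]:
    """Keep transcripts with FPKM > 0 in both replicates.

    Returns the surviving transcripts (input order) and their log10 of the
    replicate-mean FPKM.
    """
    kept, log10 = [], {}
    for t in txs:
        rec = expr.get(t.transcript_id)
        if rec is not None and rec.expressed:
            kept.append(t)
            log10[t.transcript_id] = rec.log10_fpkm
    return kept, log10


def cluster_ctss(
    ctss: pd.DataFrame,
    tpm_threshold: float = 0.1,
    max_gap: int = 20,
) -> List[CTSSCluster]:
    """Cluster per-position CAGE TPM values into start-site clusters.

    Positions below ``tpm_threshold`` are removed before clustering (so a
    singleton at exactly the threshold survives); remaining positions on the
    same chromosome and strand are merged while consecutive gaps are at most
    ``max_gap``. The dominant position is the TPM argmax, ties broken toward
    the most 5' member in transcription direction.
    """
    required = {"chrom", "position", "strand", "tpm"}
    if not required.issubset(ctss.columns):
        raise ValueError(f"CTSS table must have columns {sorted(required)}")
    if len(ctss) == 0:
        return []
    if (ctss["tpm"] < 0).any():
        raise ValueError("negative TPM in CTSS table")

    kept = ctss[ctss["tpm"] >= tpm_threshold]
    clusters: List[CTSSCluster] = []
    for (chrom, strand), grp in kept.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy(dtype=np.int64)
        tpm = grp["tpm"].to_numpy(dtype=np.float64)
        if len(pos) == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
        for seg_pos, seg_tpm in zip(np.split(pos, breaks), np.split(tpm, breaks)):
            best = seg_tpm.max()
            cand = seg_pos[seg_tpm == best]
            dominant = int(cand.min() if strand == "+" else cand.max())
            clusters.append(
                CTSSCluster(
                    chrom=chrom,
                    strand=strand,
                    positions=seg_pos,
                    tpms=seg_tpm,
                    dominant_position=dominant,
                    total_tpm=float(seg_tpm.sum()),
                )
            )
    return clusters


def filter_by_dominant_ctss(
    txs: Sequence[TranscriptModel],
    clusters: Sequence[CTSSCluster],
    tolerance: int = 0,
) -> Tuple[List[TranscriptModel], Dict[str, CTSSCluster]]:
    """Keep transcripts whose TSS matches a dominant CAGE start site.

    A transcript is retained iff a cluster on its chromosome and strand has
    its dominant position within ``tolerance`` bp of the annotated TSS; the
    matched cluster is returned for TSS-shape features.
    """
    by_key: Dict[Tuple[str, str], List[CTSSCluster]] = {}
    for c in clusters:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    dom_sorted: Dict[Tuple[str, str], Tuple[np.ndarray, List[CTSSCluster]]] = {}
    for key, cl in by_key.items():
        cl.sort(key=lambda c: c.dominant_position)
        dom_sorted[key] = (np.array([c.dominant_position for c in cl]), cl)

    kept, match = [], {}
    for t in txs:
        entry = dom_sorted.get((t.chrom, t.strand))
        if entry is None:
            continue
        doms, cl = entry
        i = int(np.searchsorted(doms, t.tss))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(doms) and abs(int(doms[j]) - t.tss) <= tolerance:
                if best is None or abs(int(doms[j]) - t.tss) < abs(
                    int(doms[best]) - t.tss
                ):
                    best = j
        if best is not None:
            kept.append(t)
            match[t.transcript_id] = cl[best]
    return kept, match


def aggregate_cage_replicates(
    replicates: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Aggregate the two most correlated CAGE replicates into one TPM table.

    Replicate tables have columns (chrom, position, strand, count). The pair
    with the highest Pearson correlation of counts over shared positions is
    summed and normalized to tags per million.
    """
    names = list(replicates)
    if len(names) < 2:
        df = replicates[names[0]].copy()
    else:
        best_pair, best_rho = None, -np.inf
        indexed = {
            n: d.set_index(["chrom", "position", "strand"])["count"]
            for n, d in replicates.items()
        }
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = indexed[names[i]], indexed[names[j]]
                shared = a.index.intersection(b.index)
                if len(shared) < 3:
                    rho = -np.inf
                else:
                    av, bv = a.loc[shared], b.loc[shared]
                    if av.std() == 0 or bv.std() == 0:
                        rho = -np.inf
                    else:
                        rho = float(np.corrcoef(av, bv)[0, 1])
                if rho > best_rho:
                    best_rho, best_pair = rho, (names[i], names[j])
        a = replicates[best_pair[0]].set_index(["chrom", "position", "strand"])
        b = replicates[best_pair[1]].set_index(["chrom", "position", "strand"])
        df = a["count"].add(b["count"], fill_value=0).reset_index()
    total = df["count"].sum()
    if total <= 0:
        raise ValueError("no CAGE counts to normalize")
    df = df.rename(columns={"count": "tpm"})
    df["tpm"] = df["tpm"] / total * 1e6
    return df[["chrom", "position", "strand", "tpm"]]
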
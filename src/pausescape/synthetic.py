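"""Seeded synthetic data bundles with planted pausing structure.

The generator emulates the input universe of the pausing analysis on a small
random genome: non-overlapping multi-exon protein-coding transcripts plus
interspersed non-coding RNAs (including a 7SK gene and pseudo copies),
CpG islands at a fraction of promoters, per-factor ChIP/CLIP peak files,
strand-specific nascent-transcription coverage, a two-replicate FPKM table
anti-correlated with pausing, and a per-position CAGE TPM table clustered at
TSSs.

The planted model is

    y_i = beta0 + sum_{f,r} beta[f,r] X[i,f,r] + interactions + gamma * ann_i + eps_i

where ``X`` are per-(factor, region) binding indicators, ``interactions``
are pairwise products of causal indicator columns (they make the truth
non-additive, which is what separates tree learners from a linear model),
``ann_i`` are standardized annotation covariates (GC content, log length)
and ``eps_i ~ N(0, sigma^2)``. By default ``sigma`` is calibrated so a
regression on the true design explains ~70% of variance. Coverage is
Poisson: the gene body has per-base rate proportional to expression and the
three TSS-window bases are scaled by ``2^y_i``, so the measured pausing
index recovers ``y_i`` up to counting noise.

Deliberate irregularities exercise every exclusion filter: one same-strand
overlapping coding pair, transcripts containing an N, transcripts with a
zero replicate, shifted dominant CAGE sites, and zero-coverage transcripts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import ExpressionRecord, TranscriptModel, derive_regions
from .features import CpGIslandRecord, make_column_name
from .genomic_io import (
    Peak,
    write_bed,
    write_fasta,
    write_gtf,
    write_wig_pair,
)
from .intervals import GenomicInterval, GenomeSequence, SignalTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneratorConfig:
    # layout
    n_genes: int = 3000
    n_ncrnas: int = 150
    n_chromosomes: int = 4
    tx_len_min: int = 900
    tx_len_max: int = 2000
    gap_min: int = 300
    gap_max: int = 800
    max_exons: int = 6
    # factors and effects
    n_factors: int = 60
    n_causal: int = 10
    beta_min: float = 0.6
    beta_max: float = 1.0
    n_interactions: int = 8
    interaction_scale: float = 1.5
    annotation_effect: float = 0.2
    oracle_r2: float = 0.7
    noise_sigma: Optional[float] = None  # None -> calibrate to oracle_r2
    p_bind_min: float = 0.10
    p_bind_max: float = 0.30
    p_bind_causal: float = 0.5  # binding probability of causal columns
    p_bind_ncrna: float = 0.15
    n_polii_factors: int = 2
    n_7sk_binders: int = 6
    n_pseudo_7sk: int = 3
    # expression / coverage
    expression_intercept: float = 1.0
    expression_slope: float = 0.301  # log10 FPKM lost per PI log2 unit
    expression_noise: float = 0.25
    replicate_noise: float = 0.05
    depth: float = 10.0  # body per-base Poisson rate at FPKM 10
    # sequence composition
    background_gc: float = 0.45
    promoter_gc: float = 0.60
    cpg_island_fraction: float = 0.6
    # filter-exercising irregularities
    n_overlapping_pairs: int = 1
    n_non_acgt: int = 2
    non_refseq_fraction: float = 0.03
    unexpressed_fraction: float = 0.02
    shifted_ctss_fraction: float = 0.05
    zero_coverage_fraction: float = 0.01
    housekeeping_fraction: float = 0.1
    # second cell line
    perturbed_factor_fraction: float = 0.3
    missing_factor_fraction: float = 0.15
    exclusive_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_factors:
            raise ValueError("n_causal must be <= n_factors")
        if self.noise_sigma is not None and self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not (0 < self.oracle_r2 < 1):
            raise ValueError("oracle_r2 must be in (0, 1)")
        for p in (self.p_bind_min, self.p_bind_max, self.p_bind_ncrna):
            if not (0 <= p <= 1):
                raise ValueError("binding probabilities must be in [0, 1]")


@dataclass
class SyntheticTruth:
    y: pd.Series  # true log2 PI per coding transcript
    X: pd.DataFrame  # transcripts x (assay.FACTOR.region) indicators
    beta: Dict[str, float]  # nonzero main effects per design column
    interactions: List[Tuple[str, str, float]]
    causal_factors: List[str]
    sevenk_binders: List[str]
    log10_fpkm: pd.Series
    sigma: float
    seed: int


@dataclass
class AnnotationBundle:
    genome: GenomeSequence
    transcripts: List[TranscriptModel]  # protein-coding
    ncrnas: List[TranscriptModel]
    islands: Dict[str, List[CpGIslandRecord]]
    housekeeping: Set[str]
    chrom_order: List[str]
    # transcripts that must survive the expression/CAGE filters so the
    # deliberate overlap exclusion is exercised downstream
    protected: Set[str] = None


@dataclass
class Bundle:
    cfg: GeneratorConfig
    seed: int
    annotation: AnnotationBundle
    peaks: List[Peak]
    track: SignalTrack
    expression: Dict[str, ExpressionRecord]
    ncrna_expression: Dict[str, float]
    ctss: pd.DataFrame
    go_annotation: pd.DataFrame
    sequence_specific: List[str]
    factor_assay: Dict[str, str]
    truth: SyntheticTruth


# ------------------------------------------------------------------ layout


def _segment_lengths(rng, total: int, n_seg: int, min_len: int = 40) -> List[int]:
    if n_seg == 1:
        return [total]
    w = rng.dirichlet(np.full(n_seg, 2.0))
    lens = np.maximum(min_len, np.round(w * total).astype(int))
    lens[-1] = max(min_len, total - int(lens[:-1].sum()))
    return list(lens)


def _make_transcript(
    rng,
    tid: str,
    gid: str,
    symbol: str,
    chrom: str,
    start: int,
    length: int,
    biotype: str,
    max_exons: int,
    refseq: bool = True,
    strand: Optional[str] = None,
) -> TranscriptModel:
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(1, max_exons + 1))
    seg = _segment_lengths(rng, length, 2 * n_ex - 1)
    exons, pos = [], start
    for i, L in enumerate(seg):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + L, strand))
        pos += L
    span = GenomicInterval(chrom, start, pos, strand)
    cds = None
    if biotype == "protein_coding":
        first, last = exons[0], exons[-1]
        cs = first.start + min(100, first.length // 2)
        ce = last.end - min(100, last.length // 2)
        if cs < ce:
            cds = GenomicInterval(chrom, cs, ce, strand)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        span=span,
        exons=exons,
        biotype=biotype,
        refseq_supported=refseq,
        cds_span=cds,
    )


def generate_annotation(cfg: GeneratorConfig, seed: int) -> AnnotationBundle:
    """Genome, transcript annotation, CpG islands and housekeeping list."""
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    nc_per_chrom = np.full(cfg.n_chromosomes, cfg.n_ncrnas // cfg.n_chromosomes)
    nc_per_chrom[: cfg.n_ncrnas % cfg.n_chromosomes] += 1

    transcripts: List[TranscriptModel] = []
    ncrnas: List[TranscriptModel] = []
    chrom_seq: Dict[str, np.ndarray] = {}
    islands: Dict[str, List[CpGIslandRecord]] = {c: [] for c in chroms}
    island_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    gene_i = nc_i = 0
    nc_biotypes = ("miscRNA", "miRNA", "snoRNA", "snRNA", "lincRNA")
    sevenk_ids = []
    for ci, chrom in enumerate(chroms):
        pos = int(rng.integers(200, 500))
        n_g, n_nc = int(per_chrom[ci]), int(nc_per_chrom[ci])
        # interleave genes and ncRNAs deterministically
        events = ["g"] * n_g + ["n"] * n_nc
        rng.shuffle(events)
        for ev in events:
            if ev == "g":
                gene_i += 1
                length = int(rng.integers(cfg.tx_len_min, cfg.tx_len_max + 1))
                tx = _make_transcript(
                    rng,
                    f"TX{gene_i:05d}",
                    f"G{gene_i:05d}",
                    f"GENE{gene_i:05d}",
                    chrom,
                    pos,
                    length,
                    "protein_coding",
                    cfg.max_exons,
                    refseq=rng.random() >= cfg.non_refseq_fraction,
                )
                transcripts.append(tx)
                if rng.random() < cfg.cpg_island_fraction:
                    half = int(rng.integers(100, 500))
                    s = max(0, tx.tss - half)
                    island_spans[chrom].append((s, tx.tss + half))
                pos = tx.span.end + int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
            else:
                nc_i += 1
                length = int(rng.integers(200, 400))
                biotype = nc_biotypes[int(rng.integers(len(nc_biotypes)))]
                nc = _make_transcript(
                    rng,
                    f"NC{nc_i:05d}",
                    f"NCG{nc_i:05d}",
                    f"NCRNA{nc_i:05d}",
                    chrom,
                    pos,
                    length,
                    biotype,
                    3,
                )
                ncrnas.append(nc)
                pos = nc.span.end + int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
        chrom_seq[chrom] = None  # placeholder; filled after layout
        chrom_seq[chrom] = pos + int(rng.integers(200, 500))  # chrom length

    # rename some ncRNAs into the 7SK family: one real + pseudo copies
    sevenk = [nc for nc in ncrnas if nc.chrom == chroms[0]][: cfg.n_pseudo_7sk + 1]
    if len(sevenk) < cfg.n_pseudo_7sk + 1:
        sevenk = ncrnas[: cfg.n_pseudo_7sk + 1]
    for i, nc in enumerate(sevenk):
        if i == 0:
            nc.gene_symbol, nc.biotype = "RN7SK", "snRNA"
        else:
            nc.gene_symbol, nc.biotype = f"RN7SKP{i}", "pseudogene"
        sevenk_ids.append(nc.transcript_id)

    # sequence: background GC with elevated GC at promoters and islands
    sequences: Dict[str, str] = {}
    for chrom in chroms:
        L = int(chrom_seq[chrom])
        p_bg = cfg.background_gc / 2
        probs = np.array([0.5 - p_bg, p_bg, p_bg, 0.5 - p_bg])  # A C G T
        seq = rng.choice(4, size=L, p=probs).astype(np.uint8)
        for tx in transcripts:
            if tx.chrom != chrom:
                continue
            s, e = max(0, tx.tss - 200), min(L, tx.tss + 200)
            p_gc = cfg.promoter_gc / 2
            pr = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])
            seq[s:e] = rng.choice(4, size=e - s, p=pr).astype(np.uint8)
        for s, e in island_spans[chrom]:
            e = min(e, L)
            # CpG-rich: draw dinucleotides with frequent CG pairs
            n = e - s
            block = rng.choice(4, size=n, p=[0.2, 0.3, 0.3, 0.2]).astype(np.uint8)
            cg_at = np.nonzero(rng.random(max(0, n - 1)) < 0.15)[0]
            block[cg_at] = 1  # C
            block[cg_at + 1] = 2  # G
            seq[s:e] = block
        sequences[chrom] = _BASES[seq].tobytes().decode("ascii")

    # deliberate same-strand overlapping coding pairs
    extra = []
    protected: Set[str] = set()
    coding_sorted = sorted(transcripts, key=lambda t: (t.chrom, t.span.start))
    for k in range(cfg.n_overlapping_pairs):
        host = coding_sorted[int(rng.integers(len(coding_sorted)))]
        host.refseq_supported = True
        protected.add(host.transcript_id)
        start = host.span.start + host.length // 3
        length = max(400, host.length // 2)
        ov = _make_transcript(
            rng,
            f"TXOVL{k + 1:02d}",
            f"GOVL{k + 1:02d}",
            f"GENEOVL{k + 1:02d}",
            host.chrom,
            start,
            length,
            "protein_coding",
            cfg.max_exons,
            strand=host.strand,
        )
        extra.append(ov)
    transcripts.extend(extra)

    # plant non-ACGT letters inside a few transcript spans (never the
    # overlap hosts, which must reach the overlap filter intact)
    eligible = [
        i
        for i in range(len(transcripts) - len(extra))
        if transcripts[i].transcript_id not in protected
    ]
    chosen = rng.choice(eligible, size=cfg.n_non_acgt, replace=False)
    for idx in chosen:
        tx = transcripts[int(idx)]
        seq = sequences[tx.chrom]
        p = tx.span.start + tx.length // 2
        sequences[tx.chrom] = seq[:p] + "N" + seq[p + 1 :]

    genome = GenomeSequence(sequences)
    for chrom in chroms:
        for s, e in island_spans[chrom]:
            iv = GenomicInterval(chrom, s, min(e, genome.length(chrom)))
            islands[chrom].append(CpGIslandRecord.from_sequence(iv, genome.fetch(iv)))
        islands[chrom].sort(key=lambda r: r.interval.start)

    n_hk = int(round(cfg.housekeeping_fraction * cfg.n_genes))
    hk_idx = rng.choice(cfg.n_genes, size=n_hk, replace=False)
    housekeeping = {transcripts[int(i)].gene_id for i in hk_idx}

    return AnnotationBundle(
        genome=genome,
        transcripts=transcripts,
        ncrnas=ncrnas,
        islands=islands,
        housekeeping=housekeeping,
        chrom_order=chroms,
        protected=protected,
    )


# ----------------------------------------------------------------- binding


def _factor_names(cfg: GeneratorConfig) -> Tuple[Dict[str, str], List[str]]:
    """(factor -> assay) for regular factors, plus the Pol II factor names."""
    n_chip = cfg.n_factors // 2
    names = {}
    for i in range(cfg.n_factors):
        if i < n_chip:
            names[f"FCH{i + 1:03d}"] = "chip"
        else:
            names[f"FCL{i + 1 - n_chip:03d}"] = "clip"
    polii = [f"POLR2{chr(ord('A') + i)}" for i in range(cfg.n_polii_factors)]
    return names, polii


from .annotation import REGION_NAMES  # noqa: E402


def _causal_plan(
    cfg: GeneratorConfig, factor_assay: Mapping[str, str], rng
) -> Tuple[Dict[str, float], List[Tuple[str, str, float]], List[str]]:
    """Pick causal factors, one effect column each, and interaction pairs."""
    factors = list(factor_assay)
    causal = sorted(rng.choice(factors, size=cfg.n_causal, replace=False).tolist())
    beta: Dict[str, float] = {}
    for f in causal:
        r = REGION_NAMES[int(rng.integers(len(REGION_NAMES)))]
        col = make_column_name(factor_assay[f], f, r)
        mag = rng.uniform(cfg.beta_min, cfg.beta_max)
        beta[col] = float(mag if rng.random() < 0.5 else -mag)
    causal_cols = sorted(beta)
    interactions: List[Tuple[str, str, float]] = []
    if len(causal_cols) >= 2:
        for _ in range(cfg.n_interactions):
            i, j = rng.choice(len(causal_cols), size=2, replace=False)
            w = cfg.interaction_scale * (1 if rng.random() < 0.5 else -1)
            interactions.append((causal_cols[int(i)], causal_cols[int(j)], float(w)))
    return beta, interactions, causal


def plant_binding_sites(
    annotation: AnnotationBundle,
    cfg: GeneratorConfig,
    seed: int,
    plan: Optional[Tuple[Dict[str, float], List[Tuple[str, str, float]], List[str]]] = None,
) -> Tuple[
    List[Peak],
    pd.DataFrame,
    Dict[str, str],
    List[str],
    pd.DataFrame,
    Tuple[Dict[str, float], List[Tuple[str, str, float]], List[str]],
]:
    """Draw binding indicators and place one peak per positive indicator.

    Returns (peaks, X, factor_assay, sevenk_binders, p_bind table, plan).
    Peaks are placed strictly inside a single region interval so that
    re-encoding the BED files through the feature module reproduces X
    exactly. Causal columns (chosen by the seeded causal plan, or the plan
    passed in) bind at ``p_bind_causal`` so their indicators are balanced;
    the designated 7SK-binding CLIP factors additionally receive a peak on
    each 7SK transcript; no other CLIP factor touches the 7SK family.
    """
    rng = np.random.default_rng(seed)
    factor_assay, _polii = _factor_names(cfg)
    factors = list(factor_assay)
    coding = [t for t in annotation.transcripts if not t.transcript_id.startswith("TXOVL")]
    regions = {t.transcript_id: derive_regions(t).by_name() for t in coding}

    p_bind = pd.DataFrame(
        rng.uniform(cfg.p_bind_min, cfg.p_bind_max, size=(len(factors), len(REGION_NAMES))),
        index=factors,
        columns=list(REGION_NAMES),
    )
    if plan is None:
        plan = _causal_plan(cfg, factor_assay, np.random.default_rng(seed + 1000))
    beta_plan = plan[0]
    from .features import parse_column_name

    for col in beta_plan:
        _assay, f, r, _rk = parse_column_name(col)
        p_bind.loc[f, r] = cfg.p_bind_causal

    cols = [
        make_column_name(factor_assay[f], f, r) for f in factors for r in REGION_NAMES
    ]
    ids = [t.transcript_id for t in coding]
    X = np.zeros((len(coding), len(cols)), dtype=np.int8)
    peaks: List[Peak] = []

    def _place(iv_list, strand, factor, assay):
        iv = iv_list[int(rng.integers(len(iv_list)))]
        w = min(iv.length, int(rng.integers(30, 121)))
        s = iv.start + int(rng.integers(0, iv.length - w + 1))
        pstrand = strand if assay == "clip" else "."
        peaks.append(
            Peak(GenomicInterval(iv.chrom, s, s + w, pstrand), factor, assay)
        )

    col_i = 0
    for f in factors:
        assay = factor_assay[f]
        for r in REGION_NAMES:
            draw = rng.random(len(coding)) < p_bind.loc[f, r]
            for ti, tx in enumerate(coding):
                if not draw[ti]:
                    continue
                iv_list = regions[tx.transcript_id][r]
                if not iv_list:
                    continue
                X[ti, col_i] = 1
                _place(iv_list, tx.strand, f, assay)
            col_i += 1

    # ncRNA binding (for proximal-ncRNA features); 7SK family kept clean
    sevenk_txs = [n for n in annotation.ncrnas if n.gene_symbol.startswith("RN7SK")]
    sevenk_ids = {n.transcript_id for n in sevenk_txs}
    clip_factors = [f for f in factors if factor_assay[f] == "clip"]
    binders = sorted(
        rng.choice(clip_factors, size=cfg.n_7sk_binders, replace=False).tolist()
    )
    for nc in annotation.ncrnas:
        nc_regions = derive_regions(nc).by_name()
        for f in factors:
            if nc.transcript_id in sevenk_ids and factor_assay[f] == "clip":
                continue  # only designated binders touch 7SK
            if rng.random() >= cfg.p_bind_ncrna:
                continue
            region_choices = [r for r in REGION_NAMES if nc_regions[r]]
            if not region_choices:
                continue
            r = region_choices[int(rng.integers(len(region_choices)))]
            _place(nc_regions[r], nc.strand, f, factor_assay[f])
    for f in binders:
        for nc in sevenk_txs:
            _place([nc.span], nc.strand, f, "clip")

    Xdf = pd.DataFrame(X, index=ids, columns=cols, dtype=np.int8)
    return peaks, Xdf, factor_assay, binders, p_bind, plan


# ------------------------------------------------------------------- truth


def build_truth(
    cfg: GeneratorConfig,
    annotation: AnnotationBundle,
    X: pd.DataFrame,
    factor_assay: Mapping[str, str],
    sevenk_binders: Sequence[str],
    seed: int,
    plan: Optional[Tuple[Dict[str, float], List[Tuple[str, str, float]], List[str]]] = None,
) -> SyntheticTruth:
    """Draw (or take) effects and compose the true pausing index."""
    rng = np.random.default_rng(seed)
    if plan is None:
        plan = _causal_plan(cfg, factor_assay, rng)
    beta, interactions, causal = plan

    g = np.zeros(len(X))
    for col, b in beta.items():
        g += b * X[col].to_numpy(dtype=float)
    for ca, cb, w in interactions:
        g += w * X[ca].to_numpy(dtype=float) * X[cb].to_numpy(dtype=float)

    by_id = {t.transcript_id: t for t in annotation.transcripts}
    gc, loglen = [], []
    for tid in X.index:
        tx = by_id[tid]
        seq = annotation.genome.fetch(tx.span)
        gc.append((seq.count("G") + seq.count("C")) / len(seq))
        loglen.append(np.log10(tx.length))
    gc, loglen = np.array(gc), np.array(loglen)

    def _std(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v * 0

    g += cfg.annotation_effect * _std(gc) - cfg.annotation_effect * _std(loglen)

    sigma = cfg.noise_sigma
    if sigma is None:
        sg = float(np.std(g))
        sigma = sg * np.sqrt((1 - cfg.oracle_r2) / cfg.oracle_r2)
        sigma = max(sigma, 1e-6)
    eps = rng.normal(0.0, sigma, size=len(X))
    y = pd.Series(g + eps, index=X.index, name="true_pi")

    log10_fpkm = pd.Series(
        cfg.expression_intercept
        - cfg.expression_slope * y.to_numpy()
        + rng.normal(0.0, cfg.expression_noise, size=len(y)),
        index=X.index,
        name="log10_fpkm",
    )
    return SyntheticTruth(
        y=y,
        X=X,
        beta=beta,
        interactions=interactions,
        causal_factors=causal,
        sevenk_binders=list(sevenk_binders),
        log10_fpkm=log10_fpkm,
        sigma=float(sigma),
        seed=seed,
    )


# ------------------------------------------------------------------ signals


def simulate_signals(
    truth: SyntheticTruth,
    annotation: AnnotationBundle,
    cfg: GeneratorConfig,
    seed: int,
) -> Tuple[SignalTrack, Dict[str, ExpressionRecord], pd.DataFrame]:
    """Poisson coverage, replicate FPKM table, and CAGE CTSS table."""
    if cfg.depth <= 0:
        raise ValueError("sequencing depth must be > 0")
    rng = np.random.default_rng(seed)
    by_id = {t.transcript_id: t for t in annotation.transcripts}
    ids = list(truth.y.index)
    n = len(ids)

    protected = annotation.protected or set()
    zero_cov = set(
        np.array(ids)[
            rng.choice(n, size=int(round(cfg.zero_coverage_fraction * n)), replace=False)
        ]
    ) - protected
    unexpressed = set(
        np.array(ids)[
            rng.choice(n, size=int(round(cfg.unexpressed_fraction * n)), replace=False)
        ]
    ) - protected
    shifted = set(
        np.array(ids)[
            rng.choice(n, size=int(round(cfg.shifted_ctss_fraction * n)), replace=False)
        ]
    ) - protected

    expression: Dict[str, ExpressionRecord] = {}
    fpkm_mean: Dict[str, float] = {}
    for tid in ids:
        mu = truth.log10_fpkm[tid]
        r1 = 10 ** (mu + rng.normal(0, cfg.replicate_noise))
        r2 = 10 ** (mu + rng.normal(0, cfg.replicate_noise))
        if tid in unexpressed:
            r2 = 0.0
        expression[tid] = ExpressionRecord(tid, float(r1), float(r2))
        fpkm_mean[tid] = (r1 + r2) / 2 if tid not in unexpressed else r1

    # extra transcripts (overlap pairs) still need expression + coverage
    extras = [t for t in annotation.transcripts if t.transcript_id not in set(ids)]
    for t in extras:
        expression[t.transcript_id] = ExpressionRecord(t.transcript_id, 10.0, 10.0)
        fpkm_mean[t.transcript_id] = 10.0

    cov: Dict[Tuple[str, str], List[Tuple[np.ndarray, np.ndarray]]] = {}
    y_all = dict(truth.y)
    for t in extras:
        y_all[t.transcript_id] = 0.0
    for tid, tx in ((i, by_id[i]) for i in list(ids) + [t.transcript_id for t in extras]):
        if tid in zero_cov:
            continue
        lam = cfg.depth * fpkm_mean[tid] / 10.0
        t0 = tx.tss
        pos = np.arange(tx.span.start, tx.span.end, dtype=np.int64)
        rates = np.full(len(pos), lam)
        # TSS signal concentrated within +-1 bp of the start site
        win = (pos >= t0 - 1) & (pos <= t0 + 1)
        rates[win] = lam * 2.0 ** y_all[tid]
        if t0 - 1 < tx.span.start:  # upstream window base outside the span
            up = np.arange(t0 - 1, tx.span.start, dtype=np.int64)
            pos = np.concatenate([up, pos])
            rates = np.concatenate([np.full(len(up), lam * 2.0 ** y_all[tid]), rates])
        if t0 + 1 >= tx.span.end:
            dn = np.arange(tx.span.end, t0 + 2, dtype=np.int64)
            pos = np.concatenate([pos, dn])
            rates = np.concatenate([rates, np.full(len(dn), lam * 2.0 ** y_all[tid])])
        counts = rng.poisson(rates)
        nz = counts > 0
        cov.setdefault((tx.chrom, tx.strand), []).append((pos[nz], counts[nz]))

    track = SignalTrack()
    for (chrom, strand), chunks in cov.items():
        pos = np.concatenate([c[0] for c in chunks])
        val = np.concatenate([c[1] for c in chunks]).astype(float)
        # overlapping transcripts contribute additively
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        uniq, idx = np.unique(pos, return_index=True)
        summed = np.add.reduceat(val, idx)
        track.add(chrom, strand, uniq, summed)

    rows = []
    for tid in ids + [t.transcript_id for t in extras]:
        tx = by_id[tid]
        t0, strand, chrom = tx.tss, tx.strand, tx.chrom
        base = max(fpkm_mean[tid], 0.2)
        direction = 1 if strand == "+" else -1
        if tid in shifted:
            dom = t0 + 3 * direction
            rows += [
                (chrom, dom, strand, base),
                (chrom, t0, strand, 0.5 * base),
                (chrom, t0 + 2 * direction, strand, 0.2 * base),
            ]
        else:
            rows += [
                (chrom, t0, strand, base),
                (chrom, t0 + 2 * direction, strand, 0.3 * base),
                (chrom, t0 - 2 * direction, strand, 0.25 * base),
                (chrom, t0 + 5 * direction, strand, 0.1 * base),
            ]
    # sub-threshold background singletons
    for _ in range(50):
        chrom = annotation.chrom_order[int(rng.integers(len(annotation.chrom_order)))]
        p = int(rng.integers(0, annotation.genome.length(chrom)))
        rows.append((chrom, p, "+" if rng.random() < 0.5 else "-", 1e-4))
    ctss = pd.DataFrame(rows, columns=["chrom", "position", "strand", "tpm"])
    ctss = ctss.groupby(["chrom", "position", "strand"], as_index=False)["tpm"].max()
    ctss["tpm"] = ctss["tpm"] / ctss["tpm"].sum() * 1e6
    return track, expression, ctss


def plant_polii_peaks(
    truth: SyntheticTruth,
    annotation: AnnotationBundle,
    cfg: GeneratorConfig,
    seed: int,
) -> List[Peak]:
    """Pol II ChIP peaks whose presence tracks the true pausing index."""
    rng = np.random.default_rng(seed)
    _, polii = _factor_names(cfg)
    by_id = {t.transcript_id: t for t in annotation.transcripts}
    y = truth.y
    med, sd = float(y.median()), float(y.std()) or 1.0
    peaks: List[Peak] = []
    for i, f in enumerate(polii):
        p_bind = 1.0 / (1.0 + np.exp(-(y - med) / (0.5 * sd) - 0.3 * i))
        bound = rng.random(len(y)) < p_bind.to_numpy()
        for tid, hit in zip(y.index, bound):
            if not hit:
                continue
            tx = by_id[tid]
            s = max(0, tx.tss - 15)
            peaks.append(Peak(GenomicInterval(tx.chrom, s, tx.tss + 15, "."), f, "chip"))
    return peaks


# ----------------------------------------------------------------- catalogs


def _factor_catalogs(
    cfg: GeneratorConfig, factor_assay: Mapping[str, str], seed: int
) -> Tuple[pd.DataFrame, List[str]]:
    """Random GO annotation table and sequence-specificity catalog."""
    from .factor_sets import load_default_term_map

    rng = np.random.default_rng(seed)
    term_map = load_default_term_map()
    all_terms = [g for ids in term_map.values() for g in ids]
    factors = list(factor_assay)
    rows = []
    for i, f in enumerate(factors):
        # guarantee coverage of every set, then add random extra annotations
        if i < len(all_terms):
            rows.append((f, all_terms[i]))
        n_extra = int(rng.integers(0, 3))
        for t in rng.choice(all_terms, size=n_extra, replace=False):
            rows.append((f, t))
    go = pd.DataFrame(rows, columns=["factor", "go_id"]).drop_duplicates()
    n_spec = int(round(0.4 * len(factors)))
    specific = sorted(rng.choice(factors, size=n_spec, replace=False).tolist())
    return go, specific


def _ncrna_expression(
    annotation: AnnotationBundle, cfg: GeneratorConfig, seed: int
) -> Dict[str, float]:
    """ncRNA FPKMs; the first pseudo 7SK is highly expressed, the rest low."""
    rng = np.random.default_rng(seed)
    out: Dict[str, float] = {}
    for nc in annotation.ncrnas:
        out[nc.transcript_id] = float(10 ** rng.normal(0.5, 0.4))
    vals = np.array(list(out.values()))
    hi, lo = float(np.quantile(vals, 0.95)), float(np.quantile(vals, 0.02))
    pseudo = [n for n in annotation.ncrnas if n.gene_symbol.startswith("RN7SKP")]
    for i, nc in enumerate(pseudo):
        out[nc.transcript_id] = hi if i == 0 else lo
    real = [n for n in annotation.ncrnas if n.gene_symbol == "RN7SK"]
    for nc in real:
        out[nc.transcript_id] = hi * 2
    return out


# ------------------------------------------------------------------ bundles


def generate_bundle(cfg: GeneratorConfig, seed: Optional[int] = None) -> Bundle:
    """Generate a complete single-cell-line bundle with ground truth."""
    seed = cfg.seed if seed is None else seed
    annotation = generate_annotation(cfg, seed)
    peaks, X, factor_assay, binders, _p, plan = plant_binding_sites(
        annotation, cfg, seed + 1
    )
    truth = build_truth(cfg, annotation, X, factor_assay, binders, seed + 2, plan=plan)
    track, expression, ctss = simulate_signals(truth, annotation, cfg, seed + 3)
    peaks = peaks + plant_polii_peaks(truth, annotation, cfg, seed + 4)
    go, specific = _factor_catalogs(cfg, factor_assay, seed + 5)
    return Bundle(
        cfg=cfg,
        seed=seed,
        annotation=annotation,
        peaks=peaks,
        track=track,
        expression=expression,
        ncrna_expression=_ncrna_expression(annotation, cfg, seed + 6),
        ctss=ctss,
        go_annotation=go,
        sequence_specific=specific,
        factor_assay=factor_assay,
        truth=truth,
    )


def generate_pair(cfg: GeneratorConfig, seed: Optional[int] = None) -> Tuple[Bundle, Bundle]:
    """Two cell lines sharing genome/annotation and effect sizes.

    Cell line B re-draws the binding indicators of a random factor subset
    (cell-specific binding under shared rules), drops a further factor
    subset entirely (not assayed in B), and each line has an exclusive set
    of transcripts unexpressed in the other.
    """
    seed = cfg.seed if seed is None else seed
    a = generate_bundle(cfg, seed)
    rng = np.random.default_rng(seed + 100)
    factors = list(a.factor_assay)
    n_pert = int(round(cfg.perturbed_factor_fraction * len(factors)))
    # cell-specific binding must involve the causal factors, otherwise the
    # between-line PI differences are pure noise; re-draw every causal
    # factor's binding in B, fill up with non-causal factors
    perturbed = set(a.truth.causal_factors)
    pool = [f for f in factors if f not in perturbed]
    if n_pert > len(perturbed):
        perturbed |= set(
            rng.choice(pool, size=n_pert - len(perturbed), replace=False).tolist()
        )
    remaining = [f for f in factors if f not in perturbed]
    n_miss = int(round(cfg.missing_factor_fraction * len(factors)))
    missing = set(rng.choice(remaining, size=n_miss, replace=False).tolist())

    # B: re-plant bindings for perturbed factors; recompute y with same betas
    plan_a = (a.truth.beta, a.truth.interactions, a.truth.causal_factors)
    peaks_b, X_b, _fa, binders_b, _pb, _plan = plant_binding_sites(
        a.annotation, cfg, seed + 101, plan=plan_a
    )
    X_mixed = a.truth.X.copy()
    pert_cols = [
        c
        for c in X_mixed.columns
        if c.split(".")[1] in perturbed
    ]
    X_mixed[pert_cols] = X_b[pert_cols]

    rng_b = np.random.default_rng(seed + 102)
    g = np.zeros(len(X_mixed))
    for col, bta in a.truth.beta.items():
        g += bta * X_mixed[col].to_numpy(dtype=float)
    for ca, cb, w in a.truth.interactions:
        g += w * X_mixed[ca].to_numpy(dtype=float) * X_mixed[cb].to_numpy(dtype=float)
    by_id = {t.transcript_id: t for t in a.annotation.transcripts}
    gc = np.array(
        [
            (s.count("G") + s.count("C")) / len(s)
            for s in (a.annotation.genome.fetch(by_id[i].span) for i in X_mixed.index)
        ]
    )
    loglen = np.array([np.log10(by_id[i].length) for i in X_mixed.index])

    def _std(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v * 0

    g += cfg.annotation_effect * _std(gc) - cfg.annotation_effect * _std(loglen)
    eps = rng_b.normal(0, a.truth.sigma, size=len(g))
    y_b = pd.Series(g + eps, index=X_mixed.index)
    log10_b = pd.Series(
        cfg.expression_intercept
        - cfg.expression_slope * y_b.to_numpy()
        + rng_b.normal(0, cfg.expression_noise, size=len(y_b)),
        index=X_mixed.index,
    )
    truth_b = SyntheticTruth(
        y=y_b,
        X=X_mixed,
        beta=a.truth.beta,
        interactions=a.truth.interactions,
        causal_factors=a.truth.causal_factors,
        sevenk_binders=a.truth.sevenk_binders,
        log10_fpkm=log10_b,
        sigma=a.truth.sigma,
        seed=seed + 101,
    )
    track_b, expr_b, ctss_b = simulate_signals(truth_b, a.annotation, cfg, seed + 103)

    # peaks for B: keep A's placements for unperturbed, B's for perturbed,
    # drop missing factors entirely
    def factor_of(p: Peak) -> str:
        return p.factor

    peaks_final_b = [
        p
        for p in a.peaks
        if factor_of(p) not in perturbed and factor_of(p) not in missing
    ] + [p for p in peaks_b if factor_of(p) in perturbed and factor_of(p) not in missing]
    peaks_final_b += plant_polii_peaks(truth_b, a.annotation, cfg, seed + 104)

    # exclusive transcript sets
    ids = list(a.truth.y.index)
    n_ex = int(round(cfg.exclusive_fraction * len(ids)))
    pick = rng.choice(len(ids), size=2 * n_ex, replace=False)
    only_a = {ids[int(i)] for i in pick[:n_ex]}
    only_b = {ids[int(i)] for i in pick[n_ex:]}
    for tid in only_b:  # unexpressed in A
        r = a.expression[tid]
        a.expression[tid] = ExpressionRecord(tid, r.fpkm_rep1, 0.0)
    for tid in only_a:  # unexpressed in B
        r = expr_b[tid]
        expr_b[tid] = ExpressionRecord(tid, r.fpkm_rep1, 0.0)

    b = Bundle(
        cfg=cfg,
        seed=seed + 101,
        annotation=a.annotation,
        peaks=peaks_final_b,
        track=track_b,
        expression=expr_b,
        ncrna_expression=a.ncrna_expression,
        ctss=ctss_b,
        go_annotation=a.go_annotation,
        sequence_specific=a.sequence_specific,
        factor_assay={f: s for f, s in a.factor_assay.items() if f not in missing},
        truth=truth_b,
    )
    return a, b


# -------------------------------------------------------------------- files


def write_bundle(bundle: Bundle, outdir: str | Path) -> Dict[str, Path]:
    """Write a bundle to disk in the exact dialects the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    write_fasta(bundle.annotation.genome, paths["genome"])
    paths["gtf"] = out / "annotation.gtf"
    write_gtf(bundle.annotation.transcripts + bundle.annotation.ncrnas, paths["gtf"])

    paths["wig_plus"] = out / "groseq.plus.wig"
    paths["wig_minus"] = out / "groseq.minus.wig"
    write_wig_pair(bundle.track, paths["wig_plus"], paths["wig_minus"])

    expr = pd.DataFrame(
        [
            (tid, r.fpkm_rep1, r.fpkm_rep2)
            for tid, r in bundle.expression.items()
        ],
        columns=["transcript_id", "fpkm_rep1", "fpkm_rep2"],
    )
    paths["expression"] = out / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False)

    ncexpr = pd.DataFrame(
        list(bundle.ncrna_expression.items()), columns=["transcript_id", "fpkm"]
    )
    paths["ncrna_expression"] = out / "ncrna_expression.tsv"
    ncexpr.to_csv(paths["ncrna_expression"], sep="\t", index=False)

    paths["ctss"] = out / "ctss.tsv"
    bundle.ctss.to_csv(paths["ctss"], sep="\t", index=False)

    rows = []
    for chrom, recs in bundle.annotation.islands.items():
        for r in recs:
            rows.append(
                (
                    chrom,
                    r.interval.start,
                    r.interval.end,
                    r.length,
                    r.cpg_count,
                    r.percent_cg,
                    r.percent_cpg,
                    r.obs_exp_ratio,
                )
            )
    paths["cpg_islands"] = out / "cpg_islands.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "length",
            "cpg_count",
            "percent_cg",
            "percent_cpg",
            "obs_exp_ratio",
        ],
    ).to_csv(paths["cpg_islands"], sep="\t", index=False)

    paths["housekeeping"] = out / "housekeeping.txt"
    Path(paths["housekeeping"]).write_text(
        "\n".join(sorted(bundle.annotation.housekeeping)) + "\n"
    )

    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    by_factor: Dict[Tuple[str, str], List[Peak]] = {}
    for p in bundle.peaks:
        by_factor.setdefault((p.assay, p.factor), []).append(p)
    for (assay, factor), plist in sorted(by_factor.items()):
        write_bed(plist, peak_dir / f"{assay}.{factor}.bed")
    paths["peaks_dir"] = peak_dir

    paths["go_annotation"] = out / "go_annotation.tsv"
    bundle.go_annotation.to_csv(paths["go_annotation"], sep="\t", index=False)
    paths["sequence_specific"] = out / "sequence_specific.tsv"
    pd.DataFrame({"factor": bundle.sequence_specific}).to_csv(
        paths["sequence_specific"], sep="\t", index=False
    )

    truth = bundle.truth
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "sigma": truth.sigma,
                "beta": truth.beta,
                "interactions": truth.interactions,
                "causal_factors": truth.causal_factors,
                "sevenk_binders": truth.sevenk_binders,
                "y": {k: float(v) for k, v in truth.y.items()},
                "log10_fpkm": {k: float(v) for k, v in truth.log10_fpkm.items()},
            },
            fh,
        )
    return paths
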
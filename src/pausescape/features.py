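"""Transcript x feature matrix assembly.

Columns follow the ``<assay>.<FACTOR>.<region>`` naming convention, with
``.Proximal.ncRNA.<rank>`` appended for binding on the two nearest
non-coding RNAs; e.g. ``chip.RBFOX2.5prime`` flags a ChIP peak in the 5'
region of the transcript and ``clip.RBFOX2.intron.Proximal.ncRNA.2`` a CLIP
peak in an intron of the second-nearest ncRNA. Binding features are binary
presence/absence flags; the 18 annotation/sequence features (12 transcript-
level + 6 CpG-island) are min-max scaled to [0, 1].

Pol II subunits (POLR2 prefix, including phospho-isoforms) are held out of
the default matrix — their occupancy is the measured quantity itself — and
returned as a side table for the Pol II-only reference model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import (
    REGION_NAMES,
    CTSSCluster,
    RegionSet,
    TranscriptModel,
    derive_regions,
)
from .genomic_io import Peak
from .intervals import GenomicInterval, GenomeSequence

POLII_PATTERN = re.compile(r"^POLR2")

ANNOTATION_FEATURES = (
    "tx.len",
    "tx.strand",
    "tx.chr.loc",
    "tx.loc",
    "tx.ex.num",
    "tx.ex.width",
    "tx.ex.ratio",
    "tx.ex.seq",
    "tx.gc.seq",
    "tx.tss.width",
    "tx.tss.at.cont",
    "housekeeping",
)

CPG_FEATURES = (
    "cpg.island.dist",
    "cpg.island.length",
    "cpg.island.count",
    "cpg.island.percent.cg",
    "cpg.island.percent.cpg",
    "cpg.island.percent.exp.v.obs",
)

BINARY_ANNOTATION = frozenset({"tx.strand", "housekeeping"})


@dataclass
class CpGIslandRecord:
    interval: GenomicInterval
    cpg_count: int
    percent_cg: float
    percent_cpg: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.interval.length

    @classmethod
    def from_sequence(cls, iv: GenomicInterval, seq: str) -> "CpGIslandRecord":
        """Compute island statistics from its sequence.

        Observed/expected CpG ratio is (CpG count * length) / (C count * G
        count), the UCSC convention.
        """
        seq = seq.upper()
        n = len(seq)
        c, g = seq.count("C"), seq.count("G")
        cpg = seq.count("CG")
        obs_exp = (cpg * n) / (c * g) if c > 0 and g > 0 else 0.0
        return cls(
            interval=iv,
            cpg_count=cpg,
            percent_cg=(c + g) / n if n else 0.0,
            percent_cpg=cpg / n if n else 0.0,
            obs_exp_ratio=obs_exp,
        )


def make_column_name(
    assay: str, factor: str, region: str, rank: Optional[int] = None
) -> str:
    name = f"{assay}.{factor}.{region}"
    if rank is not None:
        name += f".Proximal.ncRNA.{rank}"
    return name


def parse_column_name(name: str) -> Tuple[str, str, str, Optional[int]]:
    """Invert :func:`make_column_name` -> (assay, factor, region, rank).

    Accepts the historical misspelling ``Proxmial`` as an alias.
    """
    rank: Optional[int] = None
    m = re.search(r"\.(?:Proximal|Proxmial)\.ncRNA\.(\d+)$", name)
    if m:
        rank = int(m.group(1))
        name = name[: m.start()]
    parts = name.split(".")
    if len(parts) < 3 or parts[0] not in ("chip", "clip"):
        raise ValueError(f"not a binding column name: {name!r}")
    assay, region = parts[0], parts[-1]
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region in column {name!r}")
    factor = ".".join(parts[1:-1])
    return assay, factor, region, rank


class PeakIndex:
    """Interval-tree index of peaks for overlap queries.

    ChIP peaks are strandless; CLIP peaks match only regions on the same
    strand when their strand is declared ('.' CLIP peaks match both).
    """

    def __init__(self, peaks: Iterable[Peak]):
        self._trees: Dict[Tuple[str, str, str], IntervalTree] = {}
        factors: Dict[str, set] = {"chip": set(), "clip": set()}
        for p in peaks:
            iv = p.interval
            strand = "." if p.assay == "chip" else iv.strand
            key = (p.assay, iv.chrom, strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                iv.start, iv.end, p.factor
            )
            factors[p.assay].add(p.factor)
        self.factors_by_assay: Dict[str, Tuple[str, ...]] = {
            a: tuple(sorted(fs)) for a, fs in factors.items()
        }

    def all_factors(self) -> List[Tuple[str, str]]:
        """Sorted (assay, factor) pairs present in the index."""
        return [
            (assay, f)
            for assay in ("chip", "clip")
            for f in self.factors_by_assay.get(assay, ())
        ]

    def query(self, iv: GenomicInterval) -> Dict[str, set]:
        """Factors with >= 1 bp overlap of iv, per assay."""
        hits: Dict[str, set] = {"chip": set(), "clip": set()}
        for assay, strands in (("chip", (".",)), ("clip", (iv.strand, "."))):
            for s in strands:
                tree = self._trees.get((assay, iv.chrom, s))
                if tree is not None:
                    for node in tree.overlap(iv.start, iv.end):
                        hits[assay].add(node.data)
        return hits


def encode_binding_features(
    regions: RegionSet, index: PeakIndex
) -> Dict[Tuple[str, str, str], int]:
    """Binary flag per (assay, factor, region): 1 iff any peak overlaps any
    interval of that region by >= 1 bp. A peak spanning two regions sets both."""
    flags: Dict[Tuple[str, str, str], int] = {}
    for region_name, ivs in regions.by_name().items():
        for iv in ivs:
            for assay, factors in index.query(iv).items():
                for f in factors:
                    flags[(assay, f, region_name)] = 1
    return flags


def _region_flags_cached(
    tx: TranscriptModel,
    index: PeakIndex,
    cache: Dict[str, Dict[Tuple[str, str, str], int]],
) -> Dict[Tuple[str, str, str], int]:
    got = cache.get(tx.transcript_id)
    if got is None:
        got = encode_binding_features(derive_regions(tx), index)
        cache[tx.transcript_id] = got
    return got


def nearest_ncrnas(
    tx: TranscriptModel, ncrnas: Sequence[TranscriptModel], k: int = 2
) -> List[TranscriptModel]:
    """The k ncRNAs with smallest |ncRNA TSS - tx TSS| on tx's chromosome.

    Any strand and either side count; ties break toward the smaller TSS
    coordinate, then transcript id, for determinism.
    """
    cands = [n for n in ncrnas if n.chrom == tx.chrom]
    cands.sort(key=lambda n: (abs(n.tss - tx.tss), n.tss, n.transcript_id))
    return cands[:k]


def proximal_ncrna_features(
    tx: TranscriptModel,
    ncrnas: Sequence[TranscriptModel],
    index: PeakIndex,
    k: int = 2,
    _cache: Optional[Dict[str, Dict[Tuple[str, str, str], int]]] = None,
) -> Dict[Tuple[str, str, str, int], int]:
    """Region-resolved binding flags of the k most TSS-proximal ncRNAs,
    ranked 1..k by distance; Pol II factors excluded."""
    cache = _cache if _cache is not None else {}
    flags: Dict[Tuple[str, str, str, int], int] = {}
    for rank, nc in enumerate(nearest_ncrnas(tx, ncrnas, k), start=1):
        for (assay, f, region), v in _region_flags_cached(nc, index, cache).items():
            if POLII_PATTERN.match(f):
                continue
            flags[(assay, f, region, rank)] = v
    return flags


def cpg_features(
    tss_chrom: str,
    tss: int,
    islands: Mapping[str, Sequence[CpGIslandRecord]],
    distance_cap: float = 1_000_000.0,
) -> Dict[str, float]:
    """Six features of the CpG island nearest to the TSS.

    Distance is 0 when the TSS lies inside an island; if the chromosome has
    no island, distance is set to ``distance_cap`` and the island-descriptive
    features to 0. Equidistant islands resolve to the smaller coordinate.
    """
    recs = islands.get(tss_chrom, ())
    best: Optional[CpGIslandRecord] = None
    best_dist = np.inf
    for rec in recs:
        iv = rec.interval
        if iv.start <= tss < iv.end:
            d = 0.0
        elif tss < iv.start:
            d = float(iv.start - tss)
        else:
            d = float(tss - (iv.end - 1))
        if d < best_dist or (
            d == best_dist and best is not None and iv.start < best.interval.start
        ):
            best_dist, best = d, rec
    if best is None:
        return {
            "cpg.island.dist": float(distance_cap),
            "cpg.island.length": 0.0,
            "cpg.island.count": 0.0,
            "cpg.island.percent.cg": 0.0,
            "cpg.island.percent.cpg": 0.0,
            "cpg.island.percent.exp.v.obs": 0.0,
        }
    return {
        "cpg.island.dist": best_dist,
        "cpg.island.length": float(best.length),
        "cpg.island.count": float(best.cpg_count),
        "cpg.island.percent.cg": best.percent_cg,
        "cpg.island.percent.cpg": best.percent_cpg,
        "cpg.island.percent.exp.v.obs": best.obs_exp_ratio,
    }


def annotation_features(
    tx: TranscriptModel,
    cluster: Optional[CTSSCluster],
    genome: GenomeSequence,
    housekeeping: Iterable[str] = (),
    chrom_order: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """Twelve transcript-level annotation/sequence features.

    ``tx.chr.loc`` is the ordinal index of the chromosome in ``chrom_order``
    (genome order by default); ``tx.strand`` encodes + as 1 and - as 0.
    TSS-cluster features are 0 when no CAGE cluster was matched.
    """
    hk = set(housekeeping)
    order = list(chrom_order) if chrom_order is not None else list(genome.chromosomes())
    seq = genome.fetch(tx.span)
    gc = (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
    n_ex = len(tx.exons)
    feats = {
        "tx.len": float(tx.length),
        "tx.strand": 1.0 if tx.strand == "+" else 0.0,
        "tx.chr.loc": float(order.index(tx.chrom) + 1),
        "tx.loc": float(tx.span.start),
        "tx.ex.num": float(n_ex),
        "tx.ex.width": tx.exonic_length / n_ex,
        "tx.ex.ratio": tx.length / n_ex,
        "tx.ex.seq": tx.exonic_length / tx.length,
        "tx.gc.seq": gc,
        "housekeeping": 1.0 if (tx.gene_id in hk or tx.gene_symbol in hk) else 0.0,
    }
    if cluster is None:
        feats["tx.tss.width"] = 0.0
        feats["tx.tss.at.cont"] = 0.0
    else:
        feats["tx.tss.width"] = float(cluster.width)
        cseq = genome.fetch(cluster.span)
        feats["tx.tss.at.cont"] = (
            (cseq.count("A") + cseq.count("T")) / len(cseq) if cseq else 0.0
        )
    return {k: feats[k] for k in ANNOTATION_FEATURES}


@dataclass
class FeatureMatrix:
    """Transcripts x features with per-column metadata.

    ``metadata`` has one row per column: name, kind (binding/annotation),
    assay, factor, region, rank (ncRNA rank or <NA>), p_obs (observed binding
    proportion for binding columns).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate column names in feature matrix")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids in feature matrix")
        if list(self.metadata["name"]) != list(self.values.columns):
            raise ValueError("metadata rows must align with matrix columns")

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    def binding_columns(self) -> List[str]:
        return list(self.metadata.loc[self.metadata["kind"] == "binding", "name"])

    def annotation_columns(self) -> List[str]:
        return list(self.metadata.loc[self.metadata["kind"] == "annotation", "name"])

    def factors(self) -> List[str]:
        f = self.metadata.loc[self.metadata["kind"] == "binding", "factor"]
        return sorted(f.dropna().unique())

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        names = list(names)
        meta = self.metadata.set_index("name").loc[names].reset_index()
        return FeatureMatrix(self.values[names].copy(), meta)

    def to_tsv(self, values_path, metadata_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="transcript_id")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index=False)


def minmax_scale_columns(
    df: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Min-max scale the given columns to [0, 1]; constant columns become 0.

    Columns already within [0, 1] are left untouched, which makes scaling
    idempotent and keeps binary indicators bit-exact.
    """
    out = df.copy()
    for c in columns:
        col = out[c].astype(float)
        lo, hi = col.min(), col.max()
        if lo >= 0.0 and hi <= 1.0:
            if lo == hi and lo not in (0.0, 1.0):
                out[c] = 0.0
            continue
        if lo == hi:
            out[c] = 0.0
        else:
            out[c] = (col - lo) / (hi - lo)
    return out


def assemble_matrix(
    txs: Sequence[TranscriptModel],
    peaks: Sequence[Peak],
    ncrnas: Sequence[TranscriptModel],
    islands: Mapping[str, Sequence[CpGIslandRecord]],
    clusters: Mapping[str, CTSSCluster],
    genome: GenomeSequence,
    housekeeping: Iterable[str] = (),
    k_ncrna: int = 2,
    scale: bool = True,
    chrom_order: Optional[Sequence[str]] = None,
    cpg_distance_cap: float = 1_000_000.0,
) -> Tuple[FeatureMatrix, pd.DataFrame]:
    """Build the full feature matrix and the Pol II side table.

    Returns ``(matrix, polii_table)`` where the matrix holds binding flags
    for all non-Pol II factors (own regions + two proximal ncRNAs) plus the
    scaled annotation block, and ``polii_table`` holds the excluded POLR2*
    binding columns for the Pol II-only reference model.
    """
    index = PeakIndex(peaks)
    pairs = index.all_factors()
    regular = [(a, f) for a, f in pairs if not POLII_PATTERN.match(f)]
    polii = [(a, f) for a, f in pairs if POLII_PATTERN.match(f)]

    columns: List[Tuple[str, str, str, str, Optional[int]]] = []
    for a, f in regular:
        for r in REGION_NAMES:
            columns.append(("binding", a, f, r, None))
    for a, f in regular:
        for rank in range(1, k_ncrna + 1):
            for r in REGION_NAMES:
                columns.append(("binding", a, f, r, rank))
    col_names = [make_column_name(a, f, r, rk) for _, a, f, r, rk in columns]
    polii_names = [make_column_name(a, f, r) for a, f in polii for r in REGION_NAMES]

    ids = [t.transcript_id for t in txs]
    bind = np.zeros((len(txs), len(col_names)), dtype=np.int8)
    polii_arr = np.zeros((len(txs), len(polii_names)), dtype=np.int8)
    col_pos = {name: i for i, name in enumerate(col_names)}
    polii_pos = {name: i for i, name in enumerate(polii_names)}

    nc_cache: Dict[str, Dict[Tuple[str, str, str], int]] = {}
    ann_rows: List[Dict[str, float]] = []
    for i, tx in enumerate(txs):
        own = encode_binding_features(derive_regions(tx), index)
        for (a, f, r), v in own.items():
            name = make_column_name(a, f, r)
            if POLII_PATTERN.match(f):
                polii_arr[i, polii_pos[name]] = v
            else:
                bind[i, col_pos[name]] = v
        prox = proximal_ncrna_features(tx, ncrnas, index, k=k_ncrna, _cache=nc_cache)
        for (a, f, r, rank), v in prox.items():
            bind[i, col_pos[make_column_name(a, f, r, rank)]] = v
        row = annotation_features(
            tx, clusters.get(tx.transcript_id), genome, housekeeping, chrom_order
        )
        row.update(
            cpg_features(tx.chrom, tx.tss, islands, distance_cap=cpg_distance_cap)
        )
        ann_rows.append(row)

    ann_df = pd.DataFrame(ann_rows, index=ids)
    bind_df = pd.DataFrame(bind, index=ids, columns=col_names, dtype=float)
    values = pd.concat([bind_df, ann_df], axis=1)

    ann_names = list(ann_df.columns)
    if scale:
        numeric = [c for c in ann_names if c not in BINARY_ANNOTATION]
        values = minmax_scale_columns(values, numeric)

    meta_rows = []
    for (kind, a, f, r, rk), name in zip(columns, col_names):
        meta_rows.append(
            {
                "name": name,
                "kind": kind,
                "assay": a,
                "factor": f,
                "region": r,
                "rank": rk,
                "p_obs": float(values[name].mean()),
            }
        )
    for name in ann_names:
        meta_rows.append(
            {
                "name": name,
                "kind": "annotation",
                "assay": None,
                "factor": None,
                "region": None,
                "rank": None,
                "p_obs": np.nan,
            }
        )
    metadata = pd.DataFrame(meta_rows)
    matrix = FeatureMatrix(values, metadata)
    polii_table = pd.DataFrame(polii_arr, index=ids, columns=polii_names, dtype=float)
    return matrix, polii_table
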
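"""Readers and writers for the genomics formats the pipeline touches.

Everything is converted to the package-internal 0-based half-open convention
on read (GTF and wiggle files are 1-based on disk) and converted back on
write, so round-trips are exact. Only plain-text dialects are supported:
GENCODE-style GTF, BED3/6, fixedStep/variableStep wiggle and FASTA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotation import TranscriptModel
from .intervals import GenomicInterval, GenomeSequence, SignalTrack


@dataclass(frozen=True)
class Peak:
    """A peak-called binding site tagged with its factor and assay."""

    interval: GenomicInterval
    factor: str
    assay: str  # "chip" or "clip"


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf_transcripts(
    path: str | Path,
    attributes_required: Sequence[str] = ("gene_id", "transcript_id"),
) -> List[TranscriptModel]:
    """Read transcript models from a GENCODE-dialect GTF.

    Expects ``transcript`` and ``exon`` records (optionally ``CDS``);
    coordinates are converted from 1-based inclusive to 0-based half-open.
    Exons are ordered 5'->3' in transcription direction on the resulting
    models. A ``tag "RefSeq_supported"`` attribute marks RefSeq support.
    """
    spans: Dict[str, dict] = {}
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    order: List[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("transcript", "exon", "CDS"):
                continue
            attr = _parse_attributes(attrs)
            for req in attributes_required:
                if req not in attr:
                    raise ValueError(
                        f"{path}:{lineno}: missing required attribute {req!r}"
                    )
            tid = attr["transcript_id"]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if feature == "transcript":
                if tid not in spans:
                    order.append(tid)
                spans[tid] = {
                    "span": iv,
                    "gene_id": attr.get("gene_id", ""),
                    "gene_symbol": attr.get("gene_name", ""),
                    "biotype": attr.get("gene_type", attr.get("transcript_type", "")),
                    "refseq": attr.get("tag", "") == "RefSeq_supported",
                }
            elif feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:  # CDS
                cds.setdefault(tid, []).append((iv.start, iv.end))

    out: List[TranscriptModel] = []
    for tid in order:
        info = spans[tid]
        span: GenomicInterval = info["span"]
        ex = exons.get(tid, [span])
        for e in ex:
            if e.start < span.start or e.end > span.end:
                raise ValueError(f"{path}: exon {e} outside transcript {tid} span")
        cds_span = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
            cds_span = GenomicInterval(span.chrom, cs, ce, span.strand)
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                gene_symbol=info["gene_symbol"],
                chrom=span.chrom,
                strand=span.strand,
                span=span,
                exons=ex,
                biotype=info["biotype"],
                refseq_supported=info["refseq"],
                cds_span=cds_span,
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            tag = '; tag "RefSeq_supported"' if tx.refseq_supported else ""
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_type "{tx.biotype}"; gene_name "{tx.gene_symbol}"{tag};'
            )
            fh.write(
                f"{tx.chrom}\tpausescape\ttranscript\t{tx.span.start + 1}\t"
                f"{tx.span.end}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for e in sorted(tx.exons, key=lambda e: e.start):
                fh.write(
                    f"{tx.chrom}\tpausescape\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds_span is not None:
                c = tx.cds_span
                fh.write(
                    f"{tx.chrom}\tpausescape\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def read_bed_peaks(path: str | Path, factor: str, assay: str) -> List[Peak]:
    """Read BED3+ peaks; strand (column 6) is honoured for clip, ignored for chip."""
    if assay not in ("chip", "clip"):
        raise ValueError("assay must be 'chip' or 'clip'")
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            strand = "."
            if assay == "clip" and len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            peaks.append(
                Peak(GenomicInterval(fields[0], start, end, strand), factor, assay)
            )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.factor}\t0\t{iv.strand}\n")


_WIG_HEADERS = ("fixedStep", "variableStep", "track", "browser", "#")


def _wig_header_params(line: str) -> Dict[str, str]:
    return dict(kv.split("=", 1) for kv in line.split()[1:])


def read_wig_signal(
    paths: Mapping[str, str | Path] | Sequence[str | Path] | str | Path,
    strand_convention: str = "two_file",
    genome_build: str = "synthetic",
) -> SignalTrack:
    """Read strand-specific coverage from wiggle files.

    Two strand dialects are supported, matching the deposits seen for
    nascent-transcription data:

    - ``two_file``: ``paths`` is a mapping ``{"+": plus_path, "-": minus_path}``;
      every value in a file belongs to that file's strand (absolute values
      are stored, so minus-strand files may carry negated values).
    - ``signed``: ``paths`` is one path or a sequence of paths; negative
      values are minus-strand coverage stored as magnitude.

    Wiggle positions are 1-based and shifted to the internal 0-based
    convention. Conflicting duplicate declarations for a position raise.
    """
    track = SignalTrack(genome_build=genome_build)
    if strand_convention == "two_file":
        if not isinstance(paths, Mapping):
            raise ValueError("two_file convention needs a {strand: path} mapping")
        for strand, p in paths.items():
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand key {strand!r}")
            _read_one_wig(p, track, fixed_strand=strand)
    elif strand_convention == "signed":
        seq = [paths] if isinstance(paths, (str, Path)) else list(paths)
        for p in seq:
            _read_one_wig(p, track, fixed_strand=None)
    else:
        raise ValueError(f"unknown strand convention {strand_convention!r}")
    return track


def _flush_block(
    track: SignalTrack,
    chrom: str,
    positions: np.ndarray,
    values: np.ndarray,
    fixed_strand: Optional[str],
) -> None:
    if len(positions) == 0:
        return
    if fixed_strand is not None:
        track.add(chrom, fixed_strand, positions, np.abs(values))
    else:
        neg = values < 0
        if np.any(~neg):
            track.add(chrom, "+", positions[~neg], values[~neg])
        if np.any(neg):
            track.add(chrom, "-", positions[neg], -values[neg])


def _read_one_wig(
    path: str | Path, track: SignalTrack, fixed_strand: Optional[str]
) -> None:
    lines = Path(path).read_text().splitlines()
    header_idx = [i for i, l in enumerate(lines) if l.startswith(_WIG_HEADERS)]
    header_idx.append(len(lines))
    if not header_idx or header_idx[0] != 0:
        raise ValueError(f"{path}: wig file must start with a declaration line")

    # accumulate per chromosome, flush once per file for speed
    acc: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for h, nxt in zip(header_idx[:-1], header_idx[1:]):
        header = lines[h]
        body = lines[h + 1 : nxt]
        if header.startswith(("track", "browser", "#")):
            continue
        params = _wig_header_params(header)
        chrom = params["chrom"]
        span = int(params.get("span", 1))
        if header.startswith("fixedStep"):
            start = int(params["start"]) - 1  # to 0-based
            step = int(params.get("step", 1))
            vals = np.asarray(body, dtype=np.float64)
            base = start + step * np.arange(len(vals), dtype=np.int64)
            if span == 1:
                pos, v = base, vals
            else:
                pos = (base[:, None] + np.arange(span)).ravel()
                v = np.repeat(vals, span)
        else:  # variableStep
            if body:
                arr = np.array([l.split() for l in body], dtype=np.float64)
                base = arr[:, 0].astype(np.int64) - 1
                vals = arr[:, 1]
            else:
                base = np.empty(0, dtype=np.int64)
                vals = np.empty(0)
            if span == 1:
                pos, v = base, vals
            else:
                pos = (base[:, None] + np.arange(span)).ravel()
                v = np.repeat(vals, span)
        acc.setdefault(chrom, []).append((pos, v))

    for chrom, chunks in acc.items():
        pos = np.concatenate([c[0] for c in chunks])
        v = np.concatenate([c[1] for c in chunks])
        _flush_block(track, chrom, pos, v, fixed_strand)


def write_wig_pair(
    track: SignalTrack, plus_path: str | Path, minus_path: str | Path
) -> None:
    """Write a track as a fixedStep plus/minus file pair (1-based positions)."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom, s in sorted(track.keys()):
                if s != strand:
                    continue
                pos, vals = track.arrays(chrom, strand)
                if len(pos) == 0:
                    continue
                # contiguous runs become single fixedStep blocks
                breaks = np.nonzero(np.diff(pos) != 1)[0] + 1
                for seg_pos, seg_val in zip(
                    np.split(pos, breaks), np.split(vals, breaks)
                ):
                    fh.write(f"fixedStep chrom={chrom} start={seg_pos[0] + 1} step=1\n")
                    fh.write("\n".join(f"{v:g}" for v in seg_val))
                    fh.write("\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA into an in-memory genome; duplicate names raise."""
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"{path}: duplicate chromosome {name!r}")
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
            elif line:
                raise ValueError(f"{path}: sequence before first FASTA header")
    return GenomeSequence({n: "".join(parts) for n, parts in seqs.items()})


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
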
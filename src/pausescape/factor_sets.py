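"""Functional factor sets, 7SK-binder identification, matrix subsetting.

Factor sets group the assayed DNA/RNA-binding proteins by the gene-expression
step they act in (chromatin organization, initiation, elongation,
termination, splicing, 3'-processing/export), using a flat factor -> GO-term
annotation table as input. The elongation set is additionally extended with
established pause-regulatory factors (DSIF, NELF, SEC, P-TEFb, 7SK-snRNP
members) from a packaged literature list, and Pol II subunits are removed
from it since their occupancy trivially tracks the pausing signal.

A separate, data-driven set collects every factor with at least one CLIP
peak on a 7SK transcript — the non-coding RNA whose snRNP sequesters P-TEFb —
including expressed pseudogene copies of 7SK.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .features import POLII_PATTERN, FeatureMatrix
from .genomic_io import Peak

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class FactorSet:
    name: str
    members: Set[str]
    provenance: Dict[str, str] = field(default_factory=dict)

    def __or__(self, other: "FactorSet") -> "FactorSet":
        prov = dict(other.provenance)
        prov.update(self.provenance)
        return FactorSet(
            f"{self.name}+{other.name}", set(self.members) | set(other.members), prov
        )


def _load_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("pausescape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_default_term_map() -> Dict[str, List[str]]:
    df = _load_packaged_tsv("go_term_map.tsv")
    return {s: list(g["go_id"]) for s, g in df.groupby("set_name", sort=False)}


def load_elongation_literature() -> List[str]:
    return list(_load_packaged_tsv("elongation_literature.tsv")["factor"])


def load_elongation_assayed() -> List[str]:
    """The elongation factors actually assayed in the reference dataset
    (before Pol II subunit removal)."""
    return list(_load_packaged_tsv("elongation_assayed_k562.tsv")["factor"])


def load_novel_7sk_binders() -> List[str]:
    """RNA-binding proteins with CLIP evidence on 7SK not previously linked
    to it (AQR plus fifteen further factors)."""
    return list(_load_packaged_tsv("novel_7sk_binders.tsv")["factor"])


def build_functional_sets(
    go_annotation: pd.DataFrame,
    term_map: Optional[Mapping[str, Sequence[str]]] = None,
    literature_extension: Optional[Sequence[str]] = None,
    assayed_factors: Optional[Iterable[str]] = None,
) -> List[FactorSet]:
    """Build the GO-derived functional factor sets.

    ``go_annotation`` is a flat table with columns (factor, go_id); a factor
    belongs to a set iff it is annotated to any of the set's mapped terms.
    The Elongation set is unioned with the literature extension (restricted
    to assayed factors when a universe is given) and stripped of Pol II
    subunits.
    """
    if term_map is None:
        term_map = load_default_term_map()
    if literature_extension is None:
        literature_extension = load_elongation_literature()
    if not {"factor", "go_id"}.issubset(go_annotation.columns):
        raise ValueError("go_annotation needs columns (factor, go_id)")
    for go_id in go_annotation["go_id"]:
        if not _GO_ID_RE.match(str(go_id)):
            raise ValueError(f"malformed GO id {go_id!r}")
    for ids in term_map.values():
        for go_id in ids:
            if not _GO_ID_RE.match(str(go_id)):
                raise ValueError(f"malformed GO id {go_id!r} in term map")

    assayed = set(assayed_factors) if assayed_factors is not None else None
    by_term: Dict[str, Set[str]] = {}
    for term, grp in go_annotation.groupby("go_id"):
        by_term[term] = set(grp["factor"])

    out: List[FactorSet] = []
    for set_name, ids in term_map.items():
        members: Set[str] = set()
        prov: Dict[str, str] = {}
        for go_id in ids:
            for f in by_term.get(go_id, ()):
                members.add(f)
                prov.setdefault(f, go_id)
        if set_name == "Elongation":
            ext = set(literature_extension)
            if assayed is not None:
                ext &= assayed
            for f in ext - members:
                prov[f] = "literature"
            members |= ext
            removed = {f for f in members if POLII_PATTERN.match(f)}
            members -= removed
            for f in removed:
                prov.pop(f, None)
        out.append(FactorSet(set_name, members, prov))
    return out


def _is_pseudo(tx: TranscriptModel) -> bool:
    return "pseudo" in tx.biotype.lower() or bool(
        re.search(r"P\d*$", tx.gene_symbol)
    )


def identify_7sk_binders(
    ncrna_txs: Sequence[TranscriptModel],
    clip_peaks: Sequence[Peak],
    ncrna_expression: Mapping[str, float],
    gene_name_pattern: str = "RN7SK*",
) -> FactorSet:
    """Factors with >= 1 same-strand CLIP peak on any 7SK transcript.

    The 7SK transcript set comprises all non-pseudo transcripts whose gene
    symbol matches ``gene_name_pattern`` plus pseudo copies expressed at
    least at the median expression of all expressed non-coding transcripts
    (rationale: binders of highly expressed pseudo copies compete for the
    same protein pool).
    """
    matches = [
        t for t in ncrna_txs if fnmatch.fnmatch(t.gene_symbol, gene_name_pattern)
    ]
    expressed_vals = [
        v for t in ncrna_txs if (v := ncrna_expression.get(t.transcript_id)) is not None
    ]
    median = float(np.median(expressed_vals)) if expressed_vals else np.inf

    targets: List[TranscriptModel] = []
    for t in matches:
        if not _is_pseudo(t):
            targets.append(t)
        else:
            expr = ncrna_expression.get(t.transcript_id)
            if expr is not None and expr >= median:
                targets.append(t)
    if not targets:
        import warnings

        warnings.warn("no 7SK transcript found; returning empty binder set")
        return FactorSet("7SK.Binding", set())

    members: Set[str] = set()
    prov: Dict[str, str] = {}
    for p in clip_peaks:
        if p.assay != "clip":
            continue
        for t in targets:
            if p.interval.overlaps(t.span, stranded=True):
                members.add(p.factor)
                prov.setdefault(p.factor, t.transcript_id)
                break
    return FactorSet("7SK.Binding", members, prov)


def stratify_sequence_specific(
    fs: FactorSet, catalog: Iterable[str]
) -> Tuple[FactorSet, FactorSet]:
    """Partition a factor set into sequence-specific and non-specific binders
    according to a motif catalog given as a flat factor list."""
    cat = set(catalog)
    specific = fs.members & cat
    return (
        FactorSet(f"{fs.name}.seq.specific", specific),
        FactorSet(f"{fs.name}.non.seq.specific", fs.members - specific),
    )


def subset_matrix(
    m: FeatureMatrix, fs: FactorSet, keep_annotation: bool = True
) -> FeatureMatrix:
    """Restrict a feature matrix to one factor set's binding columns.

    The annotation block always accompanies binding features unless
    explicitly dropped. A subset with zero binding columns raises.
    """
    meta = m.metadata
    keep = meta[(meta["kind"] == "binding") & meta["factor"].isin(fs.members)]
    names = list(keep["name"])
    if not names:
        raise ValueError(f"factor set {fs.name!r} matches no binding columns")
    if keep_annotation:
        names = names + m.annotation_columns()
    return m.select_columns(names)


def random_baseline_matrix(m: FeatureMatrix, seed: int) -> FeatureMatrix:
    """A randomized null matrix for baseline models.

    Draws a factor count uniformly in [1, F], samples that many factors
    without replacement, and regenerates each retained binding column as
    independent Bernoulli draws with that column's observed binding
    proportion ``p_obs``. The annotation block is kept intact.
    """
    rng = np.random.default_rng(seed)
    factors = m.factors()
    n_pick = int(rng.integers(1, len(factors) + 1))
    picked = set(rng.choice(factors, size=n_pick, replace=False))

    meta = m.metadata
    keep = meta[(meta["kind"] == "binding") & meta["factor"].isin(picked)]
    names = list(keep["name"])
    sub = m.select_columns(names + m.annotation_columns())
    values = sub.values.copy()
    p_obs = keep.set_index("name")["p_obs"]
    n = len(values)
    for name in names:
        values[name] = (rng.random(n) < float(p_obs[name])).astype(float)
    return FeatureMatrix(values, sub.metadata.copy())
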
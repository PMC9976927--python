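"""End-to-end orchestration: filters -> PI -> features -> model -> scores.

`run_pipeline` executes the full single-cell-line analysis on a
:class:`PipelineInputs` (constructed either from a synthetic bundle in
memory or from files on disk) and returns a :class:`RunReport` with every
intermediate of interest. `compare_cell_lines` runs the two-cell-line
validation: models trained on the feature columns common to both lines,
applied to the full cross-line data, to exclusively expressed transcripts,
and to differential-pausing groups.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .annotation import (
    CTSSCluster,
    ExpressionRecord,
    TranscriptModel,
    cluster_ctss,
    filter_by_dominant_ctss,
    filter_expressed,
    filter_high_confidence,
)
from .factor_sets import (
    FactorSet,
    build_functional_sets,
    identify_7sk_binders,
)
from .features import CpGIslandRecord, FeatureMatrix, assemble_matrix
from .genomic_io import (
    Peak,
    read_bed_peaks,
    read_fasta,
    read_gtf_transcripts,
    read_wig_signal,
)
from .intervals import GenomicInterval, GenomeSequence, SignalTrack
from .interpretation import (
    ContributionTable,
    aggregate_by_binding_mode,
    aggregate_by_factor,
    aggregate_by_group,
    compute_attributions,
    factor_mode_scores,
    fisher_enrichment,
    select_minimal_factor_set,
    splicing_intron_enrichment_table,
)
from .modeling import (
    FitResult,
    ModelSpec,
    differential_pausing_eval,
    evaluate,
    fit_and_evaluate,
    polii_only_model,
    synchronize_features,
    train_model,
)
from .pausing import (
    ExclusionReport,
    PIConfig,
    apply_pi_filters,
    compute_all_pi,
    optimize_tss_window,
)

NONCODING_BIOTYPES = {"miscRNA", "miRNA", "snoRNA", "snRNA", "lincRNA"}


@dataclass
class PipelineSettings:
    pi: PIConfig = field(
        default_factory=lambda: PIConfig(halfwidth_grid=(1, 2, 5, 10, 50))
    )
    optimize_window: bool = True
    model: ModelSpec = field(default_factory=ModelSpec)
    ctss_tpm_threshold: float = 0.1
    ctss_max_gap: int = 20
    ctss_tolerance: int = 0
    target_share: float = 0.5
    share_base: str = "factors"
    seed: int = 0


@dataclass
class PipelineInputs:
    genome: GenomeSequence
    transcripts: List[TranscriptModel]  # protein-coding
    ncrnas: List[TranscriptModel]
    peaks: List[Peak]
    track: SignalTrack
    expression: Dict[str, ExpressionRecord]
    ncrna_expression: Dict[str, float]
    ctss: pd.DataFrame
    islands: Dict[str, List[CpGIslandRecord]]
    housekeeping: Set[str]
    go_annotation: Optional[pd.DataFrame] = None
    sequence_specific: Optional[List[str]] = None
    chrom_order: Optional[List[str]] = None


def inputs_from_bundle(bundle) -> PipelineInputs:
    ann = bundle.annotation
    return PipelineInputs(
        genome=ann.genome,
        transcripts=list(ann.transcripts),
        ncrnas=list(ann.ncrnas),
        peaks=list(bundle.peaks),
        track=bundle.track,
        expression=dict(bundle.expression),
        ncrna_expression=dict(bundle.ncrna_expression),
        ctss=bundle.ctss,
        islands=ann.islands,
        housekeeping=set(ann.housekeeping),
        go_annotation=bundle.go_annotation,
        sequence_specific=list(bundle.sequence_specific),
        chrom_order=list(ann.chrom_order),
    )


def load_inputs(data_dir: str | Path) -> PipelineInputs:
    """Load a bundle directory (as written by `synthetic.write_bundle`)."""
    d = Path(data_dir)
    for required in ("genome.fa", "annotation.gtf", "expression.tsv"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing input file: {d / required}")
    genome = read_fasta(d / "genome.fa")
    all_tx = read_gtf_transcripts(d / "annotation.gtf")
    coding = [t for t in all_tx if t.biotype == "protein_coding"]
    ncrnas = [t for t in all_tx if t.biotype in NONCODING_BIOTYPES or "pseudo" in t.biotype]
    track = read_wig_signal(
        {"+": d / "groseq.plus.wig", "-": d / "groseq.minus.wig"},
        strand_convention="two_file",
    )
    expr_df = pd.read_csv(d / "expression.tsv", sep="\t")
    expression = {
        r.transcript_id: ExpressionRecord(r.transcript_id, r.fpkm_rep1, r.fpkm_rep2)
        for r in expr_df.itertuples()
    }
    nc_df = pd.read_csv(d / "ncrna_expression.tsv", sep="\t")
    ncrna_expression = dict(zip(nc_df["transcript_id"], nc_df["fpkm"]))
    ctss = pd.read_csv(d / "ctss.tsv", sep="\t")
    cpg = pd.read_csv(d / "cpg_islands.tsv", sep="\t")
    islands: Dict[str, List[CpGIslandRecord]] = {}
    for r in cpg.itertuples():
        islands.setdefault(r.chrom, []).append(
            CpGIslandRecord(
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                cpg_count=int(r.cpg_count),
                percent_cg=float(r.percent_cg),
                percent_cpg=float(r.percent_cpg),
                obs_exp_ratio=float(r.obs_exp_ratio),
            )
        )
    housekeeping = set(
        (d / "housekeeping.txt").read_text().split()
    )
    peaks: List[Peak] = []
    for bed in sorted((d / "peaks").glob("*.bed")):
        assay, factor = bed.stem.split(".", 1)
        peaks.extend(read_bed_peaks(bed, factor=factor, assay=assay))
    go = None
    if (d / "go_annotation.tsv").exists():
        go = pd.read_csv(d / "go_annotation.tsv", sep="\t")
    seq_spec = None
    if (d / "sequence_specific.tsv").exists():
        seq_spec = list(
            pd.read_csv(d / "sequence_specific.tsv", sep="\t")["factor"]
        )
    return PipelineInputs(
        genome=genome,
        transcripts=coding,
        ncrnas=ncrnas,
        peaks=peaks,
        track=track,
        expression=expression,
        ncrna_expression=ncrna_expression,
        ctss=ctss,
        islands=islands,
        housekeeping=housekeeping,
        go_annotation=go,
        sequence_specific=seq_spec,
        chrom_order=list(genome.chromosomes()),
    )


@dataclass
class PreparedData:
    """Filtered transcripts with PI targets and the assembled feature matrix."""

    matrix: FeatureMatrix
    polii_table: pd.DataFrame
    y: pd.Series
    pi_table: pd.DataFrame
    exclusions: ExclusionReport
    best_halfwidth: int
    rho_profile: Dict[int, float]
    counts: Dict[str, int]
    cluster_map: Dict[str, CTSSCluster]


@dataclass
class RunReport:
    prepared: PreparedData
    fit: FitResult
    contributions: ContributionTable
    factor_scores: pd.DataFrame
    minimal_set: List[str]
    mode_scores: pd.Series
    set_scores: Optional[pd.Series]
    sevenk: Optional[FactorSet]
    enrichment: Optional[Tuple[float, float]]
    polii_fit: Optional[FitResult]
    settings: PipelineSettings
    provenance: Dict[str, object]


def prepare_data(inputs: PipelineInputs, settings: PipelineSettings) -> PreparedData:
    """Filters -> TSS window choice -> PI -> feature matrix."""
    counts: Dict[str, int] = {"input": len(inputs.transcripts)}
    hc = filter_high_confidence(inputs.transcripts)
    counts["high_confidence"] = len(hc)
    expressed, log10 = filter_expressed(hc, inputs.expression)
    counts["expressed"] = len(expressed)
    clusters = cluster_ctss(
        inputs.ctss,
        tpm_threshold=settings.ctss_tpm_threshold,
        max_gap=settings.ctss_max_gap,
    )
    kept, cluster_map = filter_by_dominant_ctss(
        expressed, clusters, tolerance=settings.ctss_tolerance
    )
    counts["dominant_ctss"] = len(kept)

    if settings.optimize_window:
        best_h, profile = optimize_tss_window(
            inputs.track,
            kept,
            log10,
            grid=settings.pi.halfwidth_grid,
            pseudocount=settings.pi.pseudocount,
        )
    else:
        best_h, profile = settings.pi.tss_halfwidth, {}
    pi_cfg = PIConfig(
        tss_halfwidth=best_h,
        pseudocount=settings.pi.pseudocount,
        halfwidth_grid=tuple(settings.pi.halfwidth_grid),
    )

    final, exclusions = apply_pi_filters(kept, inputs.genome, inputs.track, pi_cfg)
    counts["after_pi_filters"] = len(final)
    records = compute_all_pi(inputs.track, final, pi_cfg)
    pi_table = pd.DataFrame(
        [
            (r.transcript_id, r.c_tss, r.c_body, r.w_tss, r.w_body, r.pi)
            for r in records.values()
        ],
        columns=["transcript_id", "c_tss", "c_body", "w_tss", "w_body", "pi"],
    ).set_index("transcript_id")
    y = pi_table["pi"]

    expressed_nc = [
        n
        for n in inputs.ncrnas
        if inputs.ncrna_expression.get(n.transcript_id, 0.0) > 0
    ]
    matrix, polii_table = assemble_matrix(
        final,
        inputs.peaks,
        expressed_nc,
        inputs.islands,
        cluster_map,
        inputs.genome,
        housekeeping=inputs.housekeeping,
        chrom_order=inputs.chrom_order,
    )
    polii_table = polii_table.loc[matrix.values.index]
    return PreparedData(
        matrix=matrix,
        polii_table=polii_table,
        y=y.loc[matrix.values.index],
        pi_table=pi_table,
        exclusions=exclusions,
        best_halfwidth=best_h,
        rho_profile=profile,
        counts=counts,
        cluster_map=cluster_map,
    )


def run_pipeline(
    inputs: PipelineInputs,
    settings: Optional[PipelineSettings] = None,
    outdir: Optional[str | Path] = None,
) -> RunReport:
    """Full single-cell-line run; optionally persists intermediates."""
    settings = settings or PipelineSettings()
    prep = prepare_data(inputs, settings)
    spec = settings.model
    fit = fit_and_evaluate(prep.matrix.values, prep.y, spec)

    holdout_X = prep.matrix.values.loc[fit.predictions.index]
    ct = compute_attributions(fit.model, holdout_X)
    factor_scores = aggregate_by_factor(
        ct, prep.matrix.metadata, share_base=settings.share_base
    )
    minimal = select_minimal_factor_set(
        factor_scores["share"], target_share=settings.target_share
    )
    modes = aggregate_by_binding_mode(ct, prep.matrix.metadata)

    sevenk = None
    set_scores = None
    enrichment = None
    if inputs.go_annotation is not None:
        assayed = prep.matrix.factors()
        sets = build_functional_sets(inputs.go_annotation, assayed_factors=assayed)
        sevenk = identify_7sk_binders(
            inputs.ncrnas,
            [p for p in inputs.peaks if p.assay == "clip"],
            inputs.ncrna_expression,
        )
        elong = next((s for s in sets if s.name == "Elongation"), None)
        groups = {s.name: s.members for s in sets}
        groups["7SK.Binding"] = sevenk.members
        if elong is not None:
            groups["Elongation+7SK"] = set(elong.members) | set(sevenk.members)
        set_scores = aggregate_by_group(factor_scores["S"], groups)
        splicing = next((s for s in sets if s.name == "Splicing"), None)
        if splicing is not None:
            fm = factor_mode_scores(ct, prep.matrix.metadata)
            if "RNA_intron" in fm.columns:
                table = splicing_intron_enrichment_table(
                    fm["RNA_intron"], splicing.members
                )
                enrichment = fisher_enrichment(table, alternative="greater")

    polii_fit = None
    if prep.polii_table.shape[1] > 0:
        polii_fit = polii_only_model(prep.polii_table, prep.y, spec)

    provenance = {
        "seed": settings.seed,
        "model_seed": spec.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "grid": list(settings.pi.halfwidth_grid),
                    "pseudocount": settings.pi.pseudocount,
                    "learner": spec.learner,
                    "seed": settings.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    report = RunReport(
        prepared=prep,
        fit=fit,
        contributions=ct,
        factor_scores=factor_scores,
        minimal_set=minimal,
        mode_scores=modes,
        set_scores=set_scores,
        sevenk=sevenk,
        enrichment=enrichment,
        polii_fit=polii_fit,
        settings=settings,
        provenance=provenance,
    )
    if outdir is not None:
        persist_report(report, outdir)
    return report


def persist_report(report: RunReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prep = report.prepared
    prep.pi_table.to_csv(out / "pausing_index.tsv", sep="\t")
    prep.matrix.to_tsv(out / "feature_matrix.tsv", out / "feature_metadata.tsv")
    report.factor_scores.to_csv(out / "factor_scores.tsv", sep="\t")
    pd.Series(report.minimal_set, name="factor").to_csv(
        out / "minimal_factor_set.tsv", sep="\t", index=False
    )
    report.mode_scores.to_csv(out / "binding_mode_scores.tsv", sep="\t", header=["S"])
    summary = {
        "provenance": report.provenance,
        "counts": prep.counts,
        "exclusions": prep.exclusions.counts(),
        "best_halfwidth": prep.best_halfwidth,
        "rho_profile": {str(k): v for k, v in prep.rho_profile.items()},
        "holdout_r2": report.fit.holdout_r2,
        "holdout_rho": report.fit.holdout_rho,
        "polii_holdout_r2": report.polii_fit.holdout_r2 if report.polii_fit else None,
        "minimal_set": report.minimal_set,
        "enrichment": list(report.enrichment) if report.enrichment else None,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))


@dataclass
class CrossCellReport:
    r2_B_from_A: float
    rho_B_from_A: float
    r2_A_from_B: float
    rho_A_from_B: float
    r2_B_exclusive: Optional[float]
    r2_A_exclusive: Optional[float]
    differential_rho: Dict[str, float]
    n_common_features: int
    n_shared_transcripts: int


def compare_cell_lines(
    inputsA: PipelineInputs,
    inputsB: PipelineInputs,
    settings: Optional[PipelineSettings] = None,
) -> CrossCellReport:
    """Synchronized cross-cell-line training and evaluation.

    Models are trained per line on the feature columns common to both lines
    and applied to the other line's full data, to transcripts exclusively
    expressed there, and to differential-pausing groups (observed vs
    predicted PI differences for transcripts with >= 2-fold change).
    """
    settings = settings or PipelineSettings()
    prepA = prepare_data(inputsA, settings)
    prepB = prepare_data(inputsB, settings)
    mA, mB = synchronize_features(prepA.matrix, prepB.matrix)

    modelA = train_model(mA.values, prepA.y, settings.model)
    modelB = train_model(mB.values, prepB.y, settings.model)

    r2_B, rho_B = evaluate(modelA, mB.values, prepB.y)
    r2_A, rho_A = evaluate(modelB, mA.values, prepA.y)

    idsA, idsB = set(mA.values.index), set(mB.values.index)
    only_B = sorted(idsB - idsA)
    only_A = sorted(idsA - idsB)
    r2_B_ex = (
        evaluate(modelA, mB.values.loc[only_B], prepB.y.loc[only_B])[0]
        if len(only_B) >= 3
        else None
    )
    r2_A_ex = (
        evaluate(modelB, mA.values.loc[only_A], prepA.y.loc[only_A])[0]
        if len(only_A) >= 3
        else None
    )

    shared = sorted(idsA & idsB)
    predA_by_B = pd.Series(
        modelB.predict(mA.values.loc[shared]), index=shared
    )
    predB_by_A = pd.Series(
        modelA.predict(mB.values.loc[shared]), index=shared
    )
    diff = differential_pausing_eval(
        prepA.y.loc[shared], prepB.y.loc[shared], predA_by_B, predB_by_A
    )
    return CrossCellReport(
        r2_B_from_A=r2_B,
        rho_B_from_A=rho_B,
        r2_A_from_B=r2_A,
        rho_A_from_B=rho_A,
        r2_B_exclusive=r2_B_ex,
        r2_A_exclusive=r2_A_ex,
        differential_rho=diff,
        n_common_features=mA.values.shape[1],
        n_shared_transcripts=len(shared),
    )
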
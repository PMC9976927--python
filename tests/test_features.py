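"""Binding encodings, CpG/annotation features, matrix assembly and scaling."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pandas as pd
import pytest

from pausescape.annotation import REGION_NAMES, CTSSCluster, derive_regions
from pausescape.features import (
    CpGIslandRecord,
    FeatureMatrix,
    PeakIndex,
    annotation_features,
    assemble_matrix,
    cpg_features,
    encode_binding_features,
    make_column_name,
    minmax_scale_columns,
    nearest_ncrnas,
    parse_column_name,
    proximal_ncrna_features,
)
from pausescape.genomic_io import Peak
from pausescape.intervals import GenomicInterval, GenomeSequence

from .test_annotation import make_tx


def peak(chrom, s, e, factor="F1", assay="chip", strand="."):
    return Peak(GenomicInterval(chrom, s, e, strand), factor, assay)


class TestColumnNames:
    @pytest.mark.parametrize(
        "assay,factor,region,rank",
        [
            ("chip", "RBFOX2", "5prime", None),
            ("clip", "RBFOX2", "intron", 2),
            ("chip", "POLR2A", "codingexon", None),
            ("clip", "U2AF2", "3prime", 1),
        ],
    )
    def test_bijection(self, assay, factor, region, rank):
        name = make_column_name(assay, factor, region, rank)
        assert parse_column_name(name) == (assay, factor, region, rank)

    def test_misspelled_alias_accepted(self):
        assert parse_column_name("clip.RBFOX2.5prime.Proxmial.ncRNA.2") == (
            "clip",
            "RBFOX2",
            "5prime",
            2,
        )

    def test_non_binding_name_rejected(self):
        with pytest.raises(ValueError):
            parse_column_name("tx.len")


class TestBindingEncoding:
    def test_no_peaks_all_zero(self):
        tx = make_tx(exons=((0, 100), (200, 300)), cds=(220, 280))
        flags = encode_binding_features(derive_regions(tx), PeakIndex([]))
        assert flags == {}

    def test_peak_in_intron_only_sets_intron(self):
        tx = make_tx(exons=((0, 100), (400, 500)), cds=(420, 480))
        idx = PeakIndex([peak("chr1", 120, 150)])
        flags = encode_binding_features(derive_regions(tx), idx)
        assert flags == {("chip", "F1", "intron"): 1}

    def test_peak_spanning_boundary_sets_both(self):
        tx = make_tx(exons=((0, 100), (400, 500)), cds=(420, 480))
        idx = PeakIndex([peak("chr1", 90, 120)])
        flags = encode_binding_features(derive_regions(tx), idx)
        assert flags == {("chip", "F1", "5prime"): 1, ("chip", "F1", "intron"): 1}

    def test_clip_requires_same_strand(self):
        tx = make_tx(strand="+", exons=((0, 100),))
        same = PeakIndex([peak("chr1", 10, 20, assay="clip", strand="+")])
        oppo = PeakIndex([peak("chr1", 10, 20, assay="clip", strand="-")])
        nost = PeakIndex([peak("chr1", 10, 20, assay="clip", strand=".")])
        rs = derive_regions(tx)
        assert encode_binding_features(rs, same)
        assert not encode_binding_features(rs, oppo)
        assert encode_binding_features(rs, nost)  # undeclared strand matches

    def test_matches_brute_force_overlap_scan(self, rng):
        """Every flag equals an O(n*m) loop over peaks and region intervals."""
        factors = [("F1", "chip"), ("F2", "chip"), ("F3", "clip"), ("F4", "clip")]
        for _ in range(50):
            peaks = []
            for f, assay in factors:
                for _ in range(int(rng.integers(0, 8))):
                    s = int(rng.integers(0, 900))
                    strand = ("+", "-", ".")[int(rng.integers(3))] if assay == "clip" else "."
                    peaks.append(peak("chr1", s, s + int(rng.integers(5, 80)), f, assay, strand))
            n_ex = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(1, 1000), size=2 * n_ex, replace=False))
            exons = tuple(
                (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            tx = make_tx(strand=strand, exons=exons)
            rs = derive_regions(tx)
            got = encode_binding_features(rs, PeakIndex(peaks))
            for region, ivs in rs.by_name().items():
                for f, assay in factors:
                    hit = any(
                        p.factor == f
                        and p.assay == assay
                        and p.interval.chrom == iv.chrom
                        and p.interval.start < iv.end
                        and iv.start < p.interval.end
                        and (
                            assay == "chip"
                            or p.interval.strand == "."
                            or p.interval.strand == iv.strand
                        )
                        for p in peaks
                        for iv in ivs
                    )
                    assert got.get((assay, f, region), 0) == int(hit)


class TestProximalNcrna:
    def test_rank_by_tss_distance(self):
        tx = make_tx(exons=((1000, 1500),))
        near = make_tx("nc1", exons=((800, 900),), biotype="snRNA")  # tss 800, d 200
        far = make_tx("nc2", exons=((2000, 2100),), biotype="snRNA")  # d 1000
        assert [n.transcript_id for n in nearest_ncrnas(tx, [far, near], k=2)] == [
            "nc1",
            "nc2",
        ]

    def test_equidistant_tie_prefers_smaller_coordinate(self):
        tx = make_tx(exons=((1000, 1500),))
        left = make_tx("ncL", exons=((800, 900),), biotype="snRNA")  # tss 800
        right = make_tx("ncR", exons=((1200, 1301),), biotype="snRNA", strand="-")  # tss 1300...
        # craft exact tie: |800-1000| = 200 and |1200-1000| = 200 on plus
        right2 = make_tx("ncR2", exons=((1200, 1300),), biotype="snRNA")
        got = nearest_ncrnas(tx, [right2, left], k=1)
        assert got[0].transcript_id == "ncL"

    def test_polii_factors_excluded_and_matches_neighbour_oracle(self, rng):
        tx = make_tx(exons=((5000, 6000),))
        ncs = [
            make_tx(f"nc{i}", exons=((int(s := rng.integers(0, 12000)), int(s + 150)),),
                    biotype="snRNA")
            for i in range(10)
        ]
        peaks = []
        for nc in ncs:
            peaks.append(peak("chr1", nc.span.start, nc.span.start + 10, "FX", "chip"))
            peaks.append(peak("chr1", nc.span.start, nc.span.start + 10, "POLR2A", "chip"))
        flags = proximal_ncrna_features(tx, ncs, PeakIndex(peaks), k=2)
        assert all(f != "POLR2A" for (_a, f, _r, _k) in flags)
        ranked = sorted(ncs, key=lambda n: (abs(n.tss - tx.tss), n.tss, n.transcript_id))[:2]
        for rank, nc in enumerate(ranked, start=1):
            assert flags.get(("chip", "FX", "5prime", rank)) == 1

    def test_fewer_than_k_available(self):
        tx = make_tx(exons=((1000, 1500),))
        nc = make_tx("nc1", exons=((800, 900),), biotype="snRNA")
        p = peak("chr1", 800, 820, "FX", "chip")
        flags = proximal_ncrna_features(tx, [nc], PeakIndex([p]), k=2)
        assert flags == {("chip", "FX", "5prime", 1): 1}


class TestCpgFeatures:
    def _island(self, s, e, chrom="chr1"):
        return CpGIslandRecord.from_sequence(
            GenomicInterval(chrom, s, e), "CG" * ((e - s) // 2)
        )

    def test_tss_inside_island_distance_zero(self):
        feats = cpg_features("chr1", 150, {"chr1": [self._island(100, 200)]})
        assert feats["cpg.island.dist"] == 0.0
        assert feats["cpg.island.length"] == 100

    def test_no_island_on_chromosome_uses_cap(self):
        feats = cpg_features("chr1", 150, {}, distance_cap=5000)
        assert feats["cpg.island.dist"] == 5000
        assert feats["cpg.island.length"] == 0.0

    def test_equidistant_islands_resolve_to_smaller_coordinate(self):
        a, b = self._island(100, 200), self._island(401, 511)
        feats = cpg_features("chr1", 300, {"chr1": [a, b]})  # 101 bp to both
        # nearest by edge distance: both 101 -> smaller start wins
        assert feats["cpg.island.length"] == a.length

    def test_matches_linear_scan_oracle(self, rng):
        islands = []
        for _ in range(20):
            s = int(rng.integers(0, 10000))
            islands.append(self._island(s, s + int(rng.integers(50, 300))))
        islands.sort(key=lambda r: r.interval.start)
        for _ in range(100):
            tss = int(rng.integers(0, 11000))
            feats = cpg_features("chr1", tss, {"chr1": islands})

            def dist(r):
                if r.interval.start <= tss < r.interval.end:
                    return 0
                return min(abs(tss - r.interval.start), abs(tss - (r.interval.end - 1)))

            assert feats["cpg.island.dist"] == min(dist(r) for r in islands)

    def test_obs_exp_ratio_formula(self):
        rec = CpGIslandRecord.from_sequence(GenomicInterval("chr1", 0, 8), "CGCGATTA")
        # CpG=2, C=2, G=2, len=8 -> obs/exp = 2*8/(2*2) = 4
        assert rec.obs_exp_ratio == pytest.approx(4.0)
        assert rec.percent_cg == pytest.approx(0.5)
        assert rec.percent_cpg == pytest.approx(0.25)


class TestAnnotationFeatures:
    def _genome(self):
        return GenomeSequence({"chr1": "GC" * 5000})

    def test_single_exon_ratios(self):
        tx = make_tx(exons=((100, 400),))
        feats = annotation_features(tx, None, self._genome())
        assert feats["tx.ex.seq"] == 1.0
        assert feats["tx.ex.ratio"] == tx.length
        assert feats["tx.ex.num"] == 1
        assert feats["tx.tss.width"] == 0.0  # no CAGE cluster matched

    def test_all_gc_span(self):
        tx = make_tx(exons=((100, 400),))
        feats = annotation_features(tx, None, self._genome())
        assert feats["tx.gc.seq"] == 1.0

    def test_formula_oracle(self):
        tx = make_tx(exons=((100, 200), (300, 500)), cds=(320, 480), strand="-")
        cluster = CTSSCluster(
            chrom="chr1",
            strand="-",
            positions=np.array([495, 499]),
            tpms=np.array([1.0, 3.0]),
            dominant_position=499,
            total_tpm=4.0,
        )
        genome = GenomeSequence({"chr1": "AT" * 5000})
        feats = annotation_features(
            tx, cluster, genome, housekeeping={"g_t1"}, chrom_order=["chr1"]
        )
        assert feats["tx.len"] == 400
        assert feats["tx.strand"] == 0.0
        assert feats["tx.chr.loc"] == 1.0
        assert feats["tx.loc"] == 100
        assert feats["tx.ex.num"] == 2
        assert feats["tx.ex.width"] == 150
        assert feats["tx.ex.ratio"] == 200
        assert feats["tx.ex.seq"] == pytest.approx(300 / 400)
        assert feats["tx.gc.seq"] == 0.0
        assert feats["tx.tss.width"] == 5
        assert feats["tx.tss.at.cont"] == 1.0
        assert feats["housekeeping"] == 1.0


class TestScalingAndAssembly:
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=40,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_scaling_property(self, values):
        """Scaled values land in [0, 1] and re-scaling is the identity."""
        df = pd.DataFrame({"x": values})
        once = minmax_scale_columns(df, ["x"])
        assert once["x"].between(0.0, 1.0).all()
        twice = minmax_scale_columns(once, ["x"])
        pd.testing.assert_frame_equal(once, twice)

    def test_scaling_idempotent_and_constant_to_zero(self, rng):
        df = pd.DataFrame(
            {
                "a": rng.uniform(-5, 17, size=50),
                "b": np.full(50, 7.0),
                "binary": rng.integers(0, 2, size=50).astype(float),
            }
        )
        once = minmax_scale_columns(df, ["a", "b", "binary"])
        assert once["a"].min() == 0.0 and once["a"].max() == 1.0
        assert (once["b"] == 0.0).all()
        assert (once["binary"] == df["binary"]).all()  # binary untouched
        twice = minmax_scale_columns(once, ["a", "b", "binary"])
        pd.testing.assert_frame_equal(once, twice)

    def test_assembled_column_count_matches_combinatorics(self, small_bundle, small_report):
        m = small_report.prepared.matrix
        n_factors = len(m.factors())
        n_regions = len(REGION_NAMES)
        # own regions + 2 ranked proximal-ncRNA blocks, plus 18 annotation cols
        assert m.values.shape[1] == n_factors * n_regions * 3 + 18
        meta = m.metadata
        assert (meta["kind"] == "binding").sum() == n_factors * n_regions * 3
        assert not meta["name"].duplicated().any()

    def test_polii_columns_segregated(self, small_report):
        m = small_report.prepared.matrix
        assert not any(f.startswith("POLR2") for f in m.factors())
        polii = small_report.prepared.polii_table
        assert polii.shape[1] > 0
        assert all(c.split(".")[1].startswith("POLR2") for c in polii.columns)

    def test_binding_columns_binary_and_scaled_in_unit_interval(self, small_report):
        m = small_report.prepared.matrix
        vals = m.values
        for c in m.binding_columns():
            assert set(np.unique(vals[c])) <= {0.0, 1.0}
        assert (vals.min() >= 0).all() and (vals.max() <= 1.0 + 1e-12).all()

    def test_duplicate_transcripts_rejected(self):
        df = pd.DataFrame({"chip.F.5prime": [1.0, 0.0]}, index=["a", "a"])
        meta = pd.DataFrame(
            [
                {
                    "name": "chip.F.5prime",
                    "kind": "binding",
                    "assay": "chip",
                    "factor": "F",
                    "region": "5prime",
                    "rank": None,
                    "p_obs": 0.5,
                }
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(df, meta)
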
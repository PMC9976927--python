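"""Region derivation, transcript filters and CAGE start-site clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from pausescape.annotation import (
    CTSSCluster,
    ExpressionRecord,
    TranscriptModel,
    aggregate_cage_replicates,
    cluster_ctss,
    derive_regions,
    filter_by_dominant_ctss,
    filter_expressed,
    filter_high_confidence,
)
from pausescape.intervals import GenomicInterval


def make_tx(tid="t1", strand="+", exons=((0, 100), (200, 300)), cds=None,
            biotype="protein_coding", refseq=True, chrom="chr1"):
    iv = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    span = GenomicInterval(chrom, min(s for s, _ in exons), max(e for _, e in exons), strand)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=f"g_{tid}",
        gene_symbol=tid.upper(),
        chrom=chrom,
        strand=strand,
        span=span,
        exons=iv,
        biotype=biotype,
        refseq_supported=refseq,
        cds_span=GenomicInterval(chrom, *cds, strand) if cds else None,
    )


def flatten(ivs):
    return sorted((i.start, i.end) for i in ivs)


class TestDeriveRegions:
    def test_single_exon_noncoding_is_all_five_prime(self):
        tx = make_tx(exons=((10, 110),), biotype="lincRNA")
        rs = derive_regions(tx)
        assert flatten(rs.five_prime) == [(10, 110)]
        assert rs.coding_exons == rs.three_prime == rs.introns == []

    def test_two_exon_plus_with_cds_in_second_exon(self):
        tx = make_tx(exons=((0, 100), (200, 300)), cds=(220, 280))
        rs = derive_regions(tx)
        assert flatten(rs.introns) == [(100, 200)]
        assert flatten(rs.five_prime) == [(0, 100), (200, 220)]
        assert flatten(rs.coding_exons) == [(220, 280)]
        assert flatten(rs.three_prime) == [(280, 300)]

    def test_minus_strand_mirror_is_strand_symmetric(self):
        # mirror of the previous case around position 300
        tx = make_tx(strand="-", exons=((0, 100), (200, 300)), cds=(20, 80))
        rs = derive_regions(tx)
        assert flatten(rs.introns) == [(100, 200)]
        assert flatten(rs.five_prime) == [(80, 100), (200, 300)]
        assert flatten(rs.coding_exons) == [(20, 80)]
        assert flatten(rs.three_prime) == [(0, 20)]

    def test_cds_outside_exon_union_rejected(self):
        tx = make_tx(exons=((100, 200),))
        with pytest.raises(ValueError):
            derive_regions(tx, cds_span=GenomicInterval("chr1", 50, 150, "+"))

    def test_partition_property_on_random_transcripts(self, rng):
        """Regions are disjoint and exons + introns tile the span exactly."""
        for _ in range(200):
            n_ex = int(rng.integers(1, 5))
            bounds = np.sort(rng.choice(np.arange(1, 500), size=2 * n_ex, replace=False))
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
            strand = "+" if rng.random() < 0.5 else "-"
            lo, hi = exons[0][0], exons[-1][1]
            cds = None
            if rng.random() < 0.7 and hi - lo > 4:
                c0 = int(rng.integers(lo, hi - 1))
                c1 = int(rng.integers(c0 + 1, hi))
                cds = (c0, c1)
            tx = make_tx(strand=strand, exons=tuple(exons), cds=cds)
            rs = derive_regions(tx)
            covered = set()
            for group in (rs.five_prime, rs.coding_exons, rs.introns, rs.three_prime):
                for iv in group:
                    bases = set(range(iv.start, iv.end))
                    assert not (covered & bases), "regions overlap"
                    covered |= bases
            assert covered == set(range(lo, hi))


class TestFilters:
    def test_high_confidence_set_membership(self):
        txs = [make_tx(f"t{i}", refseq=(i % 2 == 0)) for i in range(6)]
        kept = filter_high_confidence(txs, refseq_ids={"t1"})
        assert [t.transcript_id for t in kept] == ["t0", "t1", "t2", "t4"]
        assert filter_high_confidence([make_tx("x", refseq=False)]) == []
        allt = [make_tx(f"t{i}") for i in range(3)]
        assert filter_high_confidence(allt) == allt

    def test_expression_boundary_and_log(self):
        txs = [make_tx("a"), make_tx("b"), make_tx("c")]
        expr = {
            "a": ExpressionRecord("a", 1.0, 0.0),  # one silent replicate
            "b": ExpressionRecord("b", 2.0, 2.0),
        }
        kept, log10 = filter_expressed(txs, expr)
        assert [t.transcript_id for t in kept] == ["b"]
        assert log10["b"] == pytest.approx(math.log10(2.0))

    def test_filters_idempotent_and_commute(self):
        txs = [make_tx(f"t{i}", refseq=(i % 3 != 0)) for i in range(9)]
        expr = {
            f"t{i}": ExpressionRecord(f"t{i}", float(i % 2), 1.0) for i in range(9)
        }
        hc = filter_high_confidence(txs)
        assert filter_high_confidence(hc) == hc
        a, _ = filter_expressed(filter_high_confidence(txs), expr)
        b0, _ = filter_expressed(txs, expr)
        b = filter_high_confidence(b0)
        assert a == b


class TestCtssClustering:
    def test_direct_construction(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "position": [100, 105, 300],
                "strand": ["+"] * 3,
                "tpm": [5.0, 3.0, 0.05],
            }
        )
        clusters = cluster_ctss(df, tpm_threshold=0.1, max_gap=20)
        assert len(clusters) == 1
        c = clusters[0]
        assert list(c.positions) == [100, 105]
        assert c.dominant_position == 100
        assert c.width == 6
        assert c.total_tpm == pytest.approx(8.0)

    def test_empty_table(self):
        df = pd.DataFrame(columns=["chrom", "position", "strand", "tpm"])
        assert cluster_ctss(df) == []

    def test_threshold_boundary_inclusive(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "position": [100, 500],
                "strand": ["+", "+"],
                "tpm": [0.1, 0.09],
            }
        )
        clusters = cluster_ctss(df, tpm_threshold=0.1, max_gap=20)
        assert [c.dominant_position for c in clusters] == [100]

    def test_negative_tpm_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "position": [1], "strand": ["+"], "tpm": [-1.0]}
        )
        with pytest.raises(ValueError):
            cluster_ctss(df)

    def test_dominant_tie_breaks_most_five_prime(self):
        for strand, expected in (("+", 100), ("-", 104)):
            df = pd.DataFrame(
                {
                    "chrom": ["chr1"] * 2,
                    "position": [100, 104],
                    "strand": [strand] * 2,
                    "tpm": [2.0, 2.0],
                }
            )
            (c,) = cluster_ctss(df, max_gap=20)
            assert c.dominant_position == expected

    def test_clusters_are_maximal(self, rng):
        """No two clusters on the same chrom/strand lie within max_gap."""
        for _ in range(50):
            n = int(rng.integers(5, 60))
            df = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "position": rng.choice(2000, size=n, replace=False),
                    "strand": "+",
                    "tpm": rng.uniform(0.0, 2.0, size=n),
                }
            )
            gap = int(rng.integers(1, 50))
            clusters = cluster_ctss(df, max_gap=gap)
            spans = sorted((c.positions.min(), c.positions.max()) for c in clusters)
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert s1 - e0 > gap


class TestDominantCtssFilter:
    def _cluster(self, pos, chrom="chr1", strand="+"):
        return CTSSCluster(
            chrom=chrom,
            strand=strand,
            positions=np.array([pos]),
            tpms=np.array([1.0]),
            dominant_position=pos,
            total_tpm=1.0,
        )

    def test_exact_match_kept_one_off_dropped(self):
        tx = make_tx(exons=((50, 400),))
        kept, m = filter_by_dominant_ctss([tx], [self._cluster(50)], tolerance=0)
        assert kept == [tx] and m[tx.transcript_id].dominant_position == 50
        kept, _ = filter_by_dominant_ctss([tx], [self._cluster(51)], tolerance=0)
        assert kept == []
        kept, _ = filter_by_dominant_ctss([tx], [self._cluster(51)], tolerance=1)
        assert kept == [tx]

    def test_strand_must_match(self):
        tx = make_tx(exons=((50, 400),))
        kept, _ = filter_by_dominant_ctss([tx], [self._cluster(50, strand="-")])
        assert kept == []

    def test_matches_exhaustive_search(self, rng):
        txs = [
            make_tx(f"t{i}", exons=((int(p := rng.integers(0, 5000)), int(p + 200)),))
            for i in range(60)
        ]
        clusters = [self._cluster(int(rng.integers(0, 5200))) for _ in range(40)]
        for tol in (0, 2, 10):
            kept, _ = filter_by_dominant_ctss(txs, clusters, tolerance=tol)
            expected = [
                t
                for t in txs
                if any(
                    abs(c.dominant_position - t.tss) <= tol and c.strand == t.strand
                    for c in clusters
                )
            ]
            assert kept == expected


class TestCageAggregation:
    def test_most_correlated_pair_summed_to_tpm(self):
        base = pd.DataFrame(
            {"chrom": "chr1", "position": [1, 2, 3, 4], "strand": "+"}
        )
        r1 = base.assign(count=[10, 20, 30, 40])
        r2 = base.assign(count=[11, 19, 33, 41])  # highly correlated with r1
        r3 = base.assign(count=[40, 5, 22, 1])
        out = aggregate_cage_replicates({"r1": r1, "r2": r2, "r3": r3})
        expected = np.array([21, 39, 63, 81], dtype=float)
        assert np.allclose(out["tpm"], expected / expected.sum() * 1e6)
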
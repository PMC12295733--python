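import numpy as np
import pandas as pd
import pytest

from conftest import random_ecc_frame
from ecckit.annotation import (
    CATEGORIES,
    IntervalSet,
    annotate,
    derive_tracks,
    per_chromosome_proportions,
    window_density,
)
from ecckit.io_formats import GenomeLayout


def brute_overlap(tuples, chrom, start, end):
    return any(c == chrom and s < end and e > start for c, s, e in tuples)


class TestIntervalSet:
    def test_one_bp_overlap_counts_and_abutment_does_not(self):
        ivs = IntervalSet.from_tuples([("chrA", 19, 30)])
        assert ivs.overlaps("chrA", 10, 20)
        assert not IntervalSet.from_tuples([("chrA", 20, 30)]).overlaps("chrA", 10, 20)

    def test_matches_all_pairs_on_random_sets(self):
        rng = np.random.default_rng(11)
        tuples = [
            ("chr" + str(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 500)))
            for s in rng.integers(0, 50_000, size=300)
        ]
        ivs = IntervalSet.from_tuples(tuples)
        queries = [
            ("chr" + str(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 800)))
            for s in rng.integers(0, 50_000, size=400)
        ]
        got = ivs.overlaps_many(
            [q[0] for q in queries],
            np.array([q[1] for q in queries]),
            np.array([q[2] for q in queries]),
        )
        want = np.array([brute_overlap(tuples, *q) for q in queries])
        np.testing.assert_array_equal(got, want)

    def test_complement_partitions_the_genome(self, toy_layout):
        ivs = IntervalSet.from_tuples(
            [("chrA", 100, 200), ("chrA", 150, 300), ("chrB", 0, 500_000)]
        )
        comp = ivs.complement(toy_layout)
        assert ivs.total_bp + comp.total_bp == toy_layout.total_bp
        for chrom, s, e in comp.to_tuples():
            assert not ivs.overlaps(chrom, s, e)


class TestDerivedTracks:
    layout = GenomeLayout(("chrA",), {"chrA": 1_000_000})

    @staticmethod
    def gene_model(rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "strand", "feature"]
        )

    def test_plus_strand_gene_windows(self):
        gm = self.gene_model([("chrA", 5000, 8000, "g", "+", "gene")])
        cpg = pd.DataFrame(columns=["chrom", "start", "end"])
        d = derive_tracks(gm, cpg, self.layout)
        assert d["gene_upstream_2kb"] == [("chrA", 3000, 5000)]
        assert d["gene_downstream_2kb"] == [("chrA", 8000, 10000)]

    def test_minus_strand_swaps_upstream_and_downstream(self):
        gm = self.gene_model([("chrA", 5000, 8000, "g", "-", "gene")])
        cpg = pd.DataFrame(columns=["chrom", "start", "end"])
        d = derive_tracks(gm, cpg, self.layout)
        assert d["gene_upstream_2kb"] == [("chrA", 8000, 10000)]
        assert d["gene_downstream_2kb"] == [("chrA", 3000, 5000)]

    def test_windows_clip_at_chromosome_bounds(self):
        gm = self.gene_model([("chrA", 500, 900, "g", "+", "gene")])
        cpg = pd.DataFrame(columns=["chrom", "start", "end"])
        d = derive_tracks(gm, cpg, self.layout)
        assert d["gene_upstream_2kb"] == [("chrA", 0, 500)]

    def test_intergenic_is_complement_of_merged_genes(self):
        layout = GenomeLayout(("chrA",), {"chrA": 1000})
        gm = self.gene_model(
            [("chrA", 100, 200, "g1", "+", "gene"), ("chrA", 150, 300, "g2", "-", "gene")]
        )
        cpg = pd.DataFrame(columns=["chrom", "start", "end"])
        d = derive_tracks(gm, cpg, layout, flank_bp=10)
        assert d["intergenic"] == [("chrA", 0, 100), ("chrA", 300, 1000)]

    def test_cpg_flanks_are_strandless_windows(self):
        gm = self.gene_model([])
        cpg = pd.DataFrame([("chrA", 10_000, 10_500)], columns=["chrom", "start", "end"])
        d = derive_tracks(gm, cpg, self.layout)
        assert d["cpg_upstream_2kb"] == [("chrA", 8000, 10_000)]
        assert d["cpg_downstream_2kb"] == [("chrA", 10_500, 12_500)]

    def test_gene_on_undeclared_chromosome_errors(self):
        gm = self.gene_model([("chrZ", 0, 10, "g", "+", "gene")])
        cpg = pd.DataFrame(columns=["chrom", "start", "end"])
        with pytest.raises(ValueError, match="undeclared"):
            derive_tracks(gm, cpg, self.layout)


class TestCatalog:
    def test_has_all_24_categories_nonempty_core(self, small_catalog):
        assert tuple(small_catalog.keys()) == CATEGORIES
        for cat in ("gene", "exon", "intron", "enhancer", "dhs", "cpg_island",
                    "repeat_all", "sine", "alu", "mir", "transposon"):
            assert small_catalog[cat].n_intervals > 0, cat

    def test_overlap_matrix_consistency(self, small_genome, small_catalog):
        layout, _ = small_genome
        ecc = random_ecc_frame(layout, 400, np.random.default_rng(5))
        m = annotate(ecc, small_catalog)
        # repeat_all is implied by any repeat-class hit
        classes = ["sine", "line", "ltr", "dna_repeat", "simple_repeat",
                   "low_complexity", "satellite"]
        assert (m[classes].any(axis=1) <= m["repeat_all"]).all()
        # Alu and MIR are SINE families; transposon covers the four classes
        assert (m["alu"] <= m["sine"]).all() and (m["mir"] <= m["sine"]).all()
        assert (m[["sine", "line", "ltr", "dna_repeat"]].any(axis=1) == m["transposon"]).all()
        # genic/intergenic jointly cover the genome
        assert (m["gene"] | m["intergenic"]).all()


class TestDensity:
    def test_counts_by_start_window(self, toy_layout):
        ecc = pd.DataFrame(
            {"chrom": ["chrA"] * 10, "start": np.arange(10) * 1000, "end": np.arange(10) * 1000 + 200}
        )
        d = window_density(ecc, toy_layout, window_bp=1_000_000)
        assert d.loc[(d.chrom == "chrA") & (d.window_start == 0), "count"].item() == 10
        assert d["count"].sum() == 10

    def test_rejects_nonpositive_window(self, toy_layout):
        with pytest.raises(ValueError):
            window_density(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                           toy_layout, window_bp=0)

    def test_proportions_sum_to_one_and_track_uniformity(self):
        layout = GenomeLayout(("chr1", "chr2"), {"chr1": 10**6, "chr2": 10**6})
        ecc = random_ecc_frame(layout, 10_000, np.random.default_rng(0), max_len=200)
        props = per_chromosome_proportions(ecc, layout)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)
        assert props["chr1"] == pytest.approx(0.5, abs=0.05)
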
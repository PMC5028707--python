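"""Filter cascade: pairing, SINE containment, TIS overlap, CAGE support,
and the end-to-end screen on synthetic data with planted truth."""

import json

import pytest

from sineup_scan.errors import ConfigError, SineupError
from sineup_scan.models import CageCluster, GenomicInterval, RepeatFeature
from sineup_scan.screen import (
    FunnelReport,
    ScreenConfig,
    annotate_cage_support,
    filter_sine_containing,
    filter_tis_overlap,
    find_antisense_pairs,
    run_screen,
    screen_transcripts,
)
from sineup_scan.simulate import SyntheticDatasetSpec, build_dataset, generate_dataset

from conftest import exon_bases, interval_bases, tx


def repeat(start, end, name="FRAM", rclass="SINE", family="Alu", strand="+", chrom="chr1"):
    return RepeatFeature(
        chrom=chrom,
        interval=GenomicInterval(chrom, start, end, strand),
        strand=strand,
        repeat_name=name,
        repeat_class=rclass,
        repeat_family=family,
    )


def cage(start, end, tpm=1.0, strand="-", chrom="chr1", name="c"):
    return CageCluster(
        chrom=chrom,
        interval=GenomicInterval(chrom, start, end, strand),
        strand=strand,
        tpm=tpm,
        name=name,
    )


SENSE = tx("REF", "+", [(100, 500)], cds=(160, 460), source="reference")


class TestFindAntisensePairs:
    def test_head_to_head_pair_found(self):
        (p,) = find_antisense_pairs([tx("A", "-", [(50, 200)])], [SENSE])
        assert (p.antisense_id, p.sense_id) == ("A", "REF")
        assert p.configuration.category == "divergent"

    def test_same_strand_and_intergenic_yield_nothing(self):
        asm = [tx("S", "+", [(50, 200)]), tx("I", "-", [(5000, 5400)])]
        assert find_antisense_pairs(asm, [SENSE]) == []

    def test_one_nat_pairs_with_each_overlapped_isoform(self):
        iso2 = tx("REF2", "+", [(120, 480)], cds=(200, 470), source="reference")
        pairs = find_antisense_pairs([tx("A", "-", [(50, 200)])], [SENSE, iso2])
        assert [(p.antisense_id, p.sense_id) for p in pairs] == [("A", "REF"), ("A", "REF2")]

    def test_planted_mix_matches_all_pairs_brute_force(self, rng):
        """On a synthetic dataset the sweep returns exactly the pairs an
        all-pairs per-base oracle finds."""
        ds = build_dataset(SyntheticDatasetSpec(seed=3, n_true=3, n_no_sine=2,
                                                n_no_tis=2, n_same_strand=2,
                                                n_intergenic=2))
        pairs = find_antisense_pairs(ds.assembly, ds.reference)
        got = {(p.antisense_id, p.sense_id) for p in pairs}
        oracle = set()
        for a in ds.assembly:
            for r in ds.reference:
                if a.strand != r.strand and len(exon_bases(a) & exon_bases(r)) >= 1:
                    oracle.add((a.transcript_id, r.transcript_id))
        assert got == oracle


class TestFilterSine:
    def test_fram_kept_and_attached(self):
        pairs = find_antisense_pairs([tx("A", "-", [(50, 200)])], [SENSE])
        kept = filter_sine_containing(pairs, [repeat(60, 207)])
        assert [r.repeat_name for r in kept[0].embedded_repeats] == ["FRAM"]

    def test_line_only_dropped_unless_class_allowed(self):
        pairs = find_antisense_pairs([tx("A", "-", [(50, 200)])], [SENSE])
        line = repeat(60, 207, name="L1MA4", rclass="LINE", family="L1")
        sine_elsewhere = repeat(5000, 5300)
        assert filter_sine_containing(pairs, [line, sine_elsewhere]) == []
        kept = filter_sine_containing(
            pairs, [line, sine_elsewhere], classes={"SINE", "LINE"}
        )
        assert [r.repeat_name for r in kept[0].embedded_repeats] == ["L1MA4"]

    def test_unknown_class_label_is_config_error(self):
        pairs = find_antisense_pairs([tx("A", "-", [(50, 200)])], [SENSE])
        with pytest.raises(ConfigError, match="LTR.*present.*SINE"):
            filter_sine_containing(pairs, [repeat(60, 207)], classes={"SINE", "LTR"})

    def test_exonic_not_intronic_overlap_counts(self):
        anti = tx("A", "-", [(50, 120), (180, 260)])
        pairs = find_antisense_pairs([anti], [SENSE])
        intronic = repeat(130, 170)
        assert filter_sine_containing(pairs, [intronic]) == []


class TestFilterTis:
    def test_covering_antisense_kept_with_width(self):
        pairs = find_antisense_pairs([tx("A", "-", [(110, 210)])], [SENSE])
        kept = filter_tis_overlap(pairs)
        assert kept[0].tis_overlap_bp == 5  # TIS window [155,160)

    def test_three_prime_only_overlap_dropped(self):
        pairs = find_antisense_pairs([tx("A", "-", [(400, 700)])], [SENSE])
        assert filter_tis_overlap(pairs) == []

    def test_cds_only_antisense_dropped(self):
        pairs = find_antisense_pairs([tx("A", "-", [(200, 300)])], [SENSE])
        assert filter_tis_overlap(pairs) == []

    def test_sense_without_cds_never_matches(self):
        ref = tx("NC", "+", [(100, 500)], source="reference")
        pairs = find_antisense_pairs([tx("A", "-", [(50, 200)])], [ref])
        assert filter_tis_overlap(pairs) == []

    @pytest.mark.parametrize("offset", range(-3, 4))
    def test_boundary_sweep_matches_per_base_oracle(self, offset):
        """Antisense 3' ends swept across the window edge: kept iff >=1
        shared base (half-open boundary semantics)."""
        from sineup_scan.intervals import tis_window

        anti_end = 155 + offset  # window starts at 155
        if anti_end <= 50:
            pytest.skip("degenerate")
        anti = tx("A", "-", [(50, anti_end)])
        pairs = find_antisense_pairs([anti], [SENSE])
        kept = filter_tis_overlap(pairs) if pairs else []
        win = tis_window(SENSE, k=5)
        expected = len(exon_bases(anti) & interval_bases(win.intervals))
        assert (len(kept) == 1) == (expected >= 1)
        if kept:
            assert kept[0].tis_overlap_bp == expected


class TestCageSupport:
    def _pair(self, anti_exons=((50, 200),)):
        (p,) = find_antisense_pairs([tx("A", "-", [tuple(e) for e in anti_exons])], [SENSE])
        return p

    def test_supported_within_halfwidth(self):
        # antisense 5' end at base 199; cluster 150 nt upstream
        (p,) = annotate_cage_support([self._pair()], [cage(348, 360, tpm=7.2)])
        assert (p.cage_supported, p.cage_distance, p.cage_best_tpm) == (True, 149, 7.2)

    @pytest.mark.parametrize("dist,inside", [(200, True), (201, False)])
    def test_boundary_200_in_201_out(self, dist, inside):
        (p,) = annotate_cage_support(
            [self._pair()], [cage(199 + dist, 199 + dist + 10)]
        )
        assert p.cage_supported is inside

    def test_strand_mismatch_ignored_unless_allowed(self):
        clusters = [cage(180, 210, strand="+")]
        (p,) = annotate_cage_support([self._pair()], clusters)
        assert not p.cage_supported
        (p,) = annotate_cage_support([self._pair()], clusters, same_strand=False)
        assert p.cage_supported and p.cage_distance == 0

    def test_best_tpm_and_min_distance_over_clusters(self):
        clusters = [cage(377, 387, tpm=3.0), cage(157, 167, tpm=9.0)]
        (p,) = annotate_cage_support([self._pair()], clusters)
        # exhaustive-scan oracle over both clusters
        dists = [max(c.interval.start - 199, 199 - c.interval.end + 1, 0) for c in clusters]
        assert p.cage_supported
        assert p.cage_best_tpm == 9.0
        assert p.cage_distance == min(dists)


class TestRunScreen:
    def test_planted_dataset_recovers_exact_truth(self, tmp_path):
        ds = generate_dataset(SyntheticDatasetSpec(seed=7), tmp_path / "data")
        cfg = ScreenConfig(
            ds.paths["assembly"], ds.paths["reference"], ds.paths["repeats"],
            ds.paths["cage"], out_dir=tmp_path / "out",
        )
        candidates, report = run_screen(cfg)
        assert {c.antisense_id for c in candidates} == ds.truth_ids("true_candidate")
        assert (report.n_assembly, report.n_antisense, report.n_sine, report.n_tis) == (
            30, 20, 15, 10,
        )
        assert (tmp_path / "out" / "funnel.json").exists()
        funnel = json.loads((tmp_path / "out" / "funnel.json").read_text())
        assert funnel["n_tis"] == 10

    def test_empty_assembly_gives_zero_funnel(self, tmp_path):
        ds = generate_dataset(SyntheticDatasetSpec(seed=5, n_true=2), tmp_path / "d")
        empty = tmp_path / "empty.gtf"
        empty.write_text("")
        cfg = ScreenConfig(empty, ds.paths["reference"], ds.paths["repeats"], ds.paths["cage"])
        candidates, report = run_screen(cfg)
        assert candidates == []
        assert (report.n_assembly, report.n_antisense, report.n_sine,
                report.n_tis, report.n_cage) == (0, 0, 0, 0, 0)

    def test_missing_input_is_fatal_with_name(self, tmp_path):
        cfg = ScreenConfig(tmp_path / "nope.gtf", tmp_path / "nope.gtf",
                           tmp_path / "nope.out", tmp_path / "nope.bed")
        with pytest.raises(SineupError, match="nope.gtf"):
            run_screen(cfg)

    def test_reference_without_cds_warns_and_empties_tis(self):
        ref = [tx("NC", "+", [(100, 500)], source="reference")]
        asm = [tx("A", "-", [(50, 200)])]
        with pytest.warns(UserWarning, match="no CDS"):
            _, report = screen_transcripts(asm, ref, [repeat(60, 207)], [])
        assert report.n_antisense == 1 and report.n_tis == 0

    def test_cage_filter_promotes_annotation_to_filter(self):
        asm = [tx("A", "-", [(110, 210)])]
        reps = [repeat(120, 207)]
        cands, rep = screen_transcripts(asm, [SENSE], reps, [], ScreenConfig("", "", "", ""))
        assert len(cands) == 1 and not cands[0].cage_supported
        cfg = ScreenConfig("", "", "", "", cage_filter=True)
        cands2, rep2 = screen_transcripts(asm, [SENSE], reps, [], cfg)
        assert cands2 == [] and rep2.n_tis == 1 and rep2.n_cage == 0


class TestCascadeProperties:
    def test_funnel_monotone_and_filters_commute_on_fuzz(self):
        """SINE and TIS filters are independent predicates: order must not
        change the surviving set; funnel counts never increase."""
        for seed in range(12):
            ds = build_dataset(SyntheticDatasetSpec(
                seed=seed, n_true=3, n_no_sine=2, n_no_tis=2,
                n_same_strand=2, n_intergenic=1,
                n_background_repeats=10, cage_noise_clusters=3,
            ))
            pairs = find_antisense_pairs(ds.assembly, ds.reference)
            ab = filter_tis_overlap(filter_sine_containing(pairs, ds.repeats))
            ba = filter_sine_containing(filter_tis_overlap(pairs), ds.repeats)
            assert {(p.antisense_id, p.sense_id) for p in ab} == {
                (p.antisense_id, p.sense_id) for p in ba
            }
            _, rep = screen_transcripts(ds.assembly, ds.reference, ds.repeats, ds.cage)
            assert rep.n_assembly >= rep.n_antisense >= rep.n_sine >= rep.n_tis >= rep.n_cage

    def test_funnel_report_rejects_non_monotone_counts(self):
        with pytest.raises(SineupError):
            FunnelReport(5, 6, 2, 1, 0)

    def test_byte_identical_outputs_across_runs(self, tmp_path):
        ds = generate_dataset(SyntheticDatasetSpec(seed=13, n_true=4), tmp_path / "d")
        digests = []
        for run in ("r1", "r2"):
            out = tmp_path / run
            cfg = ScreenConfig(ds.paths["assembly"], ds.paths["reference"],
                               ds.paths["repeats"], ds.paths["cage"], out_dir=out)
            run_screen(cfg)
            digests.append(tuple(
                (out / f).read_bytes() for f in ("candidates.tsv", "candidates.bed", "funnel.json")
            ))
        assert digests[0] == digests[1]
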
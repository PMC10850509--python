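"""Loop filtering, anchor classification, NLS, aggregate gene scores,
and the baseline-vs-depletion contrast."""
import numpy as np
import pytest

import rosehip as rh
from rosehip.core import Anchor, Gene, GenomeModel, Loop, Peak
from rosehip.loops import (
    LoopFilterConfig,
    assign_peak_context,
    classify_anchors_and_loops,
    filter_loops,
    gene_aggregate_scores,
    loop_class_contrast,
    normalized_loop_score,
    partition_loci_for_differential,
)
from rosehip.tracks import CoverageTrack


def make_loop(name, pet, fdr, a=("chr1", 0, 1000), b=("chr1", 5000, 6000)):
    return Loop(Anchor(*a), Anchor(*b), name, pet, fdr)


class TestLoopFilter:
    @pytest.mark.parametrize(
        "pet,fdr,kept",
        [
            (4, 0.009, True),   # both boundaries satisfied
            (3, 0.001, False),  # PET below minimum
            (10, 0.01, False),  # FDR boundary is strict
            (4, 0.0099999, True),
        ],
    )
    def test_boundary_conventions(self, pet, fdr, kept):
        out = filter_loops([make_loop("l", pet, fdr)])
        assert bool(out) is kept

    def test_idempotent_and_order_independent(self):
        loops = [make_loop(f"l{i}", pet, fdr)
                 for i, (pet, fdr) in enumerate([(4, 0.001), (2, 0.001), (9, 0.5), (7, 0.005)])]
        once = filter_loops(loops)
        assert [l.name for l in filter_loops(once)] == [l.name for l in once]
        reversed_names = {l.name for l in filter_loops(loops[::-1])}
        assert reversed_names == {l.name for l in once}

    def test_planted_pass_count_exact(self, small_config):
        """The generator's configured pass count is recovered exactly."""
        cfg = rh.SimulationConfig(
            **{
                **small_config.__dict__,
                "n_loops": 120,
                "n_loops_pass": 75,
                "n_chromosomes": 5,
            }
        )
        data = rh.simulate_dataset(cfg, seed=3, with_tracks=False)
        retained = filter_loops(data.loops_baseline)
        assert len(retained) == 75
        truth_pass = set(data.truth.true_vcp_loops) | set(data.truth.true_control_loops)
        assert {l.name for l in retained} == truth_pass


class TestClassification:
    VCP = [Peak("chr1", 500, 600, "v1"), Peak("chr1", 5500, 5600, "v2")]

    def test_both_anchors_hit_gives_vcp(self):
        loops = [make_loop("l", 5, 0.001)]
        _, out = classify_anchors_and_loops(loops, self.VCP)
        assert out[0].loop_class == "vcp"

    def test_neither_anchor_hit_gives_control(self):
        loops = [make_loop("l", 5, 0.001, a=("chr2", 0, 1000), b=("chr2", 5000, 6000))]
        _, out = classify_anchors_and_loops(loops, self.VCP)
        assert out[0].loop_class == "control"

    def test_single_anchor_hit_gives_vcp(self):
        loops = [make_loop("l", 5, 0.001, b=("chr1", 8000, 9000))]
        _, out = classify_anchors_and_loops(loops, self.VCP)
        assert out[0].loop_class == "vcp"

    def test_region_restriction_narrows_vcp_peaks(self):
        loops = [make_loop("l", 5, 0.001)]
        far_region = [rh.StitchedRegion("chr1", 100_000, 200_000, [])]
        _, out = classify_anchors_and_loops(loops, self.VCP, restrict_to_regions=far_region)
        assert out[0].loop_class == "control"


class TestNormalizedLoopScore:
    def test_worked_example(self):
        loops = [make_loop(f"l{i}", p, 0.001) for i, p in enumerate([4, 6, 10])]
        normalized_loop_score(loops)
        assert [l.nls for l in loops] == pytest.approx([0.6, 0.9, 1.5])

    def test_equal_pets_give_unit_scores(self):
        loops = [make_loop(f"l{i}", 7, 0.001) for i in range(5)]
        normalized_loop_score(loops)
        assert all(l.nls == pytest.approx(1.0) for l in loops)

    @pytest.mark.parametrize("mode", ["mean", "median"])
    def test_invariant_under_uniform_pet_scaling(self, mode):
        pets = [4, 6, 9, 30]
        a = [make_loop(f"l{i}", p, 0.001) for i, p in enumerate(pets)]
        b = [make_loop(f"l{i}", 2 * p, 0.001) for i, p in enumerate(pets)]
        normalized_loop_score(a, mode)
        normalized_loop_score(b, mode)
        assert [l.nls for l in a] == pytest.approx([l.nls for l in b])

    def test_mean_mode_has_unit_mean(self):
        rng = np.random.default_rng(0)
        loops = [make_loop(f"l{i}", int(p), 0.001)
                 for i, p in enumerate(rng.integers(4, 100, 50))]
        normalized_loop_score(loops)
        assert np.mean([l.nls for l in loops]) == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalized_loop_score([])


def toy_scoring_fixture():
    """One gene with a promoter peak (uniform coverage 3) and a looped
    enhancer peak (coverage 2) connected by a loop of NLS 1.5."""
    genome = GenomeModel([("chr1", 100_000)], [Gene("g", "chr1", 50_000)])
    prom_peak = Peak("chr1", 49_750, 50_250, "prom")
    enh_peak = Peak("chr1", 10_000, 10_500, "enh")
    loop = Loop(
        Anchor("chr1", 9_500, 11_000), Anchor("chr1", 49_000, 51_000), "lp", 6, 0.001
    )
    loop.loop_class = "vcp"
    loop.nls = 1.5
    track = CoverageTrack({"chr1": (np.array([0, 30_000]), np.array([30_000, 100_000]),
                                    np.array([2.0, 3.0]))})
    return genome, [prom_peak, enh_peak], [loop], {"at3": track}


class TestPeakContext:
    def test_promoter_boundary_is_half_open(self):
        genome = GenomeModel([("chr1", 100_000)], [Gene("g", "chr1", 50_000)])
        cfg = LoopFilterConfig()
        inside = Peak("chr1", 52_249, 52_749, "in")  # center 52499 = tss + 2499
        outside = Peak("chr1", 52_250, 52_750, "out")  # center 52500 = tss + 2500
        ctx = assign_peak_context([inside, outside], genome, [], cfg)
        assert ctx[0].promoter_genes == {"g"}
        assert ctx[1].is_unassigned

    def test_looped_enhancer_context(self):
        genome, peaks, loops, _ = toy_scoring_fixture()
        ctx = assign_peak_context(peaks, genome, loops)
        enh = next(c for c in ctx if c.peak.name == "enh")
        assert [(g, l.name) for g, l in enh.enhancer_pairs] == [("g", "lp")]

    def test_peak_outside_everything_unassigned(self):
        genome, _, loops, _ = toy_scoring_fixture()
        stray = Peak("chr1", 70_000, 70_500, "stray")
        ctx = assign_peak_context([stray], genome, loops)
        assert ctx[0].is_unassigned


class TestGeneAggregateScore:
    def test_worked_example(self):
        genome, peaks, loops, tracks = toy_scoring_fixture()
        ctx = assign_peak_context(peaks, genome, loops)
        profiles = gene_aggregate_scores(ctx, genome, tracks, loops)
        prof = profiles["g"]
        assert prof.scores["at3"] == pytest.approx(3.0 + 2.0 * 1.5)
        assert prof.gene_class == "looped_enhancer"
        assert prof.nls_per_promoter == pytest.approx(1.5)

    def test_gene_without_context_is_untargeted(self):
        genome, peaks, loops, tracks = toy_scoring_fixture()
        genome = GenomeModel(
            genome.chromosomes, genome.genes + [Gene("lonely", "chr1", 90_000)]
        )
        ctx = assign_peak_context(peaks, genome, loops)
        profiles = gene_aggregate_scores(ctx, genome, tracks, loops)
        assert profiles["lonely"].gene_class == "untargeted"
        assert profiles["lonely"].scores["at3"] == 0.0

    def test_matches_brute_force_oracle(self, small_dataset):
        """Pipeline scores equal an exhaustive double-loop computation."""
        data = small_dataset
        cfg = LoopFilterConfig()
        retained = filter_loops(data.loops_baseline, cfg)
        classify_anchors_and_loops(retained, data.peaks["vcp"])
        normalized_loop_score(retained)
        vcp_peaks = data.peaks["vcp"]
        ctx = assign_peak_context(vcp_peaks, data.genome, retained, cfg)
        profiles = gene_aggregate_scores(
            ctx, data.genome, data.tracks, retained, cfg
        )

        track = data.tracks["at3"]
        W = cfg.promoter_window
        for g in data.genome.genes:
            expected = 0.0
            for p in vcp_peaks:
                E = track.window_mean(p.chrom, p.center - 500, p.center + 500)
                if p.chrom == g.chrom and g.tss - W <= p.center < g.tss + W:
                    expected += E
                for lp in retained:
                    for mine, partner in (
                        (lp.anchor1, lp.anchor2),
                        (lp.anchor2, lp.anchor1),
                    ):
                        if (
                            mine.chrom == p.chrom
                            and mine.start <= p.center < mine.end
                            and partner.overlaps(g.chrom, g.tss - W, g.tss + W)
                        ):
                            expected += E * lp.nls
            assert profiles[g.gene_id].scores["at3"] == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )

    def test_removing_a_loop_removes_exactly_its_term(self):
        genome, peaks, loops, tracks = toy_scoring_fixture()
        ctx = assign_peak_context(peaks, genome, loops)
        with_loop = gene_aggregate_scores(ctx, genome, tracks, loops)["g"]
        ctx2 = assign_peak_context(peaks, genome, [])
        without = gene_aggregate_scores(ctx2, genome, tracks, [])["g"]
        assert with_loop.scores["at3"] - without.scores["at3"] == pytest.approx(
            2.0 * 1.5
        )


class TestLoopContrast:
    def test_closed_form_log_ratio(self):
        base = [make_loop("l", 10, 0.001)]
        dep = [make_loop("l", 5, 0.001)]
        base[0].loop_class = dep[0].loop_class = "vcp"
        # balancing loop keeps total PETs equal across conditions, so in
        # the vanishing-pseudocount limit 10 -> 5 is exactly -1
        base2 = [make_loop("x", 10, 0.001, a=("chr2", 0, 100), b=("chr2", 500, 600))]
        dep2 = [make_loop("x", 15, 0.001, a=("chr2", 0, 100), b=("chr2", 500, 600))]
        for l in base2 + dep2:
            l.loop_class = "control"
        res = loop_class_contrast(base + base2, dep + dep2, pseudocount=1e-12)
        table = res.table.set_index("name")
        assert table.loc["l", "log2_ratio"] == pytest.approx(-1.0, abs=1e-6)

    def test_identical_conditions_give_zero_ratios(self):
        loops = [make_loop(f"l{i}", 5 + i, 0.001,
                           a=("chr1", i * 10_000, i * 10_000 + 1000),
                           b=("chr1", i * 10_000 + 5000, i * 10_000 + 6000))
                 for i in range(10)]
        for i, l in enumerate(loops):
            l.loop_class = "vcp" if i % 2 else "control"
        res = loop_class_contrast(loops, loops)
        assert np.allclose(res.table["log2_ratio"], 0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_no_matched_loops_raises(self):
        a = [make_loop("a", 5, 0.001)]
        b = [make_loop("b", 5, 0.001, a=("chr2", 0, 100), b=("chr2", 500, 600))]
        with pytest.raises(ValueError, match="matched"):
            loop_class_contrast(a, b)

    def test_depletion_detected_and_directional(self):
        """delta = 0.5 on VCP loops shifts their ratios below control."""
        cfg = rh.SimulationConfig(
            n_loops=600, n_loops_pass=550, depletion_factor=0.5,
            n_singleton_peaks=0, n_background_genes=0, n_clusters=60,
            n_chromosomes=8,
        )
        detected = 0
        for seed in range(5):
            data = rh.simulate_dataset(cfg, seed=seed, with_tracks=False)
            base = filter_loops(data.loops_baseline)
            dep = filter_loops(data.loops_depleted)
            classify_anchors_and_loops(base, data.peaks["vcp"])
            classify_anchors_and_loops(dep, data.peaks["vcp"])
            res = loop_class_contrast(base, dep)
            if res.p_value < 0.01 and res.median_ratio["vcp"] < res.median_ratio["control"]:
                detected += 1
        assert detected == 5


class TestLocusPartition:
    def setup_method(self):
        self.loops = [make_loop("l", 5, 0.001, a=("chr1", 0, 2000), b=("chr1", 8000, 10_000))]
        self.vcp = [Peak("chr1", 100, 300, "v")]

    def test_vcp_coincident_top_ranked_in_set_one(self):
        k27 = [Peak("chr1", 50, 350, "kA"), Peak("chr1", 8100, 8400, "kB")]
        enrich = {"kA": 10.0, "kB": 1.0}
        top, bottom = partition_loci_for_differential(
            k27, self.vcp, enrich, self.loops, top_k=1, bottom_k=1
        )
        assert [p.name for p in top] == ["kA"]
        assert [p.name for p in bottom] == ["kB"]

    def test_peak_outside_anchors_in_neither_set(self):
        k27 = [Peak("chr1", 50_000, 50_300, "far")]
        top, bottom = partition_loci_for_differential(
            k27, self.vcp, {"far": 100.0}, self.loops, top_k=5, bottom_k=5
        )
        assert top == [] and bottom == []

    def test_sets_are_disjoint(self, small_dataset):
        data = small_dataset
        retained = filter_loops(data.loops_baseline)
        enrich = {p.name: float(p.score or 0) for p in data.peaks["h3k27ac"]}
        top, bottom = partition_loci_for_differential(
            data.peaks["h3k27ac"], data.peaks["vcp"], enrich, retained,
            top_k=10, bottom_k=10,
        )
        assert not ({p.name for p in top} & {p.name for p in bottom})
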
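"""Read blocks, candidate windows, arm geometry, Dicer signature, confidence."""

import numpy as np
import pandas as pd
import pytest

from mirnome import hairpin_discovery as hd
from mirnome import rna_structure as rs
from mirnome import synthetic_data as sd
from mirnome.mapping import Alignment


def aln(start, end, strand="+", contig="c1", count=1.0, n_hits=1):
    return Alignment("r", contig, start, end, strand, n_hits, count)


class TestBuildBlocks:
    def test_overlapping_reads_merge(self):
        blocks = hd.build_blocks([aln(10, 32), aln(20, 42)])
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (10, 42)

    def test_abutting_reads_stay_separate(self):
        blocks = hd.build_blocks([aln(10, 32), aln(32, 54)])
        assert [(b.start, b.end) for b in blocks] == [(10, 32), (32, 54)]

    def test_strands_never_merge(self):
        blocks = hd.build_blocks([aln(10, 32, "+"), aln(15, 37, "-")])
        assert len(blocks) == 2

    def test_total_count_sums_members(self):
        blocks = hd.build_blocks([aln(10, 32, count=3.0), aln(20, 42, count=2.0)])
        assert blocks[0].total_count == 5.0

    def test_matches_connected_components_oracle(self, rng):
        import networkx as nx
        alns = [aln(int(s), int(s) + int(rng.integers(18, 31)))
                for s in rng.integers(0, 3000, size=400)]
        blocks = hd.build_blocks(alns)
        g = nx.Graph()
        g.add_nodes_from(range(len(alns)))
        for i, a in enumerate(alns):
            for j, b in enumerate(alns[:i]):
                if a.start < b.end and b.start < a.end:
                    g.add_edge(i, j)
        comps = sorted(
            (min(alns[i].start for i in c), max(alns[i].end for i in c))
            for c in nx.connected_components(g))
        assert sorted((b.start, b.end) for b in blocks) == comps


class TestCandidateWindows:
    GENOME = {"c1": "".join("ACGT"[c] for c in
                            np.random.default_rng(3).integers(0, 4, 2000))}

    def test_window_counts_per_size(self):
        block = hd.ReadBlock("c1", 1000, 1022, "+", [aln(1000, 1022)])
        wins = hd.candidate_windows(block, self.GENOME)
        by_size = {s: sum(1 for *_, sz in wins if sz == s) for s in (80, 100, 120)}
        assert by_size == {80: 6, 100: 8, 120: 10}
        for seq, ws, we, s in wins:
            assert ws <= 1000 and we >= 1022 and we - ws == s == len(seq)

    def test_oversized_block_yields_nothing(self):
        block = hd.ReadBlock("c1", 100, 260, "+", [aln(100, 260)])
        assert hd.candidate_windows(block, self.GENOME) == []

    def test_contig_edge_windows_discarded(self):
        block = hd.ReadBlock("c1", 5, 27, "+", [aln(5, 27)])
        wins = hd.candidate_windows(block, self.GENOME)
        assert all(ws >= 0 for _, ws, _, _ in wins)
        assert len(wins) < 24

    def test_minus_strand_reverse_complement(self):
        block = hd.ReadBlock("c1", 1000, 1022, "-", [aln(1000, 1022, "-")])
        seq, ws, we, _ = hd.candidate_windows(block, self.GENOME)[0]
        assert seq == sd.revcomp(self.GENOME["c1"][ws:we])


@pytest.fixture(scope="module")
def planted():
    """A planted hairpin embedded mid-contig, with mature/star coordinates."""
    rng = np.random.default_rng(11)
    pre, m0, m1, s0, s1 = sd._build_hairpin(rng)
    flank5 = "".join("ACGT"[c] for c in rng.integers(0, 4, 200))
    flank3 = "".join("ACGT"[c] for c in rng.integers(0, 4, 200))
    genome = {"c1": flank5 + pre + flank3}
    off = len(flank5)
    return genome, off, (off + m0, off + m1), (off + s0, off + s1), len(pre)


class TestArmAndDicer:
    def test_mature_block_on_five_prime_arm(self, planted):
        genome, off, (m0, m1), _, plen = planted
        block = hd.ReadBlock("c1", m0, m1, "+", [aln(m0, m1, count=20)])
        fr = rs.fold(genome["c1"][off:off + plen])
        assert fr.shape == "[]"
        assert hd.locate_arm(block, fr, (off, off + plen)) == "5p"

    def test_star_block_on_three_prime_arm(self, planted):
        genome, off, _, (s0, s1), plen = planted
        block = hd.ReadBlock("c1", s0, s1, "+", [aln(s0, s1, count=5)])
        fr = rs.fold(genome["c1"][off:off + plen])
        assert hd.locate_arm(block, fr, (off, off + plen)) == "3p"

    def test_loop_block_located_in_loop(self, planted):
        genome, off, _, _, plen = planted
        loop_mid = off + plen // 2
        block = hd.ReadBlock("c1", loop_mid - 4, loop_mid + 4, "+",
                             [aln(loop_mid - 4, loop_mid + 4)])
        fr = rs.fold(genome["c1"][off:off + plen])
        assert hd.locate_arm(block, fr, (off, off + plen)) == "loop"

    def test_half_arm_half_loop_is_spanning(self, planted):
        genome, off, _, _, plen = planted
        mid = off + plen // 2
        block = hd.ReadBlock("c1", mid - 16, mid + 4, "+", [aln(mid - 16, mid + 4)])
        fr = rs.fold(genome["c1"][off:off + plen])
        assert hd.locate_arm(block, fr, (off, off + plen)) == "spanning"

    def test_dicer_signature_on_clean_duplex(self, planted):
        genome, off, (m0, m1), (s0, s1), plen = planted
        mature = [aln(m0, m1, count=18), aln(m0 - 1, m1, count=2)]
        star = [aln(s0, s1, count=3)]
        block = hd.ReadBlock("c1", m0 - 1, m1, "+", mature)
        fr = rs.fold(genome["c1"][off:off + plen])
        assert hd.dicer_signature(block, star, fr, (off, off + plen)) is True

    def test_dicer_rejected_for_ragged_starts(self, planted):
        genome, off, (m0, m1), _, plen = planted
        ragged = [aln(m0 + i, m0 + i + 22, count=1.0) for i in range(-3, 4)]
        block = hd.ReadBlock("c1", m0 - 3, m1 + 3, "+", ragged)
        fr = rs.fold(genome["c1"][off:off + plen])
        assert hd.dicer_signature(block, [], fr, (off, off + plen)) is False

    def test_dicer_rejected_for_shifted_duplex(self, planted):
        genome, off, (m0, m1), (s0, s1), plen = planted
        block = hd.ReadBlock("c1", m0, m1, "+", [aln(m0, m1, count=10)])
        shifted_star = [aln(s0 + 6, s1 + 6, count=3)]
        fr = rs.fold(genome["c1"][off:off + plen])
        assert hd.dicer_signature(block, shifted_star, fr,
                                  (off, off + plen)) is False


def make_candidate(**overrides):
    fr = rs.fold("GGCGCGAUCGUAGCUAGCAUGGCAGCACACACAC"
                 "GCTGCCATGCTAGCTACGATCGCGCC")
    base = dict(contig="c1", strand="+", window_start=0, window_end=70,
                window_size=80, fold=fr, arm="5p", block_start=2, block_end=24,
                n_reads=50.0, median_read_len=22.0, start_heterogeneity=0.05,
                end_heterogeneity=0.0, gc_content=0.5, dicer_overhang=True,
                randfold_p=0.01)
    base.update(overrides)
    return hd.HairpinCandidate(**base)


class TestConfidence:
    def test_clean_candidate_is_confident(self):
        assert hd.classify_confidence(make_candidate()) == "confident"

    def test_single_read_block_non_confident(self):
        c = make_candidate(n_reads=1.0, randfold_p=None, dicer_overhang=False)
        assert hd.classify_confidence(c) == "non_confident"

    def test_marginal_randfold_without_star_is_candidate(self):
        c = make_candidate(n_reads=3.0, randfold_p=0.08, dicer_overhang=True)
        assert hd.classify_confidence(c) == "candidate"

    @pytest.mark.parametrize("overrides", [
        {"arm": "loop"}, {"arm": "spanning"},
        {"randfold_p": 0.2, "dicer_overhang": False},
    ])
    def test_rule_violations_demote(self, overrides):
        c = make_candidate(n_reads=3.0, **overrides)
        assert hd.classify_confidence(c) != "confident"

    def test_confident_requires_mirna_like_lengths(self):
        c = make_candidate(median_read_len=28.0)
        assert hd.classify_confidence(c) == "candidate"

    def test_homology_promotes_candidate(self):
        c = make_candidate(n_reads=3.0, randfold_p=0.08)
        assert hd.classify_confidence(c, has_homolog=True) == "confident"

    def test_confident_rules_reassertable_from_stored_features(self):
        th = hd.DiscoveryThresholds()
        c = make_candidate()
        assert hd.classify_confidence(c, th) == "confident"
        assert (c.fold.shape == "[]" and c.arm in ("5p", "3p")
                and c.n_reads >= th.confident_min_reads
                and c.randfold_p <= th.randfold_confident
                and c.dicer_overhang)


class TestSplitAndDedup:
    def test_known_novel_split(self):
        known = pd.DataFrame(
            [("c1", 0, 22, "+", "miRNA_known", "mir-a")],
            columns=["contig", "start", "end", "strand", "klass", "name"])
        on_known = make_candidate(block_start=0, block_end=22)
        elsewhere = make_candidate(block_start=500, block_end=522,
                                   window_start=480, window_end=560)
        out = hd.split_known_novel([on_known, elsewhere], known)
        assert [c.status for c in out] == ["known", "novel"]

    def test_antisense_candidate_stays_novel(self):
        known = pd.DataFrame(
            [("c1", 0, 22, "-", "miRNA_known", "mir-a")],
            columns=["contig", "start", "end", "strand", "klass", "name"])
        out = hd.split_known_novel([make_candidate(block_start=0, block_end=22)],
                                   known)
        assert out[0].status == "novel"

    def test_dedup_one_call_per_locus(self):
        cands = [make_candidate(window_size=s, randfold_p=p)
                 for s, p in [(80, 0.02), (100, 0.01), (120, 0.01)]]
        kept = hd.dedup_candidates(cands)
        assert len(kept) == 1
        # lowest p wins; tie broken by smallest window
        assert kept[0].randfold_p == 0.01 and kept[0].window_size == 100

    def test_dedup_keeps_distinct_loci(self):
        far = make_candidate(window_start=5000, window_end=5070,
                             block_start=5002, block_end=5024)
        kept = hd.dedup_candidates([make_candidate(), far])
        assert len(kept) == 2
        assert all(c.candidate_id for c in kept)


class TestEndToEnd:
    def test_discovery_recovers_planted_novels(self, small_run):
        res = small_run
        truth = res.truth
        novel = truth.loci_of_class("novel_hairpin")
        recovered = 0
        for _, r in novel.iterrows():
            recovered += any(
                c.strand == r["strand"] and c.status == "novel"
                and c.window_start < r["end"] and c.window_end > r["start"]
                and c.confidence in ("confident", "candidate")
                for c in res.candidates)
        assert recovered == len(novel)

    def test_no_confident_calls_on_structural_rna(self, small_run):
        res = small_run
        structural = res.truth.loci[res.truth.loci["klass"].isin(
            ["trna", "rrna", "snrna_snorna"])]
        for c in res.candidates:
            if c.confidence != "confident":
                continue
            hit = structural[(structural["start"] < c.window_end)
                             & (structural["end"] > c.window_start)]
            assert hit.empty

    def test_determinism(self, small_run, tmp_path):
        from mirnome import pipeline as pl
        from tests.conftest import small_config
        pc = pl.PipelineConfig(output_dir=str(tmp_path / "again"),
                               simulation=small_config(), seed=7,
                               write_reads=False)
        res2 = pl.run_pipeline(pc)
        first = [(c.candidate_id, c.window_start, c.confidence, c.randfold_p)
                 for c in small_run.candidates]
        second = [(c.candidate_id, c.window_start, c.confidence, c.randfold_p)
                  for c in res2.candidates]
        assert first == second
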
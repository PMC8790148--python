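import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyanophage import recruitment as rec
from cyanophage import seq_core as sq
from cyanophage import synthetic_data as syn
from cyanophage.errors import ArgumentError


@pytest.fixture(scope="module")
def target_reads(small_genome):
    """Error-free reads drawn entirely from inside target genes."""
    genome, genes = small_genome
    rng = np.random.default_rng(17)
    reads = []
    for i in range(60):
        f = genes[int(rng.integers(0, len(genes)))]
        if len(f) < 120:
            continue
        start = int(rng.integers(f.start, f.end - 120 + 1))
        seq = genome.seq[start : start + 120]
        if rng.random() < 0.5:
            seq = sq.reverse_complement(seq)
        reads.append(sq.SeqRecord(id=f"t{i:03d}", seq=seq))
    return reads


class TestPrefilter:
    def test_perfect_reads_all_recovered(self, target, target_reads):
        kept = rec.prefilter(target.proteome, target_reads)
        assert set(kept) == {r.id for r in target_reads}

    def test_unrelated_reads_all_rejected(self, target):
        for seed in range(10):
            decoy, _ = syn.generate_genome(
                syn.GenomeSpec(length=6000, gc=0.5, n_genes=4, seed=5000 + seed,
                               genome_id=f"decoy{seed}")
            )
            reads, _ = syn.simulate_metagenome(
                [(decoy, 1.0)], n_reads=30, read_len=120, error_rate=0.0,
                seed=seed,
            )
            assert rec.prefilter(target.proteome, reads) == []

    def test_empty_read_set(self, target):
        assert rec.prefilter(target.proteome, []) == []

    def test_each_id_reported_once(self, target, target_reads):
        kept = rec.prefilter(target.proteome, target_reads)
        assert len(kept) == len(set(kept))


class TestCompetitiveAssign:
    def test_empty_panel_recruits_all_candidates(self, target, target_reads):
        empty = rec.ReferencePanel(())
        recruited = rec.competitive_assign(target_reads, target, empty)
        assert {r.read_id for r in recruited} == {r.id for r in target_reads}

    def test_panel_origin_read_not_recruited(self, target, panel):
        """A read copied verbatim from a panel member's homolog gene loses the
        competition to the panel and is not recruited."""
        member = panel.entries[0]
        reads, truth = syn.simulate_metagenome(
            [(member.genome, 1.0)], n_reads=40, read_len=150, error_rate=0.0,
            seed=23, id_prefix="panelread",
        )
        candidates = [
            r for r in reads
            if r.id in set(rec.prefilter(target.proteome, reads))
        ]
        assert candidates, "panel homolog reads should pass the prefilter"
        recruited = rec.competitive_assign(candidates, target, panel)
        assert recruited == []

    def test_exact_tie_not_recruited(self, target):
        """A panel member carrying an identical copy of a target protein ties
        every read from that gene; ties are conservatively unrecruited."""
        prot = target.proteome[0]
        twin = rec.PanelEntry(
            phage_id="twin",
            proteome=(sq.SeqRecord(id="twin|orf001", seq=prot.seq,
                                   alphabet="protein"),),
            genome_len=10_000,
            group_label="TWIN",
        )
        panel = rec.ReferencePanel((twin,))
        gene = target.genes[0]
        seq = target.genome.seq[gene.start : gene.start + 120]
        read = sq.SeqRecord(id="tie_read", seq=seq)
        assert rec.competitive_assign([read], target, panel) == []

    def test_swapping_target_partitions_reads(self, target, panel):
        """With the roles of target and a panel member exchanged, no read is
        recruited by both units — the competition partitions candidates."""
        member = panel.entries[0]
        reads, _ = syn.simulate_metagenome(
            [(target.genome, 0.5), (member.genome, 0.5)], n_reads=120,
            read_len=150, error_rate=0.01, seed=41,
        )
        as_target = {
            r.read_id for r in rec.competitive_assign(
                reads, target,
                rec.ReferencePanel((member,)),
            )
        }
        member_target = rec.TargetPhage(
            member.genome, sq.find_orfs(member.genome)
        )
        target_entry = rec.PanelEntry(
            phage_id=target.phage_id,
            proteome=tuple(target.proteome),
            genome_len=len(target.genome.seq),
            group_label="TARGET",
        )
        as_member = {
            r.read_id for r in rec.competitive_assign(
                reads, member_target, rec.ReferencePanel((target_entry,)),
            )
        }
        assert not (as_target & as_member)

    def test_recruited_positions_match_truth(self, target, small_genome):
        """Recruited reads land within a read length of their true origin."""
        genome, genes = small_genome
        reads, truth = syn.simulate_metagenome(
            [(genome, 1.0)], n_reads=50, read_len=150, error_rate=0.0, seed=31
        )
        candidates = [
            r for r in reads if r.id in set(rec.prefilter(target.proteome, reads))
        ]
        recruited = rec.competitive_assign(candidates, target, rec.ReferencePanel(()))
        t = truth.set_index("read_id")
        assert recruited
        for r in recruited:
            true_start = int(t.loc[r.read_id, "start"])
            assert abs(r.genome_start - true_start) <= 150
            assert 0 <= r.genome_start < len(genome.seq)


class TestNormalize:
    def test_zero_hits_zero_abundance(self):
        assert rec.normalize(0, 42_134, 10**9).normalized == 0.0

    def test_hand_arithmetic(self):
        record = rec.normalize(100, 42_134, 10**9)
        assert record.normalized == pytest.approx(100 / 42.134, rel=1e-12)

    def test_doubling_metagenome_halves_abundance(self):
        one = rec.normalize(100, 42_134, 10**9).normalized
        two = rec.normalize(100, 42_134, 2 * 10**9).normalized
        assert two == pytest.approx(one / 2)

    @given(st.integers(1, 10**4), st.integers(1, 10**3))
    def test_scale_invariance(self, n_hits, factor):
        base = rec.normalize(n_hits, 42_134, 10**8).normalized
        scaled = rec.normalize(n_hits * factor, 42_134, 10**8 * factor).normalized
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ArgumentError):
            rec.normalize(1, 0, 10**9)
        with pytest.raises(ArgumentError):
            rec.normalize(1, 42_134, 0)


class TestGroupAbundance:
    def _panel(self):
        entries = [
            rec.PanelEntry(phage_id=p, proteome=(), genome_len=40_000, group_label=g)
            for p, g in [("a", "G1"), ("b", "G1"), ("c", "G2")]
        ]
        return rec.ReferencePanel(entries)

    def test_singleton_groups_pass_through(self):
        panel = self._panel()
        records = [rec.normalize(10, 40_000, 10**9, unit_id="c")]
        sums = rec.group_abundance(records, panel)
        assert sums["G2"] == pytest.approx(records[0].normalized)

    def test_group_sum_and_permutation_invariance(self):
        panel = self._panel()
        records = [
            rec.normalize(40, 40_000, 10**9, unit_id="a"),
            rec.normalize(100, 40_000, 10**9, unit_id="b"),
        ]
        fwd = rec.group_abundance(records, panel)
        rev = rec.group_abundance(records[::-1], panel)
        assert fwd == rev
        assert fwd["G1"] == pytest.approx(sum(r.normalized for r in records))

    def test_unknown_phage_rejected(self):
        with pytest.raises(ArgumentError):
            rec.group_abundance(
                [rec.normalize(1, 40_000, 10**9, unit_id="nope")], self._panel()
            )


class TestCoverageAndMap:
    def _read(self, i, start, end, gene):
        return rec.RecruitedRead(
            read_id=f"r{i}", metagenome_id="m1", target_gene=gene,
            genome_start=start, genome_end=end, identity=0.9, bit_margin=5.0,
        )

    def test_no_reads_zero_coverage(self, small_genome):
        _, genes = small_genome
        assert rec.gene_coverage([], genes) == 0.0

    def test_full_coverage(self, small_genome):
        _, genes = small_genome
        reads = [
            self._read(i, f.start, f.start + 60, f.orf_index)
            for i, f in enumerate(genes)
        ]
        assert rec.gene_coverage(reads, genes) == 1.0

    def test_partial_coverage_fraction(self, small_genome):
        _, genes = small_genome
        covered = genes[:13]
        reads = [
            self._read(i, f.start, f.start + 60, f.orf_index)
            for i, f in enumerate(covered)
        ]
        assert rec.gene_coverage(reads, genes) == pytest.approx(13 / 20)

    def test_map_conserves_read_count(self, small_genome):
        _, genes = small_genome
        reads = [
            self._read(i, genes[j].start, genes[j].start + 50, genes[j].orf_index)
            for i, j in enumerate([0, 0, 1, 5, 5, 5])
        ]
        map_df, tally = rec.recruitment_map(reads)
        assert len(map_df) == len(reads)
        assert tally["n_reads"].sum() == len(reads)

    def test_tallies_localized_to_hit_genes(self, small_genome):
        """Reads placed only in genes 15–19 tally nonzero exactly there."""
        _, genes = small_genome
        hot = [f for f in genes if 15 <= f.orf_index <= 19]
        reads = [
            self._read(i, f.start + 3, f.start + 90, f.orf_index)
            for i, f in enumerate(hot * 3)
        ]
        _, tally = rec.recruitment_map(reads)
        assert set(tally["target_gene"]) == {f.orf_index for f in hot}

    def test_empty_map(self):
        map_df, tally = rec.recruitment_map([])
        assert map_df.empty and tally.empty
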
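from dataclasses import replace

import numpy as np
import pytest

from dmgfinder.align_engine import AlignParams, dp_align_oracle, hit_passes
from dmgfinder.config import BadgeConfig
from dmgfinder.dmg_core import (
    DmgFamily,
    dc_filter,
    distribution_mode,
    group_into_families,
    mut_level_filter,
    occurrence_filter,
    run_pipeline,
    short_hit_filter,
    step1_orf_filter,
    step2_genome_filter,
    write_outputs,
)
from dmgfinder.seq_io import GroupData, OrfRecord, SequenceRecord
from dmgfinder.synthgen import mutate_sequence


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def orf(orf_id, seq, strain="s1", contig="c1", start=1, stop=None, **kw):
    return OrfRecord(orf_id=orf_id, seq=seq, strain=strain, contig=contig,
                     start=start, stop=stop or start + len(seq) - 1, **kw)


class TestStep1:
    def test_identical_orf_discarded(self, default_cfg):
        gene = random_dna(900, 1)
        a = [orf("a1", gene, strain="A1")]
        b = [orf("b1", gene, strain="B1")]
        assert step1_orf_filter(a, b, default_cfg) == []

    def test_unrelated_orf_retained(self, default_cfg):
        a = [orf("a1", random_dna(900, 2), strain="A1")]
        b = [orf("b1", random_dna(900, 3), strain="B1")]
        assert [o.orf_id for o in step1_orf_filter(a, b, default_cfg)] == ["a1"]

    def test_empty_target_group_rejected(self, default_cfg):
        with pytest.raises(ValueError, match="nothing to compare"):
            step1_orf_filter([], [orf("b1", "ACGT")], default_cfg)

    def test_planted_90pct_depends_on_cut(self):
        """A 90%-identity B homolog: retained at cut 95, discarded at 85."""
        gene = random_dna(1000, 4)
        homolog = mutate_sequence(gene, 0.90, indel_fraction=0.1, seed=5)
        verified = dp_align_oracle(gene, homolog, AlignParams(), both_strands=False)
        assert 89.0 <= verified.perc_identity <= 91.0
        a = [orf("a1", gene, strain="A1")]
        b = [orf("b1", homolog, strain="B1")]
        keep95 = step1_orf_filter(a, b, BadgeConfig(megablast_perc_identity_cut=95))
        assert [o.orf_id for o in keep95] == ["a1"]
        cfg85 = BadgeConfig(megablast_perc_identity_cut=85,
                            query_cov_cut=85, subject_cov_cut=85,
                            dc_perc_identity_cut=80, dc_query_cov_cut=60)
        assert step1_orf_filter(a, b, cfg85) == []


class TestStep2:
    def test_embedded_unannotated_gene_discarded(self, default_cfg):
        """A gene present verbatim in a background contig (but absent from
        its ORF calls) dies at the genome filter."""
        gene = random_dna(800, 6)
        contig = SequenceRecord(
            id="B1|c1", seq=random_dna(2000, 7) + gene + random_dna(2000, 8)
        )
        out = step2_genome_filter([orf("a1", gene, strain="A1")], [contig], default_cfg)
        assert out == []

    def test_absent_gene_retained(self, default_cfg):
        contig = SequenceRecord(id="B1|c1", seq=random_dna(5000, 9))
        cands = [orf("a1", random_dna(800, 10), strain="A1")]
        assert step2_genome_filter(cands, [contig], default_cfg) == cands

    def test_frameshifted_copy_still_discarded(self, default_cfg):
        """A 1 bp deletion at 30% of length barely dents full-span identity,
        so the genome filter still catches the copy."""
        gene = random_dna(900, 11)
        cut = int(0.3 * len(gene))
        shifted = gene[:cut] + gene[cut + 1:]
        oracle = dp_align_oracle(gene, shifted, AlignParams(), both_strands=False)
        params = AlignParams(perc_identity_cut=95, query_cov_cut=95)
        assert hit_passes(oracle, params)  # expected fate decided by the oracle
        contig = SequenceRecord(
            id="B1|c1", seq=random_dna(1000, 12) + shifted + random_dna(1000, 13)
        )
        assert step2_genome_filter([orf("a1", gene, strain="A1")], [contig],
                                   default_cfg) == []


class TestFamilies:
    def test_shared_gene_one_family_full_occurrence(self, default_cfg):
        gene = random_dna(700, 14)
        cands = [orf("g", gene, strain="A1"), orf("g", gene, strain="A2")]
        fams = group_into_families(cands, default_cfg, ["A1", "A2"])
        assert len(fams) == 1
        assert fams[0].percent_occurrence == 100.0
        assert fams[0].per_genome_frequency == {"A1": 1, "A2": 1}
        assert fams[0].dmg_id == "DMG_1"

    def test_partial_occurrence(self, default_cfg):
        fams = group_into_families(
            [orf("g", random_dna(700, 15), strain="A1")], default_cfg, ["A1", "A2"]
        )
        assert fams[0].percent_occurrence == 50.0

    def test_multicopy_listed_with_ascending_coordinates(self, default_cfg):
        gene = random_dna(600, 16)
        cands = [
            orf("g_c2", gene, strain="A1", contig="p1", start=5000),
            orf("g_c1", gene, strain="A1", contig="p1", start=100),
            orf("g", gene, strain="A2", contig="p1", start=300),
        ]
        (fam,) = group_into_families(cands, default_cfg, ["A1", "A2"])
        assert fam.per_genome_frequency == {"A1": 2, "A2": 1}
        a1_starts = [m.start for m in fam.members if m.strain == "A1"]
        assert a1_starts == sorted(a1_starts)

    def test_distinct_genes_stay_separate(self, default_cfg):
        cands = [
            orf("g1", random_dna(700, 17), strain="A1"),
            orf("g2", random_dna(700, 18), strain="A1"),
        ]
        assert len(group_into_families(cands, default_cfg, ["A1"])) == 2


def _fam(occurrence, dmg_id="DMG_1"):
    member = orf("m", "ATGAAATTTGGG", strain="A1")
    return DmgFamily(
        dmg_id=dmg_id, members=[member], percent_occurrence=occurrence,
        per_genome_frequency={"A1": 1}, representative=member,
    )


class TestOccurrenceFilter:
    def test_boundary_inclusive(self):
        fams = [_fam(50.0)]
        assert occurrence_filter(fams, 1.0) == []
        assert occurrence_filter(fams, 0.5) == fams

    def test_one_genome_of_fifty(self):
        """min_occurrence 0.02 on 50 genomes keeps even singletons."""
        fams = [_fam(100.0 * k / 50, dmg_id=f"DMG_{k}") for k in range(1, 51)]
        assert occurrence_filter(fams, 0.02) == fams

    def test_invalid_min_occurrence(self):
        with pytest.raises(ValueError):
            occurrence_filter([], 0.0)


class TestDcFilter:
    def _family_for(self, gene):
        member = orf("g", gene, strain="A1")
        return DmgFamily(
            dmg_id="DMG_1", members=[member], percent_occurrence=100.0,
            per_genome_frequency={"A1": 1}, representative=member,
        )

    def test_low_identity_homolog_removed_then_annotated(self):
        gene = random_dna(1000, 19)
        homolog = mutate_sequence(gene, 0.85, indel_fraction=0.1, seed=20)
        oracle = dp_align_oracle(gene, homolog, AlignParams(), both_strands=False)
        assert 84.0 <= oracle.perc_identity <= 86.0
        contig = SequenceRecord(
            id="B1|c1", seq=random_dna(1500, 21) + homolog + random_dna(1500, 22)
        )
        cfg = BadgeConfig(dc_perc_identity_cut=80, dc_query_cov_cut=60)
        survivors, _ = dc_filter([self._family_for(gene)], [contig], cfg)
        assert survivors == []
        # raising the dc identity cut above the planted identity keeps the
        # family but flags the residual hit
        cfg_strict = BadgeConfig(dc_perc_identity_cut=90, dc_query_cov_cut=60)
        survivors, residual = dc_filter([self._family_for(gene)], [contig], cfg_strict)
        assert len(survivors) == 1
        assert survivors[0].dc_blast_hit == "yes"
        assert residual

    def test_clean_family_passes_with_no_flag(self, default_cfg):
        contig = SequenceRecord(id="B1|c1", seq=random_dna(4000, 23))
        survivors, residual = dc_filter(
            [self._family_for(random_dna(1000, 24))], [contig], default_cfg
        )
        assert survivors[0].dc_blast_hit == "no"
        assert residual == []

    def test_disabled_filter_is_identity(self):
        cfg = BadgeConfig(enable_dc_filter=False)
        fams = [self._family_for(random_dna(500, 25))]
        survivors, _ = dc_filter(fams, [], cfg)
        assert survivors == fams


class TestShortHitFilter:
    def _family_for(self, gene):
        member = orf("g", gene, strain="A1")
        return DmgFamily(
            dmg_id="DMG_1", members=[member], percent_occurrence=100.0,
            per_genome_frequency={"A1": 1}, representative=member,
        )

    def test_long_planted_segment_removes_family(self, default_cfg):
        gene = random_dna(900, 26)
        seg = gene[375:525]  # 150 bp exact background copy
        contig = SequenceRecord(
            id="B1|c1", seq=random_dna(2000, 27) + seg + random_dna(2000, 28)
        )
        survivors, _ = short_hit_filter([self._family_for(gene)], [contig], default_cfg)
        assert survivors == []

    def test_short_segment_recorded_as_max_blastn(self, default_cfg):
        gene = random_dna(900, 29)
        seg = gene[400:480]  # 80 bp
        contig = SequenceRecord(
            id="B1|c1", seq=random_dna(2000, 30) + seg + random_dna(2000, 31)
        )
        survivors, residual = short_hit_filter(
            [self._family_for(gene)], [contig], default_cfg
        )
        assert len(survivors) == 1
        assert survivors[0].max_blastn == pytest.approx(80, abs=5)
        assert residual

    def test_no_hits_means_zero(self, default_cfg):
        contig = SequenceRecord(id="B1|c1", seq=random_dna(3000, 32))
        survivors, _ = short_hit_filter(
            [self._family_for(random_dna(900, 33))], [contig], default_cfg
        )
        assert survivors[0].max_blastn == 0


class TestMutLevel:
    def _setup(self, b_variant):
        gene = random_dna(900, 34)
        a_orfs = [orf("g", gene, strain="A1"), orf("g", gene, strain="A2")]
        b_orfs = [orf("g", b_variant, strain="B1")]
        b_genomes = [SequenceRecord(id="B1|c1", seq=random_dna(1000, 35) + b_variant)]
        return gene, a_orfs, b_orfs, b_genomes

    def test_single_substitution_reported(self):
        gene = random_dna(900, 34)
        variant = gene[:450] + ("A" if gene[450] != "A" else "C") + gene[451:]
        _, a_orfs, b_orfs, b_genomes = self._setup(variant)
        cfg = BadgeConfig(mode="mut_dna")
        fams = mut_level_filter(a_orfs, b_orfs, b_genomes, cfg, ["A1", "A2"])
        assert len(fams) == 1
        assert fams[0].percent_occurrence == 100.0

    def test_identical_everywhere_not_reported(self):
        gene, a_orfs, b_orfs, b_genomes = self._setup(random_dna(900, 34))
        cfg = BadgeConfig(mode="mut_dna")
        assert mut_level_filter(a_orfs, b_orfs, b_genomes, cfg, ["A1", "A2"]) == []

    def test_within_group_variation_not_reported(self):
        gene = random_dna(900, 34)
        variant = gene[:100] + ("G" if gene[100] != "G" else "T") + gene[101:]
        a_orfs = [orf("g", gene, strain="A1"), orf("g", variant, strain="A2")]
        b_orfs = [orf("g", gene[:600] + "A" * 4 + gene[604:], strain="B1")]
        cfg = BadgeConfig(mode="mut_dna")
        assert mut_level_filter(a_orfs, b_orfs, [], cfg, ["A1", "A2"]) == []


class TestDistributionMode:
    def _group(self):
        shared = random_dna(800, 36)
        unique = random_dna(800, 37)
        group = GroupData(name="all")
        for i, strain in enumerate(["g1", "g2", "g3"]):
            contig_seq = random_dna(500, 38 + i) + shared + random_dna(500, 41 + i)
            orfs = [orf("shared", shared, strain=strain, contig="c1", start=501)]
            if i == 0:
                contig_seq += unique
                orfs.append(orf("uniq", unique, strain=strain, contig="c1",
                                start=len(contig_seq) - len(unique) + 1))
            group.genomes[strain] = [SequenceRecord(id="c1", seq=contig_seq)]
            group.orfs[strain] = orfs
        return group

    def test_presence_and_copy_matrices(self):
        dist, freq, outputs = distribution_mode(self._group())
        assert dist.shape == (2, 3)
        rows = {tuple(dist.loc[i]) for i in dist.index}
        assert rows == {(1, 1, 1), (1, 0, 0)}
        assert (freq.to_numpy() == dist.to_numpy()).all()

    def test_dummy_produces_no_passing_hits(self):
        _, _, outputs = distribution_mode(self._group())
        counts = dict(outputs.step_counts)
        assert counts["step1_orf_filter"] == counts["step2_genome_filter"] == 4

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValueError):
            distribution_mode(GroupData(name="empty"))


class TestRunPipeline:
    def test_ground_truth_recovered(self, small_fixture, default_cfg):
        spec, group_a, group_b, truth = small_fixture
        out = run_pipeline(group_a, group_b, default_cfg)
        found = {m.orf_id.rsplit("_c", 1)[0] for f in out.families for m in f.members}
        assert found == truth.expected_family_genes()
        counts = [c for _, c in out.step_counts]
        assert counts == sorted(counts, reverse=True)

    def test_lower_occurrence_recovers_partial_gene(self, small_fixture):
        spec, group_a, group_b, truth = small_fixture
        cfg = BadgeConfig(min_occurrence=0.5)
        out = run_pipeline(group_a, group_b, cfg)
        found = {m.orf_id.rsplit("_c", 1)[0] for f in out.families for m in f.members}
        assert found == truth.expected_family_genes(
            min_occurrence=0.5, partial_fraction=spec.partial_fraction
        )

    def test_self_comparison_yields_nothing(self, small_fixture, default_cfg):
        _, group_a, _, _ = small_fixture
        clone = GroupData(name="clone", genomes=dict(group_a.genomes),
                          orfs=dict(group_a.orfs))
        out = run_pipeline(group_a, clone, default_cfg)
        assert out.families == []
        assert [c for _, c in out.step_counts][:1] == [0]

    def test_output_sequences_are_verbatim_inputs(self, small_fixture, default_cfg):
        _, group_a, group_b, _ = small_fixture
        input_seqs = {(o.strain, o.orf_id): o.seq for o in group_a.all_orfs()}
        out = run_pipeline(group_a, group_b, default_cfg)
        for fam in out.families:
            for m in fam.members:
                assert m.seq == input_seqs[(m.strain, m.orf_id)]

    def test_occurrence_values_quantised(self, small_fixture, default_cfg):
        spec, group_a, group_b, _ = small_fixture
        out = run_pipeline(group_a, group_b, default_cfg)
        allowed = {100.0 * k / spec.n_a for k in range(1, spec.n_a + 1)}
        for fam in out.families:
            assert fam.percent_occurrence in allowed
            assert fam.percent_occurrence >= 100.0 * default_cfg.min_occurrence - 1e-9


class TestProteinMode:
    def test_protein_mode_finds_dna_mode_families(self, small_fixture):
        """With equal cutoffs every DNA-level family of cleanly translating
        genes is also found at the protein level."""
        _, group_a, group_b, _ = small_fixture
        dna_out = run_pipeline(group_a, group_b, BadgeConfig())
        prot_out = run_pipeline(group_a, group_b, BadgeConfig(mode="protein"))
        dna_genes = {m.orf_id for f in dna_out.families for m in f.members}
        prot_genes = {m.orf_id for f in prot_out.families for m in f.members}
        assert dna_genes <= prot_genes


class TestWriteOutputs:
    def test_files_written_and_deterministic(self, tmp_path, small_fixture,
                                             default_cfg):
        _, group_a, group_b, _ = small_fixture
        out = run_pipeline(group_a, group_b, default_cfg)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_outputs(out, d1, default_cfg, group_b=group_b)
        write_outputs(out, d2, default_cfg, group_b=group_b)
        names = sorted(p.name for p in d1.iterdir())
        assert {"DMG_representatives.fasta", "DMG_table.tsv", "settings.txt",
                "DMG_distribution.tsv", "DMG_frequency.tsv", "step_counts.log",
                "residual_hits.txt", "DMG_fastas"} <= set(names)
        fam_files = sorted((d1 / "DMG_fastas").iterdir())
        assert len(fam_files) == len(out.families)
        for p in sorted(d1.rglob("*")):
            if p.is_file():
                assert p.read_bytes() == (d2 / p.relative_to(d1)).read_bytes()

    def test_representative_count_matches_families(self, tmp_path,
                                                   small_fixture, default_cfg):
        from dmgfinder.seq_io import read_fasta

        _, group_a, group_b, _ = small_fixture
        out = run_pipeline(group_a, group_b, default_cfg)
        write_outputs(out, tmp_path / "out", default_cfg)
        reps = read_fasta(tmp_path / "out" / "DMG_representatives.fasta")
        assert [r.id for r in reps] == [f.dmg_id for f in out.families]
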
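"""Profiles, E-value calibration, iterative search and genomic rescue."""

import math

import numpy as np
import pytest

from pepfam.align import progressive_msa
from pepfam.profilesearch import (EvalueModel, build_profile, calibrate_evalue,
                                  dna_rescue, find_orfs, iterative_search,
                                  merge_candidates, profile_search)
from pepfam.seqio import (IntervalAnnotation, Msa, SequenceRecord,
                          reverse_complement)


class TestBuildProfile:
    def test_hand_arithmetic_pseudocounts(self):
        # column counts {A:3, C:1}, alpha=1, uniform background 0.05
        msa = Msa([("a", "A"), ("b", "A"), ("c", "A"), ("d", "C")])
        prof = build_profile(msa, alpha=1.0)
        p_a = prof.probs[0][0]  # index 0 is A
        assert p_a == pytest.approx((3 + 0.05) / 5)
        assert prof.log_odds[0][0] == pytest.approx(math.log2(p_a / 0.05))

    def test_uniform_column_zero_log_odds(self):
        msa = Msa([(f"s{i}", c) for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")])
        prof = build_profile(msa, alpha=1.0)
        assert np.allclose(prof.log_odds[0][:20], 0.0)

    def test_single_sequence_small_alpha_limit(self):
        msa = Msa([("a", "MK")])
        prof = build_profile(msa, alpha=1e-9)
        assert prof.consensus == "MK"
        m_idx = "ACDEFGHIKLMNPQRSTVWYX".index("M")
        assert prof.log_odds[0][m_idx] == pytest.approx(math.log2(1 / 0.05), rel=1e-6)

    def test_low_occupancy_columns_dropped(self):
        msa = Msa([("a", "M-"), ("b", "M-"), ("c", "MK"), ("d", "M-")])
        prof = build_profile(msa)  # col 1 occupancy 25% < 50%
        assert prof.length == 1 and prof.source_columns == [0]

    def test_all_gap_error(self):
        with pytest.raises(ValueError):
            build_profile(Msa([("a", "--"), ("b", "--")]))


class TestEvalueModel:
    def test_gumbel_identity_at_mu(self):
        model = EvalueModel(mu=5.0, lam=0.7, n_database=100)
        assert model.pvalue(5.0) == pytest.approx(1 - math.exp(-1))

    def test_monotone_and_linear_in_n(self):
        model = EvalueModel(mu=5.0, lam=0.7, n_database=100)
        scores = np.linspace(0, 40, 50)
        es = [model.evalue(s) for s in scores]
        assert all(a >= b for a, b in zip(es, es[1:]))
        assert model.evalue(12.0, n_database=50) * 2 == \
            pytest.approx(model.evalue(12.0, n_database=100))
        assert EvalueModel(mu=0, lam=0.5, n_database=10).evalue(200.0) >= 0

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            EvalueModel(mu=0.0, lam=0.0, n_database=10)


class TestCalibration:
    def test_deterministic_under_seed(self, family, genome_data):
        msa = progressive_msa(family.members[:3])
        prof = build_profile(msa)
        m1 = calibrate_evalue(prof, genome_data.proteome, rng_seed=7)
        m2 = calibrate_evalue(prof, genome_data.proteome, rng_seed=7)
        assert (m1.mu, m1.lam) == (m2.mu, m2.lam)

    def test_degenerate_null_raises(self):
        msa = Msa([("a", "MK")])
        prof = build_profile(msa)
        db = [SequenceRecord(id=f"t{i}", residues="W") for i in range(3)]
        with pytest.raises(ValueError, match="degenerate|sigma"):
            calibrate_evalue(prof, db, n_shuffles=100, rng_seed=0)

    def test_too_few_shuffles_rejected(self, family):
        prof = build_profile(progressive_msa(family.members[:2]))
        with pytest.raises(ValueError):
            calibrate_evalue(prof, family.members, n_shuffles=10)

    def test_null_hit_count_calibrated(self, family, genome_data):
        """~1 null target at E <= 1 out of N, binomial error band."""
        msa = progressive_msa(family.members[:3])
        prof = build_profile(msa)
        rng = np.random.default_rng(42)
        nulls = []
        for k in range(500):
            t = genome_data.proteome[k % len(genome_data.proteome)]
            chars = np.array(list(t.residues))
            rng.shuffle(chars)
            nulls.append(SequenceRecord(id=f"null{k}", residues="".join(chars)))
        model = calibrate_evalue(prof, nulls[:250], n_shuffles=200, rng_seed=1)
        table = profile_search(prof, nulls, model, max_evalue=1.0)
        assert len(table) <= 3

    def test_tail_exceedance_near_nominal(self, family, genome_data):
        """Fitted tail within 2x of the empirical 99th percentile rate."""
        prof = build_profile(progressive_msa(family.members[:3]))
        model = calibrate_evalue(prof, genome_data.proteome, n_shuffles=1000,
                                 rng_seed=3)
        from pepfam.profilesearch import score_profile_target
        rng = np.random.default_rng(9)
        scores = []
        for k in range(1000):
            t = genome_data.proteome[k % len(genome_data.proteome)]
            chars = np.array(list(t.residues))
            rng.shuffle(chars)
            scores.append(score_profile_target(prof, "".join(chars))[0])
        q99 = float(np.quantile(scores, 0.99))
        fitted = model.pvalue(q99)
        assert 0.005 <= fitted <= 0.02 * 2


class TestProfileSearch:
    def test_self_profile_top_hit(self, family):
        rec = family.members[0]
        prof = build_profile(Msa([(rec.id, rec.residues)]))
        db = list(family.members) + list(family.decoys[:20])
        table = profile_search(prof, db, calibration_seed=1)
        assert table.iloc[0].target == rec.id

    def test_planted_family_found_no_decoys(self, family, genome_data):
        prof = build_profile(progressive_msa(family.members[:3]))
        model = calibrate_evalue(prof, genome_data.proteome, rng_seed=0)
        table = profile_search(prof, genome_data.proteome, model,
                               max_evalue=1e-5)
        fam_in_db = {r.id for r in genome_data.proteome if "fam" in r.id}
        assert fam_in_db <= set(table.target)
        assert not any("decoy" in t for t in table.target)

    def test_uncalibrated_disabled_raises(self, family):
        prof = build_profile(progressive_msa(family.members[:2]))
        with pytest.raises(ValueError):
            profile_search(prof, family.members, model=None,
                           calibration_seed=None)


class TestIterativeSearch:
    def test_round1_equals_pairwise(self, family, genome_data):
        from pepfam.align import all_vs_seed_search
        table, _, included = iterative_search(
            [family.ancestor], genome_data.proteome, rounds=1)
        pairwise = all_vs_seed_search(genome_data.proteome, [family.ancestor])
        assert set(table.target) == set(pairwise.subject)

    def test_fixpoint_and_monotone_growth(self, family, genome_data):
        """The profile rounds converge: extra rounds add nothing, and the
        included set grows monotonically with the round budget."""
        runs = {
            r: iterative_search([family.ancestor], genome_data.proteome,
                                rounds=r, rng_seed=2)[2]
            for r in (1, 3, 5)
        }
        ids = {r: {x.id for x in inc} for r, inc in runs.items()}
        assert ids[1] <= ids[3]
        assert ids[3] == ids[5]  # converged before the round budget

    def test_divergent_member_gained_by_iteration(self):
        """A diverged member missed by pairwise round 1 is recruited once
        the profile is built from the easy members."""
        from pepfam.synthdata import FamilySpec, generate_family
        fam = generate_family(FamilySpec(substitution_prob=0.35, rng_seed=7,
                                         n_species=6, members_per_species=3,
                                         decoys_per_species=10))
        db = fam.members + fam.decoys
        # a stringent pairwise gate misses the most diverged members;
        # the profile's E-value inclusion is what rescues them
        kwargs = dict(min_pct=72.0, min_score=150.0, rng_seed=7)
        _, _, inc1 = iterative_search([fam.ancestor], db, rounds=1, **kwargs)
        _, _, inc5 = iterative_search([fam.ancestor], db, rounds=5, **kwargs)
        fam_ids = {m.id for m in fam.members}
        found1 = {r.id for r in inc1} & fam_ids
        found5 = {r.id for r in inc5} & fam_ids
        assert found1 < found5  # iteration strictly gains members


class TestDnaRescue:
    def test_orf_extraction_on_known_gene(self, family, genome_data):
        row = genome_data.truth.iloc[0]
        genome = genome_data.genomes[row.species]
        orfs = list(find_orfs(genome, min_aa=25, max_aa=400))
        assert any(o[1] == row.start and o[2] == row.end and o[3] == row.strand
                   for o in orfs)

    def test_fully_annotated_genome_rescues_nothing(self, family):
        from pepfam.synthdata import FamilySpec, generate_family, generate_genomes
        fam = generate_family(FamilySpec(fraction_unannotated=0.0, rng_seed=5,
                                         n_species=2, decoys_per_species=2))
        gen = generate_genomes(fam)
        prof = build_profile(progressive_msa(fam.members[:3]))
        table, rescued = dna_rescue(list(gen.genomes.values()),
                                    gen.annotations, prof, rng_seed=1)
        assert rescued == [] and table.empty

    def test_unannotated_members_rescued_exactly(self, family, genome_data):
        prof = build_profile(progressive_msa(family.members[:3]))
        table, rescued = dna_rescue(list(genome_data.genomes.values()),
                                    genome_data.annotations, prof, rng_seed=1)
        unann = genome_data.truth[~genome_data.truth["annotated"]]
        by_id = {m.id: m for m in family.members}
        assert len(rescued) == len(unann)
        truth_seqs = {by_id[r.id].residues for r in unann.itertuples()}
        assert {r.residues for r in rescued} == truth_seqs
        for r in unann.itertuples():
            match = table[(table.species == r.species)
                          & (table.t_start == r.start) & (table.t_end == r.end)
                          & (table.strand == r.strand)]
            assert len(match) == 1

    def test_strand_symmetry(self, family, genome_data):
        """Reverse-complementing the genome (and flipping annotations)
        rescues the identical protein set."""
        prof = build_profile(progressive_msa(family.members[:3]))
        genomes = list(genome_data.genomes.values())[:2]
        keep_ids = {g.id for g in genomes}
        anns = [a for a in genome_data.annotations if a.seq_id in keep_ids]
        _, rescued = dna_rescue(genomes, anns, prof, rng_seed=1)
        flipped_genomes, flipped_anns = [], []
        for g in genomes:
            L = len(g.residues)
            flipped_genomes.append(SequenceRecord(
                id=g.id, residues=reverse_complement(g.residues),
                species=g.species, moltype="dna"))
            for a in anns:
                if a.seq_id == g.id:
                    flipped_anns.append(IntervalAnnotation(
                        seq_id=a.seq_id, start=L - a.end + 1, end=L - a.start + 1,
                        strand="-" if a.strand == "+" else "+",
                        feature=a.feature))
        _, rescued_flipped = dna_rescue(flipped_genomes, flipped_anns, prof,
                                        rng_seed=1)
        assert {r.residues for r in rescued} == {r.residues for r in rescued_flipped}

    def test_missing_annotations_warns_not_fails(self, family, genome_data,
                                                 caplog):
        prof = build_profile(progressive_msa(family.members[:3]))
        genomes = list(genome_data.genomes.values())[:1]
        with caplog.at_level("WARNING"):
            table, rescued = dna_rescue(genomes, [], prof, rng_seed=1)
        assert "annotation" in caplog.text
        # without the mask, annotated genes are also "rescued"
        n_genes_here = (genome_data.truth.genome_id == genomes[0].id).sum()
        assert len(rescued) == n_genes_here


class TestMerge:
    def test_disjoint_union_and_dedup(self):
        a = SequenceRecord(id="a", residues="MKV", species="s1")
        b = SequenceRecord(id="b", residues="MKW", species="s1")
        dup = SequenceRecord(id="a_dna", residues="MKV", species="s1",
                             source="denovo")
        merged = merge_candidates([a], [b])
        assert len(merged) == 2 and merged.stage == "relaxed"
        merged = merge_candidates([a], [dup])
        assert len(merged) == 1
        assert merged.members[0].source == "annotated"
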
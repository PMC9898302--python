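import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from miredit.retarget import (
    SeedMatchSite, apply_edit, fuzzy_cmeans, predict_targets,
    prepare_profiles, scan_utr, shortlist_by_pattern, site_motifs,
    sites_by_gene, target_delta,
)
from miredit.synthetic_data import simulate_expression_matrix, simulate_utrs
from oracles import oracle_scan


class TestApplyEdit:
    def test_position3_example(self):
        edit = apply_edit("UUACGCCUAGGCUAACCUGAAU", 3)
        assert edit.edited == "UUGCGCCUAGGCUAACCUGAAU"
        assert edit.canonical_seed == "UACGCCU"
        assert edit.edited_seed == "UGCGCCU"

    def test_wrong_base_rejected(self):
        seq = "UUACGCCUAGGCUAACCUGAAU"
        assert seq[4] == "G"
        with pytest.raises(ValueError, match="G"):
            apply_edit(seq, 5)

    def test_involution(self):
        edit = apply_edit("UUACGCCUAGGCUAACCUGAAU", 3)
        back = apply_edit(edit.edited, 3, from_base="G", to_base="A")
        assert back.edited == edit.canonical

    def test_changes_exactly_one_base(self):
        edit = apply_edit("UAAAAAAAAAAAAAAAAAAAAA", 9)
        diffs = [i for i, (a, b) in enumerate(zip(edit.canonical, edit.edited))
                 if a != b]
        assert diffs == [8]

    def test_seed_unchanged_for_non_seed_edit(self):
        edit = apply_edit("UAAAAAAAAAAAAAAAAAAAAA", 12)
        assert edit.canonical_seed == edit.edited_seed

    @pytest.mark.parametrize("pos", [0, 23])
    def test_out_of_range_position(self, pos):
        with pytest.raises(ValueError):
            apply_edit("UUACGCCUAGGCUAACCUGAAU", pos)


class TestScanUtr:
    SEED = "UACGCCU"

    def test_planted_8mer_found(self):
        motif = site_motifs(self.SEED)["8mer"]
        utr = "C" * 30 + motif + "C" * 30
        sites = scan_utr(self.SEED, utr)
        assert {(s.start, s.site_type) for s in sites} >= {(30, "8mer")}

    def test_empty_utr(self):
        assert scan_utr(self.SEED, "") == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            scan_utr(self.SEED, "ACGTX")

    def test_n_never_matches(self):
        motif = site_motifs(self.SEED)["6mer"]
        broken = motif[:2] + "N" + motif[3:]
        assert scan_utr(self.SEED, "CC" + broken + "CC") == []

    def test_full_mature_sequence_accepted(self):
        mature = "UUACGCCUAGGCUAACCUGAAU"
        motif = site_motifs(self.SEED)["7mer-m8"]
        utr = "G" * 10 + motif + "G" * 10
        sites = scan_utr(mature, utr)
        assert any(s.site_type == "7mer-m8" and s.start == 10 for s in sites)

    @given(utr=st.text(alphabet="ACGT", min_size=0, max_size=120),
           seed=st.text(alphabet="ACGU", min_size=7, max_size=7))
    @settings(max_examples=80, deadline=None)
    def test_matches_window_oracle(self, utr, seed):
        got = [(s.start, s.site_type) for s in scan_utr(seed, utr)]
        assert got == oracle_scan(seed.replace("U", "T"), utr)

    def test_oracle_equivalence_on_random_utrs_with_plants(self):
        rng = np.random.default_rng(11)
        motifs = list(site_motifs(self.SEED).values())
        for _ in range(40):
            utr = "".join(rng.choice(list("ACGT"), size=300))
            for _k in range(3):  # splice in motifs to guarantee hits
                m = motifs[rng.integers(0, len(motifs))]
                p = int(rng.integers(0, 280))
                utr = utr[:p] + m + utr[p + len(m):]
            got = [(s.start, s.site_type) for s in scan_utr(self.SEED, utr)]
            assert got == oracle_scan(self.SEED.replace("U", "T"), utr)


class TestTargetDelta:
    def _site(self, gene, t="8mer", form="canonical", start=0):
        return SeedMatchSite(gene, start, t, form)

    def test_canonical_only_is_lost(self):
        delta = target_delta({"g1": [self._site("g1")]}, {})
        assert delta.lost == ["g1"] and delta.gained == [] and delta.shared == []

    def test_both_forms_shared_only(self):
        delta = target_delta(
            {"g1": [self._site("g1")]},
            {"g1": [self._site("g1", form="edited")]},
        )
        assert delta.shared == ["g1"]
        assert delta.lost == [] and delta.gained == []

    def test_partition_disjoint_and_exhaustive(self):
        canon = {f"c{i}": [self._site(f"c{i}")] for i in range(4)}
        edited = {f"e{i}": [self._site(f"e{i}", form="edited")] for i in range(3)}
        edited["c0"] = [self._site("c0", form="edited")]
        delta = target_delta(canon, edited)
        sets = [set(delta.lost), set(delta.gained), set(delta.shared)]
        assert sets[0] & sets[1] == set()
        assert sets[0] & sets[2] == set()
        assert sets[1] & sets[2] == set()
        assert set.union(*sets) == set(canon) | set(edited)

    def test_ranking_by_site_type_priority(self):
        canon = {
            "weak": [self._site("weak", "6mer")],
            "strong": [self._site("strong", "8mer")],
        }
        delta = target_delta(canon, {})
        assert delta.lost == ["strong", "weak"]

    def test_recovery_from_simulated_utrs(self):
        edit = apply_edit("UUACGCCUAGGCUAACCUGAAU", 3, mirna_id="mirX")
        planted = {f"lost_{i}": ("canonical", "8mer") for i in range(5)}
        planted.update({f"gain_{i}": ("edited", "7mer-m8") for i in range(5)})
        sim = simulate_utrs(12, edit.canonical_seed, edit.edited_seed,
                            planted, rng_seed=21)
        frame = predict_targets(edit, sim.sequences)
        delta = target_delta(sites_by_gene(frame, "canonical"),
                             sites_by_gene(frame, "edited"))
        assert sorted(delta.lost) == [f"lost_{i}" for i in range(5)]
        assert sorted(delta.gained) == [f"gain_{i}" for i in range(5)]
        assert delta.shared == []


class TestFuzzyCmeans:
    def _profiles(self, design, genes=300, clusters=3, seed=5):
        sim = simulate_expression_matrix(genes, design, clusters, rng_seed=seed)
        profiles = prepare_profiles(sim.matrix, sim.sample_stages,
                                    list(design.stages))
        return sim, profiles

    def test_two_separated_genes(self):
        profiles = pd.DataFrame([[1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]],
                                index=["g1", "g2"], columns=list("abc"))
        fc = fuzzy_cmeans(profiles, c=2, m=2.0, rng_seed=0)
        for gene in ("g1", "g2"):
            _, grade = fc.dominant_cluster(gene)
            assert grade > 0.99

    def test_membership_rows_sum_to_one(self, four_stage_design):
        _, profiles = self._profiles(four_stage_design, genes=60)
        fc = fuzzy_cmeans(profiles, c=3, rng_seed=1)
        assert np.allclose(fc.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_nonincreasing(self, four_stage_design):
        _, profiles = self._profiles(four_stage_design, genes=90)
        fc = fuzzy_cmeans(profiles, c=3, rng_seed=2)
        hist = fc.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_label_recovery_300_genes(self, four_stage_design):
        from itertools import permutations

        sim, profiles = self._profiles(four_stage_design, genes=300)
        fc = fuzzy_cmeans(profiles, c=3, rng_seed=3)
        hard = fc.membership.values.argmax(axis=1)
        labels = sim.labels[:len(hard)]
        best = max(
            np.mean([perm[h] == l for h, l in zip(hard, labels)])
            for perm in permutations(range(3))
        )
        assert best >= 0.95

    def test_too_many_clusters_rejected(self):
        profiles = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError):
            fuzzy_cmeans(profiles, c=4)

    def test_zero_variance_gene_excluded_with_warning(self, four_stage_design):
        sim = simulate_expression_matrix(20, four_stage_design, 2, rng_seed=4)
        mat = sim.matrix.copy()
        mat.iloc[0] = 7.0  # constant gene
        with pytest.warns(UserWarning):
            profiles = prepare_profiles(mat, sim.sample_stages,
                                        list(four_stage_design.stages))
        assert mat.index[0] not in profiles.index

    def test_determinism(self, four_stage_design):
        _, profiles = self._profiles(four_stage_design, genes=60)
        a = fuzzy_cmeans(profiles, c=3, rng_seed=9)
        b = fuzzy_cmeans(profiles, c=3, rng_seed=9)
        assert np.array_equal(a.membership.values, b.membership.values)


class TestShortlist:
    def _clustering(self, four_stage_design, genes=120):
        sim = simulate_expression_matrix(genes, four_stage_design, 3, rng_seed=8)
        profiles = prepare_profiles(sim.matrix, sim.sample_stages,
                                    list(four_stage_design.stages))
        fc = fuzzy_cmeans(profiles, c=3, rng_seed=8)
        return sim, fc

    def test_lost_in_up_cluster_shortlisted(self, four_stage_design):
        sim, fc = self._clustering(four_stage_design)
        up_genes = [g for g, l in zip(sim.matrix.index, sim.labels) if l == 0]
        down_genes = [g for g, l in zip(sim.matrix.index, sim.labels) if l == 1]
        flat_genes = [g for g, l in zip(sim.matrix.index, sim.labels) if l == 2]
        from miredit.retarget import TargetDelta

        delta = TargetDelta(lost=[up_genes[0], flat_genes[0]],
                            gained=[down_genes[0], flat_genes[1]],
                            shared=[])
        short = shortlist_by_pattern(delta, fc)
        assert short["lost"] == [up_genes[0]]
        assert short["gained"] == [down_genes[0]]

    def test_absent_gene_skipped_with_warning(self, four_stage_design):
        _, fc = self._clustering(four_stage_design)
        from miredit.retarget import TargetDelta

        delta = TargetDelta(lost=["not_a_gene"], gained=[], shared=[])
        with pytest.warns(UserWarning):
            short = shortlist_by_pattern(delta, fc)
        assert short["lost"] == []
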
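from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from miredit.cohort import CohortEditingMatrix
from miredit.editcall import (
    CallConfig, EditingSite, SitePileup, apply_cohort_filters, binomial_p_raw,
    call_editing_sites, estimate_error_rate, filter_sites, pileup,
    quantify_expression,
)
from miredit.synthetic_data.reference import VariantRecord
from oracles import oracle_binomial_tail, oracle_pileup_tally


def make_pileup(ref="A", a=0, c=0, g=0, t=0, mirna="pre-x", matpos=3,
                contig="c1", pos=100, mito=False):
    return SitePileup(contig=contig, pos=pos, ref_base=ref, counts=(a, c, g, t),
                      mirna_id=mirna, mature_position=matpos, mito=mito)


# ------------------------------------------------------------------- pileup


class TestPileup:
    def test_perfect_reads_over_a(self, toy_annotation):
        ref = {"c1": "C" * 20 + "A" * 60 + "C" * 20 + "T" * 60 + "C" * 40}
        aln = {("c1", 25, "A" * 10): 10}
        piles = pileup(aln, toy_annotation, ref)
        site = next(p for p in piles if p.pos == 30)
        assert site.counts == (10, 0, 0, 0)
        assert site.coverage == 10

    def test_minus_strand_complemented_to_mirna_space(self, toy_annotation):
        # minus-strand hairpin at c1:100-160; genomic T -> miRNA-strand A
        ref = {"c1": "G" * 100 + "T" * 60 + "G" * 40}
        # reads carry genomic C at position 120 (miRNA-strand G)
        aln = {("c1", 115, "TTTTTCTTTT"): 4, ("c1", 115, "TTTTTTTTTT"): 6}
        piles = pileup(aln, toy_annotation, ref)
        site = next(p for p in piles if p.pos == 120)
        assert site.ref_base == "A"
        assert site.counts == (6, 0, 4, 0)  # A=6, G=4 on the miRNA strand

    def test_mature_position_mapping_minus(self, toy_annotation):
        ref = {"c1": "G" * 100 + "T" * 60 + "G" * 40}
        aln = {("c1", 125, "T" * 7): 1}
        piles = pileup(aln, toy_annotation, ref)
        # mature interval 110-132 on '-': genomic 129 is mature position 3
        site = next(p for p in piles if p.pos == 129)
        assert site.mature_position == 3 and site.in_seed

    def test_outside_premirna_suppressed_by_default(self, toy_annotation):
        ref = {"c1": "A" * 300}
        aln = {("c1", 200, "AAAA"): 5}
        assert pileup(aln, toy_annotation, ref) == []
        piles = pileup(aln, toy_annotation, ref, include_outside=True)
        assert len(piles) == 4 and piles[0].mirna_id is None

    def test_matches_brute_force_tally(self, toy_annotation):
        ref = {"c1": "ACGT" * 100}
        reads = [("c1", 20, "GTACGTACGT"), ("c1", 22, "ACGTACGTAC"),
                 ("c1", 25, "TACGTACG"), ("c1", 20, "GTACGTACGT"),
                 ("c1", 30, "GCGTACGTAG")]
        counter = {}
        for r in reads:
            counter[r] = counter.get(r, 0) + 1
        piles = pileup(counter, toy_annotation, ref)
        tally = oracle_pileup_tally(reads)
        for p in piles:
            expected = tally[(p.contig, p.pos)]
            # toy hairpin at 10-70 is '+', so no complementing here
            for i, base in enumerate("ACGT"):
                assert p.counts[i] == expected.get(base, 0)
        # every tallied in-hairpin position must be emitted
        in_pre = [k for k in tally if 10 <= k[1] < 70]
        assert len(piles) == len(in_pre)

    def test_unknown_contig_rejected(self, toy_annotation):
        with pytest.raises(ValueError, match="chrUn"):
            pileup({("chrUn", 0, "AAAA"): 1}, toy_annotation, {"c1": "A" * 100})


# --------------------------------------------------------------- error rate


class TestErrorRate:
    def test_error_free_returns_floor(self):
        piles = [make_pileup(a=100)]
        assert estimate_error_rate(piles) == 1e-6

    def test_three_in_three_hundred(self):
        # 3 non-A->G mismatches over 300 eligible bases -> 0.01
        piles = [
            make_pileup(ref="C", c=98, t=2, pos=1),
            make_pileup(ref="G", g=99, a=1, pos=2),
            make_pileup(ref="A", a=100, pos=3),
        ]
        assert estimate_error_rate(piles) == pytest.approx(3 / 300)

    def test_a_to_g_excluded_from_estimate(self):
        piles = [make_pileup(a=80, g=20)]
        assert estimate_error_rate(piles) == 1e-6

    def test_no_eligible_sites_raises(self):
        with pytest.raises(ValueError, match="error_rate"):
            estimate_error_rate([make_pileup(a=2)], min_coverage=10)


# ------------------------------------------------------------------ calling


class TestCallEditingSites:
    def test_no_g_level_zero_p_one(self):
        sites = call_editing_sites(
            [make_pileup(a=100)], CallConfig(error_rate=0.01)
        )
        assert sites[0].editing_level == 0.0
        assert sites[0].p_raw == 1.0

    def test_exact_tail_oracle_950_50(self):
        # A=950, G=50, per-base null 0.01/3: exact upper tail
        p = binomial_p_raw(50, 1000, 0.01 / 3)
        exact = oracle_binomial_tail(50, 1000, Fraction(1, 300))
        assert exact > 0
        assert abs(p - float(exact)) / float(exact) < 1e-9

    def test_bonferroni_arithmetic(self):
        piles = [make_pileup(a=990, g=10, pos=i) for i in range(100)]
        sites = call_editing_sites(piles, CallConfig(error_rate=0.01))
        s = sites[0]
        assert s.p_bonferroni == pytest.approx(min(1.0, s.p_raw * 100))
        assert s.p_bonferroni >= s.p_raw

    def test_low_coverage_site_not_tested(self):
        piles = [make_pileup(a=5, g=1), make_pileup(a=50, g=5, pos=101)]
        sites = call_editing_sites(piles, CallConfig(error_rate=0.01))
        assert len(sites) == 1 and sites[0].site.pos == 101

    def test_monotone_in_g_count(self):
        ps = [binomial_p_raw(g, 200, 0.003) for g in range(0, 201, 10)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_editing_level_denominator_a_plus_g(self):
        sites = call_editing_sites(
            [make_pileup(a=80, g=20, c=10, t=10)], CallConfig(error_rate=0.01)
        )
        assert sites[0].editing_level == pytest.approx(0.2)

    def test_family_wise_error_control(self):
        # 200 fully-null replicates, 100 sites each: FWER <= alpha + 3*SE
        rng = np.random.default_rng(123)
        err = 0.01
        cfg = CallConfig(error_rate=err, alpha_bonferroni=0.1)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            gs = rng.binomial(200, err / 3, size=100)
            piles = [make_pileup(a=200 - g, g=g, pos=i) for i, g in enumerate(gs)]
            sites = call_editing_sites(piles, cfg)
            hits += any(s.significant for s in sites)
        se = np.sqrt(0.1 * 0.9 / n_rep)
        assert hits / n_rep <= 0.1 + 3 * se


# ---------------------------------------------------------------- filtering


class TestFilterSites:
    def _as_editing_site(self, p):
        return EditingSite(site=p, editing_level=0.2, p_raw=1e-9,
                           p_bonferroni=1e-7, significant=True)

    def test_mitochondrial_dropped(self):
        es = self._as_editing_site(make_pileup(mito=True, contig="chrM"))
        kept, flagged = filter_sites([es], None, set())
        assert kept == [] and flagged[0].filter_flags == {"MITOCHONDRIAL"}

    def test_variant_overlap_any_allele(self):
        es = self._as_editing_site(make_pileup(contig="c1", pos=100))
        variants = [VariantRecord("c1", 100, "A", "T", "rs1")]  # alt != G
        kept, flagged = filter_sites([es], None, variants)
        assert kept == [] and "KNOWN_SNP" in flagged[0].filter_flags

    def test_clean_site_retained(self):
        es = self._as_editing_site(make_pileup())
        kept, flagged = filter_sites([es], None, set())
        assert flagged == [] and kept[0].filter_flags == set()

    def test_outside_premirna_flagged(self):
        es = self._as_editing_site(make_pileup(mirna=None, matpos=0))
        kept, flagged = filter_sites([es], None, set())
        assert kept == [] and "NOT_PREMIRNA" in flagged[0].filter_flags


# ------------------------------------------------------------------- TPM


class TestQuantifyExpression:
    def test_single_mirna_gets_1e6(self, toy_annotation):
        aln = {("c1", 25, "A" * 12): 10}
        df = quantify_expression(aln, toy_annotation)
        assert df.loc["plus-3p", "tpm"] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split(self, toy_annotation):
        aln = {("c1", 25, "A" * 12): 10, ("c1", 115, "T" * 12): 10}
        df = quantify_expression(aln, toy_annotation)
        assert df.loc["plus-3p", "tpm"] == pytest.approx(5e5)
        assert df.loc["minus-3p", "tpm"] == pytest.approx(5e5)

    def test_closed_form_three_mirnas(self):
        from miredit.annotation import MatureMirna, MirnaAnnotation, Premirna

        ann = MirnaAnnotation([
            Premirna("p1", "c", 0, 60, "+", False, (MatureMirna("m1", 10, 30),)),
            Premirna("p2", "c", 100, 160, "+", False, (MatureMirna("m2", 110, 132),)),
            Premirna("p3", "c", 200, 260, "+", False, (MatureMirna("m3", 210, 232),)),
        ])
        aln = {("c", 12, "A" * 16): 10, ("c", 112, "A" * 16): 20,
               ("c", 212, "A" * 16): 70}
        df = quantify_expression(aln, ann)
        # spreadsheet recomputation: rates 10/0.020, 20/0.022, 70/0.022
        rates = {"m1": 10 / 0.020, "m2": 20 / 0.022, "m3": 70 / 0.022}
        total = sum(rates.values())
        for mid, rate in rates.items():
            assert df.loc[mid, "tpm"] == pytest.approx(rate / total * 1e6)

    def test_zero_counts_warns_all_zero(self, toy_annotation):
        with pytest.warns(UserWarning):
            df = quantify_expression({}, toy_annotation)
        assert (df["tpm"] == 0).all()


# ------------------------------------------------------------ cohort filters


def _matrix(values: dict, tpm: dict, stages=("N", "T"), n_per=5):
    sample_ids = [f"{s}_{i}" for s in stages for i in range(n_per)]
    samples = pd.DataFrame(
        {"stage": [s for s in stages for _ in range(n_per)],
         "group": ["normal" if s == stages[0] else "tumor"
                   for s in stages for _ in range(n_per)]},
        index=sample_ids,
    )
    editing = pd.DataFrame(
        {sid: [values[k][i] for k in values] for i, sid in enumerate(sample_ids)},
        index=pd.Index(list(values), tupleize_cols=False),
    )
    meta = pd.DataFrame(index=editing.index)
    tpm_df = pd.DataFrame({sid: tpm for sid in sample_ids})
    return CohortEditingMatrix(editing=editing, site_meta=meta, samples=samples,
                               tpm=tpm_df, stage_order=stages)


class TestCohortFilters:
    def test_mean_boundary_dropped(self):
        m = _matrix({("mir1", 3): [0.049] * 10}, {"mir1": 10.0})
        retained, dropped = apply_cohort_filters(m, "MEAN_AND_TPM")
        assert retained == [] and dropped[("mir1", 3)] == ["MEAN_EDITING_BELOW_MIN"]

    def test_mean_at_threshold_kept(self):
        m = _matrix({("mir1", 3): [0.05] * 10}, {"mir1": 10.0})
        retained, _ = apply_cohort_filters(m, "MEAN_AND_TPM")
        assert retained == [("mir1", 3)]

    def test_tpm_below_min_dropped(self):
        m = _matrix({("mir1", 3): [0.3] * 10}, {"mir1": 0.5})
        retained, dropped = apply_cohort_filters(m, "MEAN_AND_TPM")
        assert retained == [] and dropped[("mir1", 3)] == ["TPM_BELOW_MIN"]

    def test_n_samples_boundary(self):
        vals9 = [0.06] * 9 + [0.0] * 1
        vals10 = [0.06] * 10
        m = _matrix({("mir9", 3): vals9, ("mir10", 3): vals10}, {"mir9": 5, "mir10": 5})
        retained, dropped = apply_cohort_filters(m, "N_SAMPLES")
        assert retained == [("mir10", 3)]
        assert ("mir9", 3) in dropped

    def test_all_zero_matrix_empty_result(self):
        m = _matrix({("mir1", 3): [0.0] * 10}, {"mir1": 5})
        retained, _ = apply_cohort_filters(m, "MEAN_AND_TPM")
        assert retained == []

    def test_unknown_rule_rejected(self):
        m = _matrix({("mir1", 3): [0.0] * 10}, {"mir1": 5})
        with pytest.raises(ValueError):
            apply_cohort_filters(m, "BOGUS")
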
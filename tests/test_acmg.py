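"""Evidence-code evaluators, strength combination and the PLPV filter."""

import pytest
from hypothesis import given, settings, strategies as st

from chprev.acmg import (
    ALLOWED_CODES,
    AnnotationError,
    ConfigurationError,
    EvidenceAssignment,
    PM3Observation,
    SegregationData,
    TIER_RANK,
    classify_all,
    combine_evidence,
    derive_pm2_threshold,
    evaluate_pm1,
    evaluate_pm2,
    evaluate_pm3,
    evaluate_pp1,
    evaluate_pp3,
    evaluate_pvs1,
    loftee_filter,
    round_one_sigfig,
)
from chprev.genespec import EngineConfig, GeneSpec
from chprev.variant_io import InSilicoScores, PopulationCounts

from conftest import make_record, record_with_af


class TestPm2Threshold:
    @pytest.mark.parametrize(
        "afs,expected",
        [
            ([0.0029, 0.0001], 0.0003),  # most frequent pathogenic allele / 10
            ([0.0], 0.0),
            ([0.00042], 0.00004),
        ],
    )
    def test_order_of_magnitude_rule(self, afs, expected):
        assert derive_pm2_threshold(afs) == pytest.approx(expected, rel=1e-12)

    def test_empty_spectrum_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="explicit"):
            derive_pm2_threshold([])

    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            derive_pm2_threshold([1.5])

    @pytest.mark.parametrize("k", [1e-2, 1e-1, 10.0])
    @pytest.mark.parametrize("base", [0.0029, 0.00042, 0.011])
    def test_scale_equivariance_powers_of_ten(self, k, base):
        scaled = derive_pm2_threshold([base * k])
        assert scaled == pytest.approx(
            round_one_sigfig(k * derive_pm2_threshold([base]) * 1.0), rel=1e-9
        )


class TestLofteeFilter:
    def test_low_confidence_null_filtered(self):
        assert not loftee_filter(make_record(loftee="LC"))

    def test_non_null_passes_through(self):
        assert loftee_filter(make_record(consequence="missense", loftee="NA"))

    def test_flagged_high_confidence_filtered(self):
        assert not loftee_filter(make_record(loftee="HC", loftee_flags=("NAGNAG_SITE",)))

    def test_clinvar_plp_exempt(self):
        assert loftee_filter(make_record(loftee="LC", clinvar="PLP"))

    def test_null_without_loftee_filtered(self):
        assert not loftee_filter(make_record(loftee="NA"))


class TestPvs1:
    def test_nmd_positive_truncation_very_strong(self, toy_spec):
        v = make_record(hgvs_p="p.Gln100Ter")  # codon 100 of 1000, NMD at ~950
        assert evaluate_pvs1(v, toy_spec).strength == "VeryStrong"

    def test_missense_not_met(self, toy_spec):
        v = make_record(consequence="missense", hgvs_p="p.Arg500His")
        assert evaluate_pvs1(v, toy_spec).strength == "NotMet"

    def test_last_exon_small_truncation_moderate(self, toy_spec):
        # removes 5% of the protein, no domain hit, NMD escape
        v = make_record(consequence="frameshift", hgvs_c="c.2852delA",
                        hgvs_p="p.Lys951AsnfsTer3")
        assert evaluate_pvs1(v, toy_spec).strength == "Moderate"

    def test_nmd_escape_with_domain_hit_strong(self, toy_spec):
        spec = GeneSpec(gene="TOY", transcript="t", coding_length_aa=1000,
                        last_junction_cds=1200,
                        domains=toy_spec.domains)
        v = make_record(hgvs_p="p.Gln500Ter")  # escape; stops inside domain
        assert evaluate_pvs1(v, spec).strength == "Strong"

    def test_nmd_escape_large_truncation_strong(self, toy_spec):
        spec = GeneSpec(gene="TOY", transcript="t", coding_length_aa=1000,
                        last_junction_cds=1200)
        v = make_record(hgvs_p="p.Gln600Ter")  # removes 40%, no domains
        assert evaluate_pvs1(v, spec).strength == "Strong"

    def test_initiation_loss_moderate(self, toy_spec):
        v = make_record(consequence="initiation_loss", hgvs_c="c.1A>G", hgvs_p="p.Met1?")
        assert evaluate_pvs1(v, toy_spec).strength == "Moderate"

    def test_non_lof_mechanism_not_met(self, toy_spec):
        spec = GeneSpec(gene="TOY", transcript="t", coding_length_aa=1000,
                        last_junction_cds=2850, mechanism="other")
        assert evaluate_pvs1(make_record(), spec).strength == "NotMet"

    def test_truncation_beyond_coding_length_is_annotation_error(self, toy_spec):
        v = make_record(hgvs_p="p.Gln1001Ter")
        with pytest.raises(AnnotationError, match="beyond coding length"):
            evaluate_pvs1(v, toy_spec)

    def test_splice_variant_uses_cds_position(self, toy_spec):
        v = make_record(consequence="splice_site", hgvs_c="c.300+1G>A", hgvs_p="")
        assert evaluate_pvs1(v, toy_spec).strength == "VeryStrong"


class TestPm2:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (0.0001, "Supporting"),
            (0.0003, "Supporting"),  # boundary inclusive
            (0.0029, "NotMet"),
        ],
    )
    def test_threshold_comparison(self, af, expected):
        v = record_with_af(af, an=100000)
        assert evaluate_pm2(v, threshold=0.0003).strength == expected

    def test_no_coverage_not_met(self):
        v = make_record(counts={"GLOBAL": PopulationCounts(0, 0, 0)})
        a = evaluate_pm2(v, threshold=0.0003)
        assert a.strength == "NotMet" and "coverage" in a.rationale

    def test_homozygotes_stripped_before_comparison(self):
        # AC 10 with 5 homozygotes: het AF is 0, well under threshold
        v = make_record(counts={"GLOBAL": PopulationCounts(10, 100000, 5)})
        assert evaluate_pm2(v, threshold=1e-5).strength == "Supporting"


class TestPm3:
    def test_no_probands_not_met(self):
        assert evaluate_pm3([]).strength == "NotMet"

    def test_two_confirmed_in_trans_strong(self):
        obs = [PM3Observation(f"p{i}", "in_trans_confirmed", "pathogenic") for i in (1, 2)]
        assert evaluate_pm3(obs).strength == "Strong"  # 2.0 points

    def test_four_phase_unknown_moderate(self):
        obs = [PM3Observation(f"p{i}", "phase_unknown", "pathogenic") for i in range(4)]
        assert evaluate_pm3(obs).strength == "Moderate"  # 4 x 0.25

    def test_homozygous_half_point(self):
        assert evaluate_pm3([PM3Observation("p1", "homozygous", "none")]).strength == "Supporting"

    def test_partner_none_requires_homozygous(self):
        with pytest.raises(ValueError, match="homozygous"):
            PM3Observation("p1", "phase_unknown", "none")


class TestPp1:
    @pytest.mark.parametrize(
        "meioses,coseg,expected",
        [(0, False, "NotMet"), (3, True, "Supporting"), (5, True, "Moderate"),
         (7, True, "Strong"), (10, False, "NotMet")],
    )
    def test_meioses_thresholds(self, meioses, coseg, expected):
        assert evaluate_pp1(SegregationData(meioses, coseg)).strength == expected


class TestPp3:
    def test_revel_above_cutoff_supporting(self):
        v = make_record(consequence="missense", scores=InSilicoScores(revel=0.80))
        assert evaluate_pp3(v).strength == "Supporting"

    def test_revel_at_cutoff_not_met(self):
        # cut-off is a strict inequality
        v = make_record(consequence="missense", scores=InSilicoScores(revel=0.75))
        assert evaluate_pp3(v).strength == "NotMet"

    def test_provean_inframe_supporting(self):
        v = make_record(consequence="inframe_indel", scores=InSilicoScores(provean=-3.1))
        assert evaluate_pp3(v).strength == "Supporting"

    def test_splice_impact_supporting(self):
        v = make_record(consequence="splice_site", scores=InSilicoScores(splice_impact=0.5))
        assert evaluate_pp3(v).strength == "Supporting"


class TestPm1:
    def test_residue_in_domain_moderate(self, toy_spec):
        v = make_record(consequence="missense", hgvs_p="p.Arg500His")
        assert evaluate_pm1(v, toy_spec).strength == "Moderate"

    def test_no_domains_not_met(self):
        spec = GeneSpec(gene="TOY", transcript="t", coding_length_aa=1000,
                        last_junction_cds=2850)
        v = make_record(consequence="missense", hgvs_p="p.Arg10His")
        assert evaluate_pm1(v, spec).strength == "NotMet"

    def test_nonsense_outside_pm1_scope(self, toy_spec):
        assert evaluate_pm1(make_record(hgvs_p="p.Gln500Ter"), toy_spec).strength == "NotMet"

    def test_unparseable_position_not_met(self, toy_spec):
        v = make_record(consequence="missense", hgvs_p="p.?")
        assert evaluate_pm1(v, toy_spec).strength == "NotMet"


class TestCombine:
    def e(self, code, strength):
        return EvidenceAssignment(code, strength)

    @pytest.mark.parametrize("mode", ["points", "rule_table"])
    def test_lof_plus_rarity_likely_pathogenic(self, mode):
        result = combine_evidence(
            [self.e("PVS1", "VeryStrong"), self.e("PM2", "Supporting")], mode
        )
        assert result.tier == "LikelyPathogenic"
        assert result.points == 9

    @pytest.mark.parametrize("mode", ["points", "rule_table"])
    def test_lof_plus_in_trans_pathogenic(self, mode):
        result = combine_evidence(
            [self.e("PVS1", "VeryStrong"), self.e("PM3", "Strong")], mode
        )
        assert result.tier == "Pathogenic"
        assert result.points == 12

    @pytest.mark.parametrize("mode", ["points", "rule_table"])
    def test_no_evidence_vus(self, mode):
        result = combine_evidence([], mode)
        assert result.tier == "VUS" and result.points == 0

    def test_duplicate_code_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            combine_evidence([self.e("PM2", "Supporting"), self.e("PM2", "Moderate")])

    def test_pp4_pp5_unrepresentable(self):
        with pytest.raises(ValueError, match="not applied"):
            EvidenceAssignment("PP5", "Supporting")


# ---------------------------------------------------------------------------
# monotonicity: adding evidence or raising a strength never lowers the tier

_strengths = st.sampled_from(["Supporting", "Moderate", "Strong", "VeryStrong"])


@st.composite
def evidence_sets(draw):
    codes = draw(st.sets(st.sampled_from(ALLOWED_CODES), max_size=5))
    return [EvidenceAssignment(c, draw(_strengths)) for c in sorted(codes)]


@settings(max_examples=300, deadline=None, derandomize=True)
@given(evidence_sets(), st.data())
def test_evidence_monotonicity(evidence, data):
    for mode in ("points", "rule_table"):
        base = TIER_RANK[combine_evidence(evidence, mode).tier]
        # raise one strength a level
        if evidence:
            i = data.draw(st.integers(0, len(evidence) - 1), label="raise_index")
            raised = list(evidence)
            cur = raised[i].strength
            nxt = {"Supporting": "Moderate", "Moderate": "Strong",
                   "Strong": "VeryStrong", "VeryStrong": "VeryStrong"}[cur]
            raised[i] = EvidenceAssignment(raised[i].code, nxt)
            assert TIER_RANK[combine_evidence(raised, mode).tier] >= base
        # add one new code
        unused = [c for c in ALLOWED_CODES if c not in {e.code for e in evidence}]
        if unused:
            extra = EvidenceAssignment(
                data.draw(st.sampled_from(unused), label="new_code"),
                data.draw(_strengths, label="new_strength"),
            )
            assert TIER_RANK[combine_evidence(evidence + [extra], mode).tier] >= base


# ---------------------------------------------------------------------------
# classify_all

class TestClassifyAll:
    def test_rare_hc_nonsense_is_plpv(self, toy_spec):
        v = record_with_af(1e-5, an=200000)
        ((_, result),) = classify_all([v], {"TOY": toy_spec},
                                      EngineConfig(pm2_threshold=0.0003))
        assert result.tier == "LikelyPathogenic" and result.is_plpv

    def test_lc_nonsense_never_plpv(self, toy_spec):
        v = record_with_af(1e-5, an=200000, loftee="LC")
        ((_, result),) = classify_all([v], {"TOY": toy_spec},
                                      EngineConfig(pm2_threshold=0.0003))
        assert not result.is_plpv and result.short_circuit == "loftee_filtered"

    def test_clinvar_plp_short_circuits(self, toy_spec):
        v = record_with_af(0.01, an=200000, loftee="LC", clinvar="PLP")
        ((_, result),) = classify_all([v], {"TOY": toy_spec})
        assert result.tier == "Pathogenic" and result.short_circuit == "clinvar_plp"

    def test_clinvar_blb_excluded(self, toy_spec):
        v = record_with_af(1e-5, an=200000, consequence="missense", clinvar="BLB")
        ((_, result),) = classify_all([v], {"TOY": toy_spec})
        assert result.tier == "Benign" and not result.is_plpv

    def test_missing_gene_spec_is_error(self, toy_spec):
        with pytest.raises(ConfigurationError, match="OTHER"):
            classify_all([make_record(gene="OTHER")], {"TOY": toy_spec})

    def test_permutation_equivariance(self, toy_spec):
        records = [
            record_with_af(af, an=200000, hgvs_c=f"c.{i}C>T", hgvs_p=f"p.Gln{i}Ter")
            for i, af in enumerate([1e-5, 1e-3, 5e-2], start=100)
        ]
        spec = {"TOY": toy_spec}
        forward = classify_all(records, spec)
        backward = classify_all(records[::-1], spec)
        assert forward == backward[::-1]

    def test_intended_tiers_reproduced_on_synthetic_fixture(self, classified_study):
        """Joint fixture: every simulated variant's intended tier, both the
        pathogenic set and every decoy, is reproduced exactly."""
        config, truth, results = classified_study
        assert len(results) >= 20
        for record, result in results:
            assert result.tier == truth.intended_tiers[record.key], record.key
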
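"""ACMG/AMP evidence engine with SVI-style strength modulation.

Implements the pathogenic-side evidence codes needed to build a
presumed-pathogenic variant set from population summary data for a
loss-of-function recessive disease: PVS1 (via a decision tree over NMD
prediction, critical-domain overlap and fraction of protein removed),
PM2 (rarity against a derived frequency threshold), PM3 (in-trans
points), PP1 (co-segregation), PP3 (in-silico support), PM1 (domain
hotspot), and two combining modes (Bayesian points and the classic
rule table) that must agree on curated fixtures.

Benign-side codes are intentionally absent: ClinVar benign/likely-benign
records are short-circuited out before evaluation, and the pipeline only
needs the pathogenic side to assemble its variant set.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .genespec import EngineConfig, GeneSpec
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

STRENGTH_ORDER = ("NotMet", "Supporting", "Moderate", "Strong", "VeryStrong")
STRENGTH_RANK = {s: i for i, s in enumerate(STRENGTH_ORDER)}
POINTS = {"NotMet": 0, "Supporting": 1, "Moderate": 2, "Strong": 4, "VeryStrong": 8}

ALLOWED_CODES = ("PVS1", "PS3", "PM1", "PM2", "PM3", "PP1", "PP3")

TIERS = ("Benign", "LikelyBenign", "VUS", "LikelyPathogenic", "Pathogenic")
TIER_RANK = {t: i for i, t in enumerate(TIERS)}


class AnnotationError(ValueError):
    """Variant annotation is inconsistent with the gene specification."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceAssignment:
    code: str
    strength: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.code in ("PP4", "PP5"):
            raise ValueError(f"{self.code} is not applied in this pipeline")
        if self.code not in ALLOWED_CODES:
            raise ValueError(f"unknown evidence code {self.code!r}")
        if self.strength not in STRENGTH_ORDER:
            raise ValueError(f"unknown strength {self.strength!r}")

    @property
    def met(self) -> bool:
        return self.strength != "NotMet"

    @property
    def points(self) -> int:
        return POINTS[self.strength]


@dataclass(frozen=True)
class PM3Observation:
    """One proband carrying the variant with a second allele in the gene."""

    proband: str
    phase: str  # in_trans_confirmed | phase_unknown | homozygous
    partner_class: str = "none"  # pathogenic | likely_pathogenic | none

    def __post_init__(self) -> None:
        if self.phase not in ("in_trans_confirmed", "phase_unknown", "homozygous"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.partner_class not in ("pathogenic", "likely_pathogenic", "none"):
            raise ValueError(f"unknown partner_class {self.partner_class!r}")
        if self.partner_class == "none" and self.phase != "homozygous":
            raise ValueError("partner_class 'none' only valid for homozygous probands")


@dataclass(frozen=True)
class SegregationData:
    informative_meioses: int
    cosegregating: bool

    def __post_init__(self) -> None:
        if self.informative_meioses < 0:
            raise ValueError("informative meioses count must be non-negative")


@dataclass(frozen=True)
class ClassificationResult:
    tier: str
    evidence: tuple[EvidenceAssignment, ...] = ()
    points: int = 0
    short_circuit: str | None = None  # clinvar_plp | clinvar_blb | loftee_filtered

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def is_plpv(self) -> bool:
        return self.tier in ("Pathogenic", "LikelyPathogenic")


# ---------------------------------------------------------------------------
# thresholds

def round_one_sigfig(x: float) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    mantissa = round(x / 10 ** exponent)
    return float(f"{mantissa}e{exponent}")


def derive_pm2_threshold(pathogenic_afs: list[float]) -> float:
    """Rarity threshold: one order of magnitude below the most frequent
    known pathogenic allele, rounded to one significant figure."""
    if not pathogenic_afs:
        raise ConfigurationError(
            "empty pathogenic allele-frequency spectrum; "
            "supply an explicit PM2 threshold instead"
        )
    if any(not 0.0 <= af <= 1.0 for af in pathogenic_afs):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return round_one_sigfig(max(pathogenic_afs) / 10.0)


# ---------------------------------------------------------------------------
# LOFTEE filter

def loftee_filter(v: VariantRecord) -> bool:
    """Retain putative LoF ("null") variants only when LOFTEE calls them
    high-confidence without warning flags; known ClinVar P/LP variants and
    non-null consequences pass through unchanged."""
    if v.clinvar == "PLP" or not v.is_null_variant:
        return True
    if v.loftee == "NA":
        logger.info("%s %s: null variant without LOFTEE call, filtered", v.gene, v.hgvs_c)
        return False
    return v.loftee == "HC" and not v.loftee_flags


# ---------------------------------------------------------------------------
# HGVS position helpers (opaque-string convention: first integer wins)

_PROTEIN_POS = re.compile(r"p\.\(?(?:[A-Z][a-z]{2}|\*)?(\d+)")
_CDS_POS = re.compile(r"c\.\*?(\d+)")


def protein_position(hgvs_p: str) -> int | None:
    m = _PROTEIN_POS.search(hgvs_p or "")
    return int(m.group(1)) if m else None


def cds_position(hgvs_c: str) -> int | None:
    m = _CDS_POS.search(hgvs_c or "")
    return int(m.group(1)) if m else None


def _truncation_codon(v: VariantRecord) -> int | None:
    pos = protein_position(v.hgvs_p)
    if pos is not None:
        return pos
    nt = cds_position(v.hgvs_c)
    return None if nt is None else (nt + 2) // 3


# ---------------------------------------------------------------------------
# evidence evaluators

def evaluate_pvs1(v: VariantRecord, spec: GeneSpec) -> EvidenceAssignment:
    """Loss-of-function decision tree.

    Truncating variants predicted to undergo NMD get the full VeryStrong
    weight; NMD-escaping truncations keep Strong when they remove a
    critical domain or more than 10% of the protein, else drop to
    Moderate. Canonical splice variants run the same sub-tree on the
    affected coding position; initiation loss is Moderate; everything
    else is not a PVS1 candidate.
    """
    if spec.mechanism != "loss_of_function":
        return EvidenceAssignment("PVS1", "NotMet", "mechanism is not loss of function")
    if v.consequence == "initiation_loss":
        return EvidenceAssignment("PVS1", "Moderate", "initiation codon loss")
    if not v.is_null_variant:
        return EvidenceAssignment("PVS1", "NotMet", f"{v.consequence} not a LoF candidate")

    codon = _truncation_codon(v)
    if codon is None:
        return EvidenceAssignment("PVS1", "NotMet", "no parseable truncation position")
    if codon > spec.coding_length_aa:
        raise AnnotationError(
            f"{v.gene} {v.hgvs_c}: truncation at codon {codon} beyond coding "
            f"length {spec.coding_length_aa}"
        )
    cds_nt = 3 * codon - 2
    if spec.nmd_predicted(cds_nt):
        return EvidenceAssignment("PVS1", "VeryStrong", "truncation predicted to trigger NMD")
    fraction_removed = (spec.coding_length_aa - codon + 1) / spec.coding_length_aa
    if spec.domain_overlap(codon):
        return EvidenceAssignment(
            "PVS1", "Strong", "NMD-escaping truncation removes a critical domain"
        )
    if fraction_removed > EngineConfig.pvs1_protein_fraction:
        return EvidenceAssignment(
            "PVS1", "Strong",
            f"NMD-escaping truncation removes {fraction_removed:.0%} of the protein",
        )
    return EvidenceAssignment(
        "PVS1", "Moderate", "NMD-escaping truncation, no critical region affected"
    )


def evaluate_pm2(
    v: VariantRecord, threshold: float, reference_population: str = "GLOBAL"
) -> EvidenceAssignment:
    """Rarity code, weighted Supporting per SVI practice; the boundary is
    inclusive (AF <= threshold counts as rare)."""
    from .prevalence import allele_frequency_het

    counts = v.counts.get(reference_population)
    if counts is None or counts.allele_number == 0:
        return EvidenceAssignment("PM2", "NotMet", f"no coverage in {reference_population}")
    af = allele_frequency_het(counts)
    if af <= threshold:
        return EvidenceAssignment(
            "PM2", "Supporting", f"AF {af:.2e} <= threshold {threshold:g}"
        )
    return EvidenceAssignment("PM2", "NotMet", f"AF {af:.2e} above threshold {threshold:g}")


def evaluate_pm3(
    observations: list[PM3Observation], config: EngineConfig | None = None
) -> EvidenceAssignment:
    """In-trans evidence: SVI-style per-proband points summed, then mapped
    to a strength level."""
    config = config or EngineConfig()
    total = 0.0
    for obs in observations:
        total += config.pm3_points.get((obs.phase, obs.partner_class), 0.0)
    for cutoff, strength in config.pm3_strength_cutoffs:
        if total >= cutoff:
            return EvidenceAssignment("PM3", strength, f"{total:g} proband points")
    return EvidenceAssignment("PM3", "NotMet", f"{total:g} proband points")


def evaluate_pp1(
    seg: SegregationData, config: EngineConfig | None = None
) -> EvidenceAssignment:
    """Co-segregation strength from the count of informative meioses."""
    config = config or EngineConfig()
    if seg.cosegregating:
        for cutoff, strength in config.pp1_cutoffs:
            if seg.informative_meioses >= cutoff:
                return EvidenceAssignment(
                    "PP1", strength, f"{seg.informative_meioses} informative meioses"
                )
    return EvidenceAssignment("PP1", "NotMet", "insufficient segregation data")


def evaluate_pp3(v: VariantRecord, config: EngineConfig | None = None) -> EvidenceAssignment:
    """In-silico support, capped at Supporting; predictors vote by OR.

    REVEL > 0.75 (strict) for missense; splice-impact >= 0.2 for
    splice-adjacent variants; PROVEAN <= -2.5 for in-frame indels.
    """
    config = config or EngineConfig()
    s = v.scores
    if v.consequence == "missense" and s.revel is not None and s.revel > config.revel_cutoff:
        return EvidenceAssignment("PP3", "Supporting", f"REVEL {s.revel:g}")
    if (
        v.consequence == "splice_site"
        and s.splice_impact is not None
        and s.splice_impact >= config.splice_impact_cutoff
    ):
        return EvidenceAssignment("PP3", "Supporting", f"splice impact {s.splice_impact:g}")
    if (
        v.consequence == "inframe_indel"
        and s.provean is not None
        and s.provean <= config.provean_cutoff
    ):
        return EvidenceAssignment("PP3", "Supporting", f"PROVEAN {s.provean:g}")
    return EvidenceAssignment("PP3", "NotMet", "no predictor above cut-off")


def evaluate_pm1(v: VariantRecord, spec: GeneSpec) -> EvidenceAssignment:
    """Mutational hotspot / critical domain code, restricted to missense and
    in-frame variants (truncations are covered by the PVS1 domain logic)."""
    if v.consequence not in ("missense", "inframe_indel"):
        return EvidenceAssignment("PM1", "NotMet", f"{v.consequence} outside PM1 scope")
    residue = protein_position(v.hgvs_p)
    if residue is None:
        return EvidenceAssignment("PM1", "NotMet", "unparseable protein position")
    if spec.in_domain(residue):
        return EvidenceAssignment("PM1", "Moderate", f"residue {residue} in critical domain")
    return EvidenceAssignment("PM1", "NotMet", f"residue {residue} outside critical domains")


# ---------------------------------------------------------------------------
# combining

def _points_tier(total: int) -> str:
    if total >= 10:
        return "Pathogenic"
    if total >= 6:
        return "LikelyPathogenic"
    return "VUS"


def _rule_table_tier(evidence: list[EvidenceAssignment]) -> str:
    n = {s: 0 for s in STRENGTH_ORDER}
    for e in evidence:
        n[e.strength] += 1
    vs, st, mo, su = n["VeryStrong"], n["Strong"], n["Moderate"], n["Supporting"]

    pathogenic = (
        vs >= 2
        or (vs >= 1 and (st >= 1 or mo >= 2 or (mo >= 1 and su >= 1) or su >= 2))
        or st >= 2
        or (st >= 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)))
    )
    if pathogenic:
        return "Pathogenic"

    codes = {e.code: e for e in evidence}
    svi_lof_rare = (
        "PVS1" in codes and codes["PVS1"].strength == "VeryStrong" and "PM2" in codes
    )
    likely = (
        (vs >= 1 and mo >= 1)
        or (st >= 1 and mo >= 1)
        or (st >= 1 and su >= 2)
        or mo >= 3
        or (mo >= 2 and su >= 2)
        or (mo >= 1 and su >= 4)
        or svi_lof_rare
    )
    return "LikelyPathogenic" if likely else "VUS"


def combine_evidence(
    evidence: list[EvidenceAssignment], mode: str = "points"
) -> ClassificationResult:
    """Combine met evidence codes into a five-tier call.

    points mode: Supporting 1, Moderate 2, Strong 4, VeryStrong 8;
    >=10 Pathogenic, 6-9 LikelyPathogenic, else VUS. rule_table mode:
    the classic combining table on strength-modulated codes, plus the
    SVI special case PVS1 + rare (PM2) -> LikelyPathogenic.
    """
    met = [e for e in evidence if e.met]
    codes = [e.code for e in met]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate evidence codes: {sorted(codes)}")
    total = sum(e.points for e in met)
    if mode == "points":
        tier = _points_tier(total)
    elif mode == "rule_table":
        tier = _rule_table_tier(met)
    else:
        raise ValueError(f"unknown combining mode {mode!r}")
    return ClassificationResult(tier=tier, evidence=tuple(met), points=total)


# ---------------------------------------------------------------------------
# pipeline

def classify_variant(
    v: VariantRecord,
    spec: GeneSpec,
    config: EngineConfig,
    pm3_observations: list[PM3Observation] | None = None,
    segregation: SegregationData | None = None,
    ps3_strength: str | None = None,
) -> ClassificationResult:
    if v.clinvar == "PLP":
        return ClassificationResult("Pathogenic", short_circuit="clinvar_plp")
    if v.clinvar == "BLB":
        return ClassificationResult("Benign", short_circuit="clinvar_blb")
    if not loftee_filter(v):
        return ClassificationResult("VUS", short_circuit="loftee_filtered")

    evidence = [
        evaluate_pvs1(v, spec),
        evaluate_pm2(v, config.pm2_threshold, config.pm2_population),
        evaluate_pp3(v, config),
        evaluate_pm1(v, spec),
    ]
    if pm3_observations:
        evidence.append(evaluate_pm3(pm3_observations, config))
    if segregation is not None:
        evidence.append(evaluate_pp1(segregation, config))
    if ps3_strength is not None:
        # functional data accepted as a pre-assigned strength; no evaluator
        # exists because no accepted weighting scheme for assays does
        evidence.append(EvidenceAssignment("PS3", ps3_strength, "pre-assigned"))
    return combine_evidence(evidence, config.combining_mode)


def classify_all(
    records: list[VariantRecord],
    specs: dict[str, GeneSpec],
    config: EngineConfig | None = None,
    pm3_observations: dict[tuple[str, str], list[PM3Observation]] | None = None,
    segregation: dict[tuple[str, str], SegregationData] | None = None,
    ps3: dict[tuple[str, str], str] | None = None,
) -> list[tuple[VariantRecord, ClassificationResult]]:
    """Classify every record; input order preserved. A record is a PLPV iff
    its tier is Pathogenic or LikelyPathogenic."""
    config = config or EngineConfig()
    missing = sorted({r.gene for r in records} - set(specs))
    if missing:
        raise ConfigurationError(f"no gene specification for: {', '.join(missing)}")
    out = []
    for r in records:
        result = classify_variant(
            r,
            specs[r.gene],
            config,
            pm3_observations=(pm3_observations or {}).get(r.key),
            segregation=(segregation or {}).get(r.key),
            ps3_strength=(ps3 or {}).get(r.key),
        )
        out.append((r, result))
    return out
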
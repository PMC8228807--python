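"""Synthetic gnomAD-like cohorts with known ground truth.

Genotypes are sampled per individual under Hardy-Weinberg equilibrium
from true pathogenic allele frequencies, so the homozygote count
(nhomalt) is realisable and the homozygote-stripping allele-frequency
correction is genuinely exercised. Variant annotations (consequence,
LOFTEE call, in-silico scores, in-trans observations) are constructed
so that the evidence engine reproduces a hand-derived intended tier,
giving the full pipeline a recoverable truth without any download.

Ground truth per gene and population:

    true CF_G  = 1 - prod_i (1 - 2 p_i (1 - p_i))   (het carrier rate)
    true pGP_G = (sum_i p_i)^2                       (HWE birth prevalence)

A deterministic mode assigns expected genotype counts (rounded) instead
of sampling, for exact non-stochastic fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acmg import PM3Observation
from .genespec import EngineConfig, GeneSpec, default_gene_specs
from .populations import GNOMAD_V2_SIZES
from .reference import GENES, load_known_plpv_afs
from .variant_io import (
    InSilicoScores,
    PopulationCounts,
    VariantRecord,
    synthesize_global,
)

#: variant roles in a simulated cohort
ROLES = ("pathogenic", "decoy_lc", "decoy_benign", "decoy_vus")


@dataclass(frozen=True)
class SimVariant:
    """One simulated variant: identity, annotations, per-population truth."""

    hgvs_c: str
    hgvs_p: str
    consequence: str
    true_af: dict  # population code -> true pathogenic allele frequency
    loftee: str = "HC"
    loftee_flags: tuple[str, ...] = ()
    clinvar: str = "absent"
    revel: float | None = None
    splice_impact: float | None = None
    provean: float | None = None
    intended_tier: str = "LikelyPathogenic"
    pm3: tuple[PM3Observation, ...] = ()
    role: str = "pathogenic"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for pop, p in self.true_af.items():
            if not 0.0 <= p <= 0.05:
                raise ValueError(f"true_af[{pop}]={p} outside [0, 0.05]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    populations: tuple[tuple[str, int], ...]
    genes: dict  # gene symbol -> tuple[SimVariant, ...]
    deterministic: bool = False
    engine: EngineConfig = field(default_factory=lambda: EngineConfig(pm2_threshold=0.01))

    def __post_init__(self) -> None:
        for code, n in self.populations:
            if n < 1:
                raise ValueError(f"population {code} size must be >= 1")

    def pm3_map(self) -> dict:
        return {
            (gene, v.hgvs_c): list(v.pm3)
            for gene, variants in self.genes.items()
            for v in variants
            if v.pm3
        }


@dataclass
class CohortTruth:
    """Ground truth: allele frequencies, realised genotypes, intended tiers,
    and the per-gene, per-population CF/pGP implied by the true AFs."""

    true_af: dict  # (gene, hgvs_c) -> {pop: p}
    genotype_counts: dict  # (gene, hgvs_c) -> {pop: (n_AA, n_Aa, n_aa)}
    intended_tiers: dict  # (gene, hgvs_c) -> tier
    roles: dict  # (gene, hgvs_c) -> role
    gene_cf: dict  # (gene, pop) -> true CF_G
    gene_pgp: dict  # (gene, pop) -> true pGP_G
    population_sizes: dict  # pop -> n individuals (GLOBAL = pooled)


def _het_rate(p: float) -> float:
    return 2.0 * p * (1.0 - p)


def _pooled_af(true_af: dict, sizes: dict) -> float:
    n_total = sum(sizes.values())
    return sum(sizes[pop] * true_af.get(pop, 0.0) for pop in sizes) / n_total


def sample_cohort(config: SimulationConfig) -> tuple[list[VariantRecord], CohortTruth]:
    """Draw the cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    sizes = dict(config.populations)
    sizes_with_global = {**sizes, "GLOBAL": sum(sizes.values())}

    records: list[VariantRecord] = []
    true_af, genotype_counts, intended, roles = {}, {}, {}, {}
    for gene in config.genes:
        for v in config.genes[gene]:
            key = (gene, v.hgvs_c)
            afs = {pop: v.true_af.get(pop, 0.0) for pop in sizes}
            afs["GLOBAL"] = _pooled_af(afs, sizes)
            true_af[key] = afs
            intended[key] = v.intended_tier
            roles[key] = v.role

            counts, genos = {}, {}
            for pop, n in sizes.items():
                p = afs[pop]
                probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
                if config.deterministic:
                    n_aa = round(n * probs[2])
                    n_het = round(n * probs[1])
                    geno = (n - n_het - n_aa, n_het, n_aa)
                else:
                    draw = rng.multinomial(n, probs)
                    geno = (int(draw[0]), int(draw[1]), int(draw[2]))
                genos[pop] = geno
                counts[pop] = PopulationCounts(
                    allele_count=geno[1] + 2 * geno[2],
                    allele_number=2 * n,
                    homozygous_count=geno[2],
                )
            genotype_counts[key] = genos
            records.append(
                VariantRecord(
                    gene=gene,
                    transcript="",
                    hgvs_c=v.hgvs_c,
                    hgvs_p=v.hgvs_p,
                    consequence=v.consequence,
                    loftee=v.loftee,
                    loftee_flags=v.loftee_flags,
                    clinvar=v.clinvar,
                    scores=InSilicoScores(
                        revel=v.revel,
                        splice_impact=v.splice_impact,
                        provean=v.provean,
                    ),
                    counts=synthesize_global(counts),
                )
            )

    gene_cf, gene_pgp = {}, {}
    for gene in config.genes:
        pathogenic = [v for v in config.genes[gene] if v.role == "pathogenic"]
        for pop in sizes_with_global:
            ps = [true_af[(gene, v.hgvs_c)][pop] for v in pathogenic]
            surviving = 1.0
            for p in ps:
                surviving *= 1.0 - _het_rate(p)
            gene_cf[(gene, pop)] = 1.0 - surviving
            gene_pgp[(gene, pop)] = sum(ps) ** 2

    truth = CohortTruth(
        true_af=true_af,
        genotype_counts=genotype_counts,
        intended_tiers=intended,
        roles=roles,
        gene_cf=gene_cf,
        gene_pgp=gene_pgp,
        population_sizes=sizes_with_global,
    )
    return records, truth


# ---------------------------------------------------------------------------
# recovery assessment

def carrier_frequency_tolerance(
    truth: CohortTruth, gene: str, pop: str, n_se: float = 5.0
) -> float:
    """Accumulated n_se-binomial-standard-error allowance for the gene's
    carrier frequency: each variant's heterozygote count is Bin(n, h)."""
    n = truth.population_sizes[pop]
    tol = 0.0
    for (g, _), afs in truth.true_af.items():
        if g != gene:
            continue
        if truth.roles[(g, _)] != "pathogenic":
            continue
        h = _het_rate(afs[pop])
        tol += n_se * math.sqrt(h * (1.0 - h) / n)
    return tol


def recovery_report(
    truth: CohortTruth, estimated: dict, n_se: float = 5.0
) -> pd.DataFrame:
    """Tabulate estimated vs true CF_G and pGP_G.

    `estimated` maps (gene, population) -> (cf, pgp). Returns one row per
    gene/population/quantity with the truth, the estimate, the relative
    error and the sampling-noise tolerance.
    """
    missing = set(truth.gene_cf) - set(estimated)
    extra = set(estimated) - set(truth.gene_cf)
    if missing or extra:
        raise ValueError(
            f"gene/population mismatch; missing={sorted(missing)} extra={sorted(extra)}"
        )
    rows = []
    for (gene, pop), (cf_est, pgp_est) in sorted(estimated.items()):
        cf_true = truth.gene_cf[(gene, pop)]
        pgp_true = truth.gene_pgp[(gene, pop)]
        cf_tol = carrier_frequency_tolerance(truth, gene, pop, n_se)
        q_true = math.sqrt(pgp_true)
        pgp_tol = (q_true + cf_tol / 2.0) ** 2 - pgp_true
        rows.append({
            "gene": gene, "population": pop, "quantity": "CF_G",
            "true": cf_true, "estimated": cf_est,
            "abs_error": abs(cf_est - cf_true),
            "rel_error": abs(cf_est - cf_true) / cf_true if cf_true else 0.0,
            "tolerance": cf_tol,
        })
        rows.append({
            "gene": gene, "population": pop, "quantity": "pGP_G",
            "true": pgp_true, "estimated": pgp_est,
            "abs_error": abs(pgp_est - pgp_true),
            "rel_error": abs(pgp_est - pgp_true) / pgp_true if pgp_true else 0.0,
            "tolerance": pgp_tol,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default study: the 12-gene panel at gnomAD-like scale

#: hand-derived intended tiers for the bundled recurrent-variant table,
#: given the bundled gene annotation and the synthetic evidence profile
#: (see docs/methods.md for the derivations)
_PM3_STRONG = (
    PM3Observation("fam1", "in_trans_confirmed", "pathogenic"),
    PM3Observation("fam2", "in_trans_confirmed", "pathogenic"),
)
_PM3_MODERATE = (
    PM3Observation("fam1", "homozygous", "none"),
    PM3Observation("fam2", "homozygous", "none"),
)

#: per-variant overrides: (extra PM3 evidence, intended tier)
_KNOWN_VARIANT_PLAN = {
    ("TPO", "c.483-1G>C"): ((), "Pathogenic"),
    ("DUOX2", "c.3693+1G>T"): ((), "Pathogenic"),
    ("TG", "c.886C>T"): (_PM3_STRONG, "Pathogenic"),
    ("DUOX2", "c.2895_2898delGTTC"): (_PM3_STRONG, "Pathogenic"),
    ("SLC26A7", "c.1893delT"): (_PM3_MODERATE, "LikelyPathogenic"),
    ("TSHB", "c.373delT"): (_PM3_MODERATE, "LikelyPathogenic"),
    ("TRHR", "c.1016delA"): (_PM3_MODERATE, "LikelyPathogenic"),
}

#: synthetic additions for panel genes absent from the recurrent-variant
#: table, at plausible rare-allele frequencies
_SYNTHETIC_VARIANTS = {
    "SLC5A5": [
        ("c.1000C>T", "p.Gln334Ter", "nonsense",
         {"AFR": 2e-5, "AMR": 8e-5, "ASJ": 2e-4, "EAS": 4e-4,
          "FIN": 6e-4, "NFE": 1e-4, "SAS": 5e-5}),
        ("c.272T>A", "p.Leu91Ter", "nonsense",
         {"EAS": 3e-4, "NFE": 2e-5}),
    ],
    "GLIS3": [
        ("c.1501delA", "p.Lys501ArgfsTer10", "frameshift",
         {"AFR": 8e-5, "EAS": 2e-4, "NFE": 2e-4, "SAS": 1e-5}),
        ("c.625C>T", "p.Arg209Ter", "nonsense",
         {"AMR": 5e-5, "FIN": 3e-4, "NFE": 1e-4}),
    ],
}

#: LOFTEE/benign/uncertain decoys that must never reach the PLPV set
_DECOYS = {
    "DUOX2": [
        SimVariant("c.900G>A", "p.Trp300Ter", "nonsense",
                   {"NFE": 2e-3, "AFR": 1e-3}, loftee="LC",
                   intended_tier="VUS", role="decoy_lc"),
        SimVariant("c.150C>A", "p.Asp50Glu", "missense",
                   {"NFE": 2e-2, "EAS": 1e-2}, loftee="NA", revel=0.9,
                   intended_tier="VUS", role="decoy_vus"),
    ],
    "TG": [
        SimVariant("c.3000C>A", "p.Tyr1000Ter", "nonsense",
                   {"EAS": 1e-3, "SAS": 5e-4}, loftee="HC",
                   loftee_flags=("NAGNAG_SITE",),
                   intended_tier="VUS", role="decoy_lc"),
    ],
    "TPO": [
        SimVariant("c.200A>G", "p.Asn67Ser", "missense",
                   {"NFE": 4e-3, "AFR": 3e-3}, loftee="NA", revel=0.2,
                   clinvar="BLB", intended_tier="Benign", role="decoy_benign"),
    ],
    "TSHR": [
        SimVariant("c.700A>G", "p.Met234Val", "missense",
                   {"NFE": 1e-3}, loftee="NA", revel=0.4,
                   intended_tier="VUS", role="decoy_vus"),
    ],
}

_AF_CAP = 5e-3  # default-study pathogenic AFs span 1e-5 .. 5e-3


def default_simulation_config(seed: int, deterministic: bool = False) -> SimulationConfig:
    """The default study: 12 panel genes, 7 ancestry groups at gnomAD
    v2.1.1 cohort sizes, true pathogenic AFs taken from the bundled
    recurrent-variant table (capped at 5e-3), plus synthetic rare
    variants for panel genes missing from that table and decoy variants
    exercising every filter."""
    df = load_known_plpv_afs()
    pops = [(code, n) for code, n in GNOMAD_V2_SIZES.items() if code != "GLOBAL"]

    genes: dict[str, list[SimVariant]] = {g: [] for g in GENES}
    for row in df.to_dict("records"):
        gene = row["gene"]
        afs = {
            code: min(float(row[f"AF_{code}"]), _AF_CAP)
            for code, _ in pops
            if float(row[f"AF_{code}"]) > 0
        }
        pm3, tier = _KNOWN_VARIANT_PLAN.get(
            (gene, row["hgvs_c"]),
            ((), "LikelyPathogenic") if row["consequence"] in
            ("nonsense", "frameshift", "splice_site") else
            (_PM3_STRONG, "LikelyPathogenic"),
        )
        is_null = row["consequence"] in ("nonsense", "frameshift", "splice_site")
        genes[gene].append(
            SimVariant(
                hgvs_c=row["hgvs_c"],
                hgvs_p=row["hgvs_p"],
                consequence=row["consequence"],
                true_af=afs,
                loftee="HC" if is_null else "NA",
                revel=0.9 if row["consequence"] == "missense" else None,
                splice_impact=0.9 if row["consequence"] == "splice_site" else None,
                provean=-4.0 if row["consequence"] == "inframe_indel" else None,
                intended_tier=tier,
                pm3=pm3,
            )
        )
    for gene, entries in _SYNTHETIC_VARIANTS.items():
        for hgvs_c, hgvs_p, consequence, afs in entries:
            genes[gene].append(
                SimVariant(hgvs_c, hgvs_p, consequence, afs,
                           intended_tier="LikelyPathogenic")
            )
    for gene, decoys in _DECOYS.items():
        genes[gene].extend(decoys)

    return SimulationConfig(
        seed=seed,
        populations=tuple(pops),
        genes={g: tuple(vs) for g, vs in genes.items()},
        deterministic=deterministic,
    )


def default_gene_specs_for_simulation() -> dict[str, GeneSpec]:
    return default_gene_specs()
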
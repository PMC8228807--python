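"""Carrier frequency and predicted genetic prevalence statistics.

For an autosomal recessive disease, the heterozygous-only allele
frequency of a variant V in a population is

    AF_V = (allele_count - 2 * homozygous_count) / allele_number

(homozygotes are stripped because affected individuals are assumed not
to be carriers in the healthy reference cohort), and the per-variant
carrier frequency is CF_V = 2 * AF_V. Variants combine into a per-gene
carrier frequency by the complement product

    CF_G = 1 - prod_k (1 - CF_V_k)

and, under random mating (Hardy-Weinberg), a per-gene predicted birth
prevalence

    pGP_G = sum_{i,k} CF_V_i * CF_V_k / 4 = (sum_k CF_V_k / 2)^2,

i.e. q^2 with the gene-level pathogenic allele frequency q approximated
by sum(CF_V)/2. Cross-gene population totals are sums of the per-gene
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variant_io import PopulationCounts


class UndefinedFrequencyError(ZeroDivisionError):
    """allele_number is zero: frequency undefined, caller must skip."""


def allele_frequency_het(c: PopulationCounts) -> float:
    """Heterozygous-only allele frequency (homozygote-stripped)."""
    if c.allele_number == 0:
        raise UndefinedFrequencyError("allele_number is zero")
    return (c.allele_count - 2 * c.homozygous_count) / c.allele_number


def carrier_frequency_variant(af: float) -> float:
    """CF_V = 2 * AF_V: each heterozygote carries one of 2N alleles."""
    if not 0.0 <= af <= 0.5:
        raise ValueError(
            f"heterozygous allele frequency must lie in [0, 0.5], got {af}"
        )
    return 2.0 * af


def carrier_frequency_gene(cfs: list[float]) -> float:
    """Complement-product combination over the gene's variants."""
    out = 1.0
    for cf in cfs:
        if not 0.0 <= cf <= 1.0:
            raise ValueError(f"carrier frequency {cf} outside [0, 1]")
        out *= 1.0 - cf
    return 1.0 - out


def pgp_gene(cfs: list[float]) -> float:
    """Predicted genetic prevalence (sum_k CF_k / 2)^2: the ordered
    variant-pair double sum of CF_i*CF_k/4 in closed form."""
    for cf in cfs:
        if not 0.0 <= cf <= 1.0:
            raise ValueError(f"carrier frequency {cf} outside [0, 1]")
    q = sum(cfs) / 2.0
    return q * q


def pgp_gene_pairwise(cfs: list[float]) -> float:
    """Brute-force ordered-pair double sum; independent oracle for
    :func:`pgp_gene`, kept as an explicit O(n^2) loop."""
    total = 0.0
    for cf_i in cfs:
        for cf_k in cfs:
            total += cf_i * cf_k / 4.0
    return total


@dataclass(frozen=True)
class VariantFrequency:
    af: float
    cf: float

    def __post_init__(self) -> None:
        if self.af < 0:
            raise ValueError("AF_V must be non-negative")
        if abs(self.cf - 2 * self.af) > 1e-15:
            raise ValueError("CF_V must equal 2*AF_V")


def variant_frequency(c: PopulationCounts) -> VariantFrequency:
    af = allele_frequency_het(c)
    return VariantFrequency(af=af, cf=carrier_frequency_variant(af))


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene, per-population carrier frequency and prevalence."""

    gene: str
    population: str
    cf: float
    pgp: float
    variant_cfs: tuple[float, ...] = ()

    @property
    def n_plpv(self) -> int:
        return len(self.variant_cfs)


def summarize_gene(gene: str, population: str, cfs: list[float]) -> GeneSummary:
    return GeneSummary(
        gene=gene,
        population=population,
        cf=carrier_frequency_gene(cfs),
        pgp=pgp_gene(cfs),
        variant_cfs=tuple(cfs),
    )


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    total_cf: float
    total_pgp: float
    per_gene: tuple[GeneSummary, ...] = ()


def population_totals(
    gene_summaries: list[GeneSummary],
    population: str,
    expected_genes: list[str] | None = None,
) -> PopulationSummary:
    """Cross-gene totals for one population: plain sums of per-gene CF_G
    and pGP_G (carriers of different genes overlap negligibly at these
    frequencies, and a recessive disease needs both alleles in one gene)."""
    mine = [s for s in gene_summaries if s.population == population]
    if expected_genes is not None:
        missing = sorted(set(expected_genes) - {s.gene for s in mine})
        if missing:
            raise ValueError(
                f"missing gene summaries for {population}: {', '.join(missing)}"
            )
    return PopulationSummary(
        population=population,
        total_cf=sum(s.cf for s in mine),
        total_pgp=sum(s.pgp for s in mine),
        per_gene=tuple(mine),
    )


def format_prevalence(p: float) -> str:
    """Render a birth-prevalence probability as 'X per 100,000 (1:N)'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence {p} outside [0, 1]")
    if p == 0:
        return "0.00 per 100,000 (1:inf)"
    return f"{p * 1e5:.2f} per 100,000 (1:{round(1 / p)})"
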
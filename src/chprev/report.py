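"""End-to-end orchestration: classify -> filter -> compute -> report.

Produces four artefacts per run:

(a) per-gene, per-population PLPV counts (a variant counts in a
    population when its heterozygous allele frequency there is positive);
(b) the PLPV list with per-population allele frequencies above a display
    threshold (default global AF > 1e-4);
(c) per-population, per-gene carrier-frequency / prevalence tables with
    cross-gene totals;
(d) a JSON summary block: total PLPV count, consequence-class
    percentages, ClinVar-registered fraction.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .acmg import ClassificationResult, classify_all, derive_pm2_threshold
from .genespec import EngineConfig, GeneSpec, default_gene_specs, load_gene_specs
from .populations import PopulationRegistry, default_registry
from .prevalence import (
    GeneSummary,
    UndefinedFrequencyError,
    allele_frequency_het,
    carrier_frequency_variant,
    format_prevalence,
    population_totals,
    summarize_gene,
)
from .variant_io import VariantRecord, gene_summary_row, read_variant_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    dialect: str = "tsv"
    gene_config: str | None = None  # None -> bundled 12-gene panel
    populations: tuple[str, ...] | None = None  # None -> registry default
    combining_mode: str = "points"
    pm2_threshold: float | None = None
    pm2_derive: bool = False
    display_af: float = 1e-4
    output_dir: str = "chprev_out"

    def __post_init__(self) -> None:
        if self.pm2_threshold is not None and self.pm2_derive:
            raise ValueError("explicit PM2 threshold and --pm2-derive are mutually exclusive")


def variant_cf(record: VariantRecord, population: str) -> float | None:
    """Heterozygous carrier frequency of one variant in one population,
    or None when the population has no counts / no coverage."""
    counts = record.counts.get(population)
    if counts is None or counts.allele_number == 0:
        return None
    return carrier_frequency_variant(allele_frequency_het(counts))


def gene_summaries(
    plpvs: list[VariantRecord],
    genes: list[str],
    populations: list[str],
) -> list[GeneSummary]:
    by_gene = {g: [r for r in plpvs if r.gene == g] for g in genes}
    out = []
    for pop in populations:
        for gene in genes:
            cfs = []
            for r in by_gene[gene]:
                cf = variant_cf(r, pop)
                if cf is not None and cf > 0:
                    cfs.append(cf)
            out.append(summarize_gene(gene, pop, cfs))
    return out


def summarize_classes(
    plpvs: list[tuple[VariantRecord, ClassificationResult]]
) -> pd.DataFrame:
    """Consequence-class breakdown of the PLPV set, percents over the PLPV
    total to 1 dp, ordered by count descending then class name."""
    counts: dict[str, int] = {}
    for record, _ in plpvs:
        counts[record.consequence] = counts.get(record.consequence, 0) + 1
    total = sum(counts.values())
    rows = [
        {"consequence": c, "count": n, "percent": round(100.0 * n / total, 1)}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["consequence", "count", "percent"])


@dataclass
class ReportBundle:
    plpv_counts: pd.DataFrame
    representative: pd.DataFrame
    cf_pgp: pd.DataFrame
    summary: dict
    classified: list = field(default_factory=list)
    gene_summaries: list = field(default_factory=list)


def run_pipeline(
    cfg: RunConfig,
    pm3_observations: dict | None = None,
    segregation: dict | None = None,
    registry: PopulationRegistry | None = None,
) -> ReportBundle:
    registry = registry or default_registry()
    specs: dict[str, GeneSpec] = (
        load_gene_specs(cfg.gene_config) if cfg.gene_config else default_gene_specs()
    )
    genes = list(specs)
    populations = list(cfg.populations) if cfg.populations else registry.codes

    records = read_variant_table(cfg.input_path, cfg.dialect)
    logger.info("read %d variant records from %s", len(records), cfg.input_path)

    threshold = cfg.pm2_threshold
    if cfg.pm2_derive:
        known = [r for r in records if r.clinvar == "PLP"]
        afs = []
        for r in known:
            try:
                afs.append(allele_frequency_het(r.counts["GLOBAL"]))
            except (KeyError, UndefinedFrequencyError):
                continue
        threshold = derive_pm2_threshold(afs)
        logger.info("derived PM2 threshold %g from %d known pathogenic variants",
                    threshold, len(afs))
    engine = EngineConfig(
        pm2_threshold=threshold if threshold is not None else EngineConfig.pm2_threshold,
        combining_mode=cfg.combining_mode,
    )

    classified = classify_all(
        records, specs, engine,
        pm3_observations=pm3_observations, segregation=segregation,
    )
    plpvs = [(r, c) for r, c in classified if c.is_plpv]
    for r, c in classified:
        if not c.is_plpv:
            reason = c.short_circuit or f"tier {c.tier} below LikelyPathogenic"
            logger.info("filtered %s %s: %s", r.gene, r.hgvs_c, reason)
    plpv_records = [r for r, _ in plpvs]

    # (a) per-gene per-population PLPV counts
    count_rows = []
    for gene in genes:
        row = {"gene": gene}
        for pop in populations:
            row[pop] = sum(
                1 for r in plpv_records
                if r.gene == gene and (variant_cf(r, pop) or 0.0) > 0
            )
        count_rows.append(row)
    plpv_counts = pd.DataFrame(count_rows, columns=["gene"] + populations)

    # (b) representative PLPVs above the display threshold
    rep_rows = []
    for r in plpv_records:
        global_cf = variant_cf(r, "GLOBAL")
        if global_cf is None or global_cf / 2.0 <= cfg.display_af:
            continue
        row = {"gene": r.gene, "hgvs_c": r.hgvs_c, "hgvs_p": r.hgvs_p}
        for pop in populations:
            cf = variant_cf(r, pop)
            row[f"AF_{pop}"] = "" if cf is None else f"{cf / 2.0:.5f}"
        rep_rows.append(row)
    representative = pd.DataFrame(
        rep_rows, columns=["gene", "hgvs_c", "hgvs_p"] + [f"AF_{p}" for p in populations]
    )

    # (c) CF / pGP per gene and population, with cross-gene totals
    summaries = gene_summaries(plpv_records, genes, populations)
    cf_rows = [gene_summary_row(s) for s in summaries]
    for pop in populations:
        tot = population_totals(summaries, pop, expected_genes=genes)
        cf_rows.append({
            "gene": "TOTAL", "population": pop,
            "n_plpv": sum(s.n_plpv for s in tot.per_gene),
            "cf_percent": f"{100.0 * tot.total_cf:.2f}",
            "pgp_per_100k": f"{tot.total_pgp * 1e5:.2f}",
            "pgp_ratio": format_prevalence(tot.total_pgp).split("(")[-1].rstrip(")"),
        })
    cf_pgp = pd.DataFrame(
        cf_rows,
        columns=["gene", "population", "n_plpv", "cf_percent", "pgp_per_100k", "pgp_ratio"],
    )

    # (d) summary block
    class_table = summarize_classes(plpvs)
    n_plpv = len(plpv_records)
    n_clinvar = sum(1 for r in plpv_records if r.clinvar == "PLP")
    summary = {
        "n_variants_input": len(records),
        "n_plpv": n_plpv,
        "consequence_classes": class_table.to_dict("records"),
        "clinvar_registered": {
            "count": n_clinvar,
            "percent": round(100.0 * n_clinvar / n_plpv, 1) if n_plpv else 0.0,
        },
        "pm2_threshold": engine.pm2_threshold,
        "combining_mode": engine.combining_mode,
    }

    return ReportBundle(
        plpv_counts=plpv_counts,
        representative=representative,
        cf_pgp=cf_pgp,
        summary=summary,
        classified=classified,
        gene_summaries=summaries,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the four report artefacts; on failure remove partial output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        bundle.plpv_counts.to_csv(out / "plpv_counts.tsv", sep="\t", index=False)
        bundle.representative.to_csv(out / "representative_plpvs.tsv", sep="\t", index=False)
        bundle.cf_pgp.to_csv(out / "cf_pgp.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(bundle.summary, indent=2) + "\n")
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
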
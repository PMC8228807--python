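"""Read, validate and write population-stratified variant summary tables.

Supports two dialects:

* a canonical TSV with columns ``gene, transcript, hgvs_c, hgvs_p,
  consequence, loftee, loftee_flags, clinvar, revel, splice_impact,
  provean`` followed by ``AC_<pop>/AN_<pop>/nhomalt_<pop>`` triplets
  (mirroring gnomAD export headers so real exports map with a rename
  step), and
* VCF 4.2 in the gnomAD v2 dialect, with per-population INFO keys
  ``AC_<pop>``, ``AN_<pop>``, ``nhomalt_<pop>`` plus annotation keys for
  gene / consequence / LOFTEE / scores.

Variants are identified by ``(gene, hgvs_c)``; HGVS strings are treated
as opaque keys (no normalisation — upstream tools own nomenclature).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .populations import POPULATION_CODES

logger = logging.getLogger(__name__)

CONSEQUENCES = (
    "nonsense",
    "frameshift",
    "splice_site",
    "missense",
    "inframe_indel",
    "initiation_loss",
    "other",
)
#: consequence classes treated as putative loss-of-function ("null") variants
NULL_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site"})

LOFTEE_VALUES = ("HC", "LC", "NA")
CLINVAR_VALUES = ("PLP", "VUS", "BLB", "absent")

ANNOTATION_COLUMNS = [
    "gene", "transcript", "hgvs_c", "hgvs_p", "consequence",
    "loftee", "loftee_flags", "clinvar", "revel", "splice_impact", "provean",
]


class SchemaError(ValueError):
    """A mandatory column or INFO key is missing from the input."""


class RowParseError(ValueError):
    """A row could not be parsed into a VariantRecord."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class PopulationCounts:
    """Allele-count triplet for one variant in one population.

    allele_count    number of variant alleles observed
    allele_number   number of genotyped alleles (2 x individuals)
    homozygous_count number of homozygous-alternate individuals (nhomalt)
    """

    allele_count: int
    allele_number: int
    homozygous_count: int = 0

    def __post_init__(self) -> None:
        if min(self.allele_count, self.allele_number, self.homozygous_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.allele_count > self.allele_number:
            raise ValueError(
                f"allele_count {self.allele_count} exceeds allele_number {self.allele_number}"
            )
        if 2 * self.homozygous_count > self.allele_count:
            raise ValueError(
                f"2*homozygous_count {2 * self.homozygous_count} exceeds "
                f"allele_count {self.allele_count}"
            )
        if self.allele_number % 2:
            raise ValueError(f"allele_number {self.allele_number} is odd")


@dataclass(frozen=True)
class InSilicoScores:
    """In-silico predictor scores; any of them may be missing (None)."""

    revel: float | None = None
    splice_impact: float | None = None
    provean: float | None = None

    def __post_init__(self) -> None:
        for name in ("revel", "splice_impact"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class VariantRecord:
    """One summary row: identity, annotations and per-population counts."""

    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: str = ""
    consequence: str = "other"
    loftee: str = "NA"
    loftee_flags: tuple[str, ...] = ()
    clinvar: str = "absent"
    scores: InSilicoScores = field(default_factory=InSilicoScores)
    counts: dict[str, PopulationCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.hgvs_c:
            raise ValueError("hgvs_c must be non-empty")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; accepted: {CONSEQUENCES}"
            )
        if self.loftee not in LOFTEE_VALUES:
            raise ValueError(f"loftee must be one of {LOFTEE_VALUES}")
        if self.clinvar not in CLINVAR_VALUES:
            raise ValueError(f"clinvar must be one of {CLINVAR_VALUES}")
        for code in self.counts:
            if code not in POPULATION_CODES:
                raise ValueError(f"unknown population code {code!r}")
        subs = [c for c in self.counts if c != "GLOBAL"]
        if subs and "GLOBAL" not in self.counts:
            raise ValueError("GLOBAL counts required when subpopulation counts present")
        if subs:
            max_sub = max(self.counts[c].allele_count for c in subs)
            if self.counts["GLOBAL"].allele_count < max_sub:
                raise ValueError(
                    "GLOBAL allele_count below a subpopulation allele_count "
                    "(pooled cohort must be a superset)"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_c)

    @property
    def is_null_variant(self) -> bool:
        return self.consequence in NULL_CONSEQUENCES

    def pooled_consistency_warning(self) -> str | None:
        """gnomAD's pool includes unlisted ancestries, so GLOBAL AC may exceed
        the subpopulation sum; the reverse indicates inconsistent counts."""
        subs = [c for c in self.counts if c != "GLOBAL"]
        if not subs:
            return None
        total = sum(self.counts[c].allele_count for c in subs)
        if self.counts["GLOBAL"].allele_count < total:
            return (
                f"{self.gene} {self.hgvs_c}: GLOBAL allele_count "
                f"{self.counts['GLOBAL'].allele_count} below subpopulation sum {total}"
            )
        return None


def synthesize_global(counts: dict[str, PopulationCounts]) -> dict[str, PopulationCounts]:
    """Add a GLOBAL triplet as the subpopulation sum when absent.

    An approximation: the true gnomAD pool also contains ancestries not
    listed here ("other"), so a synthesized GLOBAL is a lower bound.
    """
    if "GLOBAL" in counts or not counts:
        return dict(counts)
    out = dict(counts)
    out["GLOBAL"] = PopulationCounts(
        allele_count=sum(c.allele_count for c in counts.values()),
        allele_number=sum(c.allele_number for c in counts.values()),
        homozygous_count=sum(c.homozygous_count for c in counts.values()),
    )
    return out


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_int(value: str, what: str, row: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise RowParseError(row, f"non-integer {what}: {value!r}") from None


def _parse_optional_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan", "None", "."):
        return None
    return float(s)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() in ("", ".", "NA")


def _record_from_fields(fields: dict, triplets: dict[str, tuple], row: int) -> VariantRecord:
    consequence = str(fields.get("consequence", "")).strip()
    if consequence not in CONSEQUENCES:
        raise RowParseError(
            row, f"unknown consequence label {consequence!r}; accepted: {CONSEQUENCES}"
        )
    loftee_raw = fields.get("loftee")
    loftee = "NA" if _is_missing(loftee_raw) else str(loftee_raw).strip()
    flags_raw = fields.get("loftee_flags", "")
    flags = () if _is_missing(flags_raw) else tuple(
        f for f in str(flags_raw).split(",") if f
    )
    clinvar_raw = fields.get("clinvar")
    clinvar = "absent" if _is_missing(clinvar_raw) else str(clinvar_raw).strip()
    try:
        scores = InSilicoScores(
            revel=_parse_optional_float(fields.get("revel")),
            splice_impact=_parse_optional_float(fields.get("splice_impact")),
            provean=_parse_optional_float(fields.get("provean")),
        )
    except ValueError as exc:
        raise RowParseError(row, str(exc)) from None

    counts: dict[str, PopulationCounts] = {}
    for pop, (ac, an, hom) in triplets.items():
        if _is_missing(ac) or _is_missing(an) or _is_missing(hom):
            # missing triplet -> population skipped (AF undefined), never zero
            continue
        try:
            counts[pop] = PopulationCounts(
                allele_count=_parse_int(ac, f"AC_{pop}", row),
                allele_number=_parse_int(an, f"AN_{pop}", row),
                homozygous_count=_parse_int(hom, f"nhomalt_{pop}", row),
            )
        except ValueError as exc:
            if isinstance(exc, RowParseError):
                raise
            raise RowParseError(row, f"{pop}: {exc}") from None
    counts = synthesize_global(counts)

    try:
        return VariantRecord(
            gene="" if _is_missing(fields.get("gene")) else str(fields["gene"]).strip(),
            transcript="" if _is_missing(fields.get("transcript")) else str(fields["transcript"]).strip(),
            hgvs_c="" if _is_missing(fields.get("hgvs_c")) else str(fields["hgvs_c"]).strip(),
            hgvs_p="" if _is_missing(fields.get("hgvs_p")) else str(fields["hgvs_p"]).strip(),
            consequence=consequence,
            loftee=loftee,
            loftee_flags=flags,
            clinvar=clinvar,
            scores=scores,
            counts=counts,
        )
    except ValueError as exc:
        raise RowParseError(row, str(exc)) from None


# ---------------------------------------------------------------------------
# readers

def read_variant_table(
    path: str | Path, dialect: str = "tsv"
) -> list[VariantRecord]:
    """Parse a variant summary table; rows violating count invariants are
    dropped with a logged row-level diagnostic (see
    :func:`read_variant_table_with_diagnostics` to capture them)."""
    records, issues = read_variant_table_with_diagnostics(path, dialect)
    for issue in issues:
        logger.warning("%s: %s", path, issue)
    return records


def read_variant_table_with_diagnostics(
    path: str | Path, dialect: str = "tsv"
) -> tuple[list[VariantRecord], list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _read_tsv(path: Path) -> tuple[list[VariantRecord], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [
        c if c.split("_")[0] not in ("AC", "AN", "nhomalt") else
        "_".join([c.split("_")[0], *map(str.upper, c.split("_")[1:])])
        for c in df.columns
    ]
    for col in ("gene", "transcript", "hgvs_c", "consequence"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    pops = sorted({
        c.split("_", 1)[1] for c in df.columns
        if c.startswith(("AC_", "AN_", "nhomalt_"))
    })
    if not pops:
        raise SchemaError("no AC_<pop>/AN_<pop>/nhomalt_<pop> columns found")
    for pop in pops:
        for prefix in ("AC", "AN", "nhomalt"):
            if f"{prefix}_{pop}" not in df.columns:
                raise SchemaError(f"missing mandatory column '{prefix}_{pop}'")

    records, issues = [], []
    for i, rowdict in enumerate(df.to_dict("records"), start=1):
        triplets = {
            pop: (rowdict[f"AC_{pop}"], rowdict[f"AN_{pop}"], rowdict[f"nhomalt_{pop}"])
            for pop in pops
        }
        try:
            rec = _record_from_fields(rowdict, triplets, i)
        except RowParseError as exc:
            issues.append(str(exc))
            continue
        warning = rec.pooled_consistency_warning()
        if warning:
            issues.append(f"warning: {warning}")
        records.append(rec)
    return records, issues


_VCF_ANNOTATION_KEYS = {
    "gene": "GENE", "transcript": "TRANSCRIPT", "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP", "consequence": "CSQ_CLASS", "loftee": "LOFTEE",
    "loftee_flags": "LOFTEE_FLAGS", "clinvar": "CLINVAR",
    "revel": "REVEL", "splice_impact": "SPLICE_IMPACT", "provean": "PROVEAN",
}


def _read_vcf(path: Path) -> tuple[list[VariantRecord], list[str]]:
    records, issues = [], []
    with pysam.VariantFile(str(path)) as vcf:
        info_keys = {k.upper(): k for k in vcf.header.info.keys()}
        for i, line in enumerate(vcf, start=1):
            fields = {}
            for field_name, key in _VCF_ANNOTATION_KEYS.items():
                actual = info_keys.get(key)
                raw = line.info.get(actual, None) if actual else None
                if isinstance(raw, tuple):
                    raw = ",".join(str(x) for x in raw)
                fields[field_name] = raw
            triplets = {}
            for pop in POPULATION_CODES:
                suffix = "" if pop == "GLOBAL" else f"_{pop}"
                keys = [f"AC{suffix}", f"AN{suffix}", f"nhomalt{suffix}"]
                vals = []
                for k in keys:
                    actual = info_keys.get(k.upper())
                    v = line.info.get(actual, None) if actual else None
                    if isinstance(v, tuple):
                        v = v[0]
                    vals.append(v)
                if all(v is not None for v in vals):
                    triplets[pop] = tuple(vals)
            try:
                rec = _record_from_fields(fields, triplets, i)
            except RowParseError as exc:
                issues.append(str(exc))
                continue
            warning = rec.pooled_consistency_warning()
            if warning:
                issues.append(f"warning: {warning}")
            records.append(rec)
    return records, issues


# ---------------------------------------------------------------------------
# variant-table writing (canonical TSV)

def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Emit the canonical TSV; exact round-trip with :func:`read_variant_table`."""
    records = list(records)
    pops = [p for p in POPULATION_CODES if any(p in r.counts for r in records)]
    columns = ANNOTATION_COLUMNS + [
        f"{prefix}_{pop}" for pop in pops for prefix in ("AC", "AN", "nhomalt")
    ]
    rows = []
    for r in records:
        row = {
            "gene": r.gene, "transcript": r.transcript,
            "hgvs_c": r.hgvs_c, "hgvs_p": r.hgvs_p,
            "consequence": r.consequence, "loftee": r.loftee,
            "loftee_flags": ",".join(r.loftee_flags),
            "clinvar": r.clinvar,
            "revel": "" if r.scores.revel is None else repr(r.scores.revel),
            "splice_impact": "" if r.scores.splice_impact is None else repr(r.scores.splice_impact),
            "provean": "" if r.scores.provean is None else repr(r.scores.provean),
        }
        for pop in pops:
            if pop in r.counts:
                c = r.counts[pop]
                row[f"AC_{pop}"] = c.allele_count
                row[f"AN_{pop}"] = c.allele_number
                row[f"nhomalt_{pop}"] = c.homozygous_count
            else:
                row[f"AC_{pop}"] = row[f"AN_{pop}"] = row[f"nhomalt_{pop}"] = ""
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report writing

def _sigfig_percent(x: float, sig: int = 3) -> str:
    """Render a probability as percent with `sig` significant figures,
    trailing zeros preserved (0.018 -> '1.80')."""
    pct = 100.0 * x
    if pct == 0:
        return "0.00"
    exponent = math.floor(math.log10(abs(pct)))
    decimals = max(0, sig - 1 - exponent)
    return f"{pct:.{decimals}f}"


def format_ratio(p: float) -> str:
    return "1:inf" if p == 0 else f"1:{round(1 / p)}"


def gene_summary_row(summary) -> dict:
    """Fixed-precision serialisation of one GeneSummary (see prevalence)."""
    return {
        "gene": summary.gene,
        "population": summary.population,
        "n_plpv": summary.n_plpv,
        "cf_percent": _sigfig_percent(summary.cf),
        "pgp_per_100k": f"{summary.pgp * 1e5:.2f}",
        "pgp_ratio": format_ratio(summary.pgp),
    }


REPORT_COLUMNS = ["gene", "population", "n_plpv", "cf_percent", "pgp_per_100k", "pgp_ratio"]


def write_report(summaries, path: str | Path, format: str = "tsv") -> None:
    """Write per-gene, per-population CF/pGP summaries.

    Deterministic column/key order; CF as percent to 3 significant
    figures, pGP both as per-100,000 (2 dp) and as a 1:N ratio.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("summaries must be non-empty")
    rows = [gene_summary_row(s) for s in summaries]
    path = Path(path)
    if format == "tsv":
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps({"summaries": rows}, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> list[dict]:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        rows = df.to_dict("records")
        for row in rows:
            row["n_plpv"] = int(row["n_plpv"])
        return rows
    if format == "json":
        return json.loads(path.read_text())["summaries"]
    raise ValueError(f"unknown report format {format!r}")
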
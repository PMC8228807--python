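"""Gene-level annotation needed by the loss-of-function decision tree.

Each gene carries the MANE transcript, coding length, the
nonsense-mediated-decay (NMD) boundary for the 50-nt rule, curated
critical-domain intervals, and the presumed disease mechanism. A bundled
YAML covers the twelve autosomal recessive congenital hypothyroidism
genes; every value is overridable from a user config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


@dataclass(frozen=True)
class DomainInterval:
    """A critical functional domain as an amino-acid range [start, end]."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid domain interval [{self.start}, {self.end}]")

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene annotation driving PVS1/PM1 evaluation.

    coding_length_aa    protein length in amino acids (stop excluded)
    last_junction_cds   coding-nucleotide offset of the last exon-exon
                        junction; truncations more than 50 nt upstream of
                        it are predicted to trigger NMD (50-nt rule)
    mechanism           'loss_of_function' enables the PVS1 tree
    """

    gene: str
    transcript: str
    coding_length_aa: int
    last_junction_cds: int
    domains: tuple[DomainInterval, ...] = ()
    mechanism: str = "loss_of_function"

    def __post_init__(self) -> None:
        if self.coding_length_aa < 1:
            raise ValueError("coding_length_aa must be positive")
        if not 0 <= self.last_junction_cds <= 3 * self.coding_length_aa:
            raise ValueError(
                f"NMD boundary {self.last_junction_cds} outside coding region "
                f"(0..{3 * self.coding_length_aa})"
            )
        for d in self.domains:
            if d.end > self.coding_length_aa:
                raise ValueError(
                    f"domain [{d.start}, {d.end}] exceeds coding length "
                    f"{self.coding_length_aa}"
                )
        if self.mechanism not in ("loss_of_function", "other"):
            raise ValueError("mechanism must be 'loss_of_function' or 'other'")

    def nmd_predicted(self, cds_position: int) -> bool:
        """50-nt rule: a premature stop escapes NMD when it falls within the
        last exon or within 50 nt upstream of the final junction."""
        return cds_position <= self.last_junction_cds - 50

    def in_domain(self, residue: int) -> bool:
        return any(residue in d for d in self.domains)

    def domain_overlap(self, start_residue: int) -> bool:
        """Does the region from `start_residue` to the C-terminus touch a
        critical domain?"""
        return any(d.end >= start_residue for d in self.domains)


def _spec_from_mapping(gene: str, m: dict) -> GeneSpec:
    domains = tuple(
        DomainInterval(int(d["start"]), int(d["end"]), str(d.get("label", "")))
        for d in m.get("domains", [])
    )
    return GeneSpec(
        gene=gene,
        transcript=str(m.get("transcript", "")),
        coding_length_aa=int(m["coding_length_aa"]),
        last_junction_cds=int(m["last_junction_cds"]),
        domains=domains,
        mechanism=str(m.get("mechanism", "loss_of_function")),
    )


def load_gene_specs(path: str | Path) -> dict[str, GeneSpec]:
    """Load a ``genes:`` YAML mapping gene symbol -> annotation."""
    data = yaml.safe_load(Path(path).read_text())
    return {g: _spec_from_mapping(g, m) for g, m in data["genes"].items()}


def default_gene_specs() -> dict[str, GeneSpec]:
    """The bundled 12-gene congenital hypothyroidism panel."""
    with resources.as_file(resources.files("chprev.data") / "genes.yaml") as p:
        return load_gene_specs(p)


@dataclass(frozen=True)
class EngineConfig:
    """Thresholds and score cut-offs for the evidence engine.

    Only the REVEL missense cut-off (0.75, strict >) is fixed by the
    upstream classification protocol; the splice and PROVEAN cut-offs and
    the PP1/PM3 tables are explicit, overridable defaults.
    """

    pm2_threshold: float = 0.0003
    pm2_population: str = "GLOBAL"
    revel_cutoff: float = 0.75
    splice_impact_cutoff: float = 0.2
    provean_cutoff: float = -2.5
    pvs1_protein_fraction: float = 0.10
    # SVI-style per-proband points for the in-trans (PM3) code
    pm3_points: dict = field(default_factory=lambda: {
        ("in_trans_confirmed", "pathogenic"): 1.0,
        ("in_trans_confirmed", "likely_pathogenic"): 0.5,
        ("homozygous", "none"): 0.5,
        ("phase_unknown", "pathogenic"): 0.25,
        ("phase_unknown", "likely_pathogenic"): 0.25,
    })
    pm3_strength_cutoffs: tuple = ((4.0, "VeryStrong"), (2.0, "Strong"),
                                   (1.0, "Moderate"), (0.5, "Supporting"))
    # informative-meioses thresholds for co-segregation (PP1)
    pp1_cutoffs: tuple = ((7, "Strong"), (5, "Moderate"), (3, "Supporting"))
    combining_mode: str = "points"
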
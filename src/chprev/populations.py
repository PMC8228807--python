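"""Population registry for gnomAD-style ancestry-stratified cohorts.

The seven continental ancestry groups of gnomAD v2.1.1 plus the pooled
global cohort. Cohort sizes are numbers of individuals (alleles = 2n).
"""

from __future__ import annotations

from dataclasses import dataclass

POPULATION_CODES = ("AFR", "AMR", "ASJ", "EAS", "FIN", "NFE", "SAS", "GLOBAL")

#: gnomAD v2.1.1 exomes+genomes cohort sizes (individuals per ancestry group).
GNOMAD_V2_SIZES = {
    "AFR": 12487,
    "AMR": 17720,
    "ASJ": 5185,
    "EAS": 9977,
    "FIN": 12562,
    "NFE": 64603,
    "SAS": 15308,
    "GLOBAL": 141456,
}


@dataclass(frozen=True)
class Population:
    """One ancestry group with its cohort size in individuals."""

    code: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.code not in POPULATION_CODES:
            raise ValueError(
                f"unknown population code {self.code!r}; expected one of {POPULATION_CODES}"
            )
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")

    @property
    def allele_number(self) -> int:
        return 2 * self.n_individuals


class PopulationRegistry:
    """Unique-code collection of populations; GLOBAL is always present."""

    def __init__(self, populations: list[Population] | None = None):
        pops = populations if populations is not None else [
            Population(code, n) for code, n in GNOMAD_V2_SIZES.items()
        ]
        codes = [p.code for p in pops]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate population codes in registry")
        if "GLOBAL" not in codes:
            raise ValueError("registry must contain the GLOBAL population")
        self._pops = {p.code: p for p in pops}

    def __getitem__(self, code: str) -> Population:
        return self._pops[code.upper()]

    def __contains__(self, code: str) -> bool:
        return code.upper() in self._pops

    def __iter__(self):
        return iter(self._pops.values())

    @property
    def codes(self) -> list[str]:
        return list(self._pops)

    @property
    def subpopulation_codes(self) -> list[str]:
        return [c for c in self._pops if c != "GLOBAL"]


def default_registry() -> PopulationRegistry:
    """The gnomAD v2.1.1 cohort (7 ancestry groups + pooled global)."""
    return PopulationRegistry()
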
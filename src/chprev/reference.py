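"""Bundled reference inputs: published gnomAD v2.1.1 panel estimates.

Two small text tables ship with the package:

* ``known_plpv_afs.tsv`` — per-population allele frequencies of 27
  recurrent pathogenic / likely pathogenic variants in the 12-gene
  congenital hypothyroidism panel (global AF > 1e-4), as reported from
  gnomAD v2.1.1;
* ``reference_summary.yaml`` — the published per-gene and per-population
  carrier-frequency / prevalence estimates and variant tallies the
  pipeline's outputs are compared against.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .populations import PopulationRegistry, default_registry
from .variant_io import InSilicoScores, PopulationCounts, VariantRecord

GENES = (
    "SLC5A5", "TPO", "TG", "IYD", "DUOXA2", "DUOX2",
    "TSHR", "SLC26A7", "GLIS3", "FOXE1", "TSHB", "TRHR",
)


def _data_path(name: str):
    return resources.files("chprev.data") / name


def load_reference_summary() -> dict:
    with resources.as_file(_data_path("reference_summary.yaml")) as p:
        return yaml.safe_load(Path(p).read_text())


def load_known_plpv_afs() -> pd.DataFrame:
    with resources.as_file(_data_path("known_plpv_afs.tsv")) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def known_plpv_records(
    registry: PopulationRegistry | None = None,
) -> list[VariantRecord]:
    """Back-compute count triplets from the published allele frequencies.

    AN is fixed at 2 x cohort size, AC = round(AF x AN), homozygotes 0
    (the published AFs are already heterozygous-only). Recomputed AF
    therefore agrees with the printed value to within one allele; where
    5-dp rounding of the published AFs would leave the pooled GLOBAL
    count one allele below a subpopulation count, GLOBAL is bumped up to
    the subpopulation maximum (still within the one-allele tolerance).
    """
    registry = registry or default_registry()
    df = load_known_plpv_afs()
    records = []
    for row in df.to_dict("records"):
        counts = {}
        for pop in registry.codes:
            af = float(row[f"AF_{pop}"])
            an = registry[pop].allele_number
            counts[pop] = PopulationCounts(
                allele_count=round(af * an), allele_number=an, homozygous_count=0
            )
        max_sub = max(
            (c.allele_count for p, c in counts.items() if p != "GLOBAL"), default=0
        )
        if counts["GLOBAL"].allele_count < max_sub:
            counts["GLOBAL"] = PopulationCounts(
                allele_count=max_sub,
                allele_number=counts["GLOBAL"].allele_number,
                homozygous_count=0,
            )
        records.append(
            VariantRecord(
                gene=row["gene"],
                transcript="",
                hgvs_c=row["hgvs_c"],
                hgvs_p=row["hgvs_p"],
                consequence=row["consequence"],
                loftee="HC" if row["consequence"] in
                       ("nonsense", "frameshift", "splice_site") else "NA",
                clinvar="absent",
                scores=InSilicoScores(),
                counts=counts,
            )
        )
    return records
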
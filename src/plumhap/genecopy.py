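"""Per-haplotype gene copy numbers from homology-group band assignments.

Two bands segregating in phase cannot be alleles of the same single-copy
gene, so the count of in-phase bands of one homology group is a *lower bound*
on the copy number of that gene within the haplotype.  The bound is a minimum
only: null alleles (mis-amplification) and same-size co-migration can hide
further copies, so reports carry that caveat explicitly and never resolve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import HaplotypeCatalog

__all__ = ["CopyNumberReport", "copy_counts", "check_single_copy_constraint", "COPY_NUMBER_CAVEAT"]

COPY_NUMBER_CAVEAT = (
    "Counts are minimum copy numbers: a null allele due to mis-amplification or "
    "to same-size co-migration of two alleles can hide additional copies."
)


@dataclass
class CopyNumberReport:
    """Allele counts per haplotype x gene group and the implied minimum copy
    number per group (the maximum count over haplotypes)."""

    counts: dict[str, dict[str, int]]          # haplotype id -> group -> count
    min_copy_number: dict[str, int]            # group -> max count over haplotypes
    duplicated_groups: list[str]
    evidence: dict[str, list[str]] = field(default_factory=dict)  # group -> haplotypes with >1
    caveat: str = COPY_NUMBER_CAVEAT

    def to_frame(self) -> pd.DataFrame:
        groups = sorted({g for row in self.counts.values() for g in row})
        return pd.DataFrame(
            [
                {"haplotype": hid, **{g: row.get(g, 0) for g in groups}}
                for hid, row in sorted(self.counts.items())
            ]
        ).set_index("haplotype")


def copy_counts(catalog: HaplotypeCatalog, gene_map: dict[str, str]) -> CopyNumberReport:
    """Exact allele-set cardinalities per haplotype and gene group.

    Bands absent from ``gene_map`` count under ``"unknown"``, which never
    triggers a duplication call.
    """
    counts: dict[str, dict[str, int]] = {}
    for hap in catalog.haplotypes:
        row: dict[str, int] = {}
        for band in hap.bands:
            group = gene_map.get(band, "unknown")
            row[group] = row.get(group, 0) + 1
        counts[hap.id] = row
    groups = sorted({g for row in counts.values() for g in row})
    min_copy = {
        g: max(row.get(g, 0) for row in counts.values()) for g in groups if g != "unknown"
    }
    duplicated = [g for g, k in min_copy.items() if k > 1]
    evidence = {
        g: sorted(hid for hid, row in counts.items() if row.get(g, 0) > 1)
        for g in duplicated
    }
    return CopyNumberReport(
        counts=counts,
        min_copy_number=min_copy,
        duplicated_groups=duplicated,
        evidence=evidence,
    )


def check_single_copy_constraint(
    catalog: HaplotypeCatalog, gene_map: dict[str, str]
) -> list[tuple[str, str, frozenset[str]]]:
    """Violations of a single-copy-per-gene assumption.

    Each violation is (haplotype id, gene group, allele set) for every group
    with more than one in-phase band — the formal trigger for inferring a
    duplication of that gene.
    """
    violations = []
    for hap in sorted(catalog.haplotypes, key=lambda h: h.id):
        by_group: dict[str, set[str]] = {}
        for band in hap.bands:
            group = gene_map.get(band, "unknown")
            if group != "unknown":
                by_group.setdefault(group, set()).add(band)
        for group in sorted(by_group):
            if len(by_group[group]) > 1:
                violations.append((hap.id, group, frozenset(by_group[group])))
    return violations
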
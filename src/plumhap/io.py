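"""Readers and writers for every external format the pipeline touches.

Formats: wide 0/1 band matrix (CSV), fragment-size table (CSV), pedigree (CSV),
phenotype table (CSV), haplotype catalog (JSON), FASTA alignments, BED, per-base
depth tables (samtools-depth dialect TSV) and Newick trees.  All coordinate
conversions (1-based inclusive text -> internal 0-based half-open) happen here,
exactly once, at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import (
    Band,
    BandGenotype,
    Family,
    Haplotype,
    HaplotypeCatalog,
    PhenotypeRecord,
    Region,
    ValidationError,
)

__all__ = [
    "read_band_matrix",
    "write_band_matrix",
    "read_fragment_table",
    "read_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_catalog",
    "write_catalog",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_depth_tsv",
    "write_depth_tsv",
    "write_newick",
]


# ---------------------------------------------------------------------------
# Band matrix (wide, first column accession, cells in {0,1})
# ---------------------------------------------------------------------------

def read_band_matrix(path: str | Path, band_registry: list[Band] | None = None) -> list[BandGenotype]:
    df = pd.read_csv(path, dtype={0: str})
    acc_col = df.columns[0]
    band_cols = list(df.columns[1:])
    if band_registry is not None:
        known = {b.id for b in band_registry}
        unknown = [c for c in band_cols if c not in known]
        if unknown:
            raise ValidationError(f"{path}: unknown band columns {unknown}")
    if df[acc_col].duplicated().any():
        dups = sorted(df.loc[df[acc_col].duplicated(), acc_col])
        raise ValidationError(f"{path}: duplicate accessions {dups}")
    genotypes = []
    for i, row in df.iterrows():
        bands = set()
        for col in band_cols:
            val = row[col]
            if val not in (0, 1):
                raise ValidationError(
                    f"{path}: non-binary cell at row {i + 2}, column {col!r}: {val!r}"
                )
            if val == 1:
                bands.add(col)
        if not bands:
            raise ValidationError(f"{path}: accession {row[acc_col]!r} (row {i + 2}) has no bands")
        genotypes.append(BandGenotype(accession=str(row[acc_col]), bands=frozenset(bands)))
    return genotypes


def write_band_matrix(
    genotypes: list[BandGenotype], path: str | Path, band_order: list[str] | None = None
) -> None:
    """Inverse of :func:`read_band_matrix` (round-trip identity modulo column order)."""
    if band_order is None:
        band_order = sorted(set().union(*(g.bands for g in genotypes)))
    rows = [
        {"accession": g.accession, **{b: int(b in g.bands) for b in band_order}}
        for g in genotypes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fragment_table(path: str | Path) -> dict[str, list[float]]:
    """Fragment-size table (accession,size_bp) -> sizes per accession."""
    df = pd.read_csv(path, dtype={0: str})
    out: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.iloc[0]), []).append(float(row.iloc[1]))
    return out


# ---------------------------------------------------------------------------
# Pedigree and phenotypes
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path, genotypes: list[BandGenotype]) -> list[Family]:
    """Pedigree CSV (family,role,accession) + band genotypes -> families.

    ``role`` is one of seed/pollen/progeny; every accession must have a band
    genotype.
    """
    by_acc = {g.accession: g for g in genotypes}
    df = pd.read_csv(path, dtype=str)
    need = {"family", "role", "accession"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: pedigree needs columns {sorted(need)}")
    families = []
    for fam_id, group in df.groupby("family", sort=False):
        seed = pollen = None
        progeny = []
        for i, row in group.iterrows():
            acc = row["accession"]
            if acc not in by_acc:
                raise ValidationError(f"{path}: line {i + 2}: no genotype for accession {acc!r}")
            if row["role"] == "seed":
                seed = by_acc[acc]
            elif row["role"] == "pollen":
                pollen = by_acc[acc]
            elif row["role"] == "progeny":
                progeny.append(by_acc[acc])
            else:
                raise ValidationError(f"{path}: line {i + 2}: bad role {row['role']!r}")
        if seed is None or pollen is None:
            raise ValidationError(f"{path}: family {fam_id!r} lacks a seed or pollen parent")
        families.append(Family(id=str(fam_id), seed_parent=seed, pollen_parent=pollen, progeny=progeny))
    return families


def write_pedigree(families: list[Family], path: str | Path) -> None:
    rows = []
    for fam in families:
        rows.append({"family": fam.id, "role": "seed", "accession": fam.seed_parent.accession})
        rows.append({"family": fam.id, "role": "pollen", "accession": fam.pollen_parent.accession})
        rows.extend(
            {"family": fam.id, "role": "progeny", "accession": p.accession} for p in fam.progeny
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotypes(path: str | Path, pale_red_presence: bool = True) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, dtype=str)
    need = {"accession", "skin", "flesh"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: phenotype table needs columns {sorted(need)}")
    return [
        PhenotypeRecord(str(r["accession"]), r["skin"], r["flesh"]).recoded(
            pale_red_presence=pale_red_presence
        )
        for _, r in df.iterrows()
    ]


def write_phenotypes(records: list[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"accession": r.accession, "skin": r.skin_color, "flesh": r.flesh_color} for r in records]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Haplotype catalog JSON
# ---------------------------------------------------------------------------

def write_catalog(catalog: HaplotypeCatalog, path: str | Path) -> None:
    payload = {
        "bands": [
            {
                "id": b.id,
                "size_bp": b.size_bp,
                "gene_group": b.gene_group,
                "monomorphic": b.monomorphic,
            }
            for b in catalog.bands
        ],
        "haplotypes": [
            {"id": h.id, "bands": sorted(h.bands), "source": h.source}
            for h in catalog.haplotypes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_catalog(path: str | Path) -> HaplotypeCatalog:
    payload = json.loads(Path(path).read_text())
    bands = [
        Band(b["id"], b["size_bp"], b.get("gene_group", "unknown"), b.get("monomorphic", False))
        for b in payload["bands"]
    ]
    haps = [
        Haplotype(h["id"], frozenset(h["bands"]), h.get("source", "family_phased"))
        for h in payload["haplotypes"]
    ]
    # HaplotypeCatalog.validate enforces the monomorphic-band invariant on read
    return HaplotypeCatalog(haplotypes=haps, bands=bands)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# BED and depth TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Region]:
    """Three-column BED (already 0-based half-open); name column optional."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: line {lineno}: need at least 3 BED columns")
        try:
            regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def write_bed(regions: list[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.sequence}\t{r.start}\t{r.end}\n")


def read_depth_tsv(path: str | Path):
    """samtools-depth dialect TSV (sequence, 1-based position, depth) -> DepthTrack."""
    from .depth import DepthTrack

    df = pd.read_csv(path, sep="\t", header=None, names=["sequence", "pos", "depth"])
    if df.empty:
        raise ValidationError(f"{path}: empty depth table")
    return DepthTrack.from_dataframe(df, one_based=True)


def write_depth_tsv(track, path: str | Path) -> None:
    track.to_dataframe(one_based=True).to_csv(path, sep="\t", header=False, index=False)


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode to a Newick file."""
    tree.write(str(path), format="newick")
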
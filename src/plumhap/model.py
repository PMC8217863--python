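"""Domain types for dominant multi-allelic PCR-band genotypes of the plum MYB10 cluster.

The experimental object is a *band*: a PCR amplicon of characteristic size scored as
present/absent on a capillary electrophoresis profile.  Bands behave as dominant
alleles — a carrier of one or two copies is indistinguishable — and a *haplotype* is
the set of bands co-transmitted on one chromosome.  A diploid accession therefore
displays the union of its two haplotypes' band sets (its *diplotype*).

This module holds the shared types, the fragment-size binning step that turns raw
GeneMapper-like sizes into band calls, the binary anthocyanin recode of colour
descriptors, and the published six-haplotype reference catalog used in examples and
tests throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "PlumhapError",
    "ValidationError",
    "ConfigurationError",
    "Band",
    "BandGenotype",
    "Haplotype",
    "HaplotypeCatalog",
    "Diplotype",
    "Family",
    "PhenotypeRecord",
    "Region",
    "BinResult",
    "bin_fragments",
    "recode_binary",
    "parse_region",
    "SKIN_COLORS",
    "FLESH_COLORS",
    "SKIN_PRESENCE",
    "FLESH_PRESENCE",
    "reference_catalog",
    "reference_gene_map",
]


class PlumhapError(Exception):
    """Base class for all package errors."""


class ValidationError(PlumhapError):
    """An input object violates a domain invariant."""


class ConfigurationError(PlumhapError):
    """Inconsistent or infeasible configuration."""


# ---------------------------------------------------------------------------
# Bands and genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """A named amplicon allele with a size bin.

    Parameters
    ----------
    id : str
        Opaque label, conventionally ``a<size>`` (e.g. ``"a356"``).
    size_bp : int
        Fragment size in base pairs; must be positive.
    gene_group : str
        Homology group of the band: ``"G1"``, ``"G2"``, ``"G3"`` or ``"unknown"``.
    monomorphic : bool
        True when the band is present in every haplotype of the study
        (uninformative for phasing).
    """

    id: str
    size_bp: int
    gene_group: str = "unknown"
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValidationError(f"band {self.id!r}: size_bp must be > 0")
        if self.gene_group not in {"G1", "G2", "G3", "unknown"}:
            raise ValidationError(
                f"band {self.id!r}: gene_group {self.gene_group!r} not one of G1/G2/G3/unknown"
            )


@dataclass(frozen=True)
class BandGenotype:
    """Observed dominant genotype of one accession: a non-empty set of band ids."""

    accession: str
    bands: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", frozenset(self.bands))
        if not self.bands:
            raise ValidationError(f"accession {self.accession!r}: empty band set")


@dataclass(frozen=True)
class Haplotype:
    """A phased set of bands carried together on one chromosome."""

    id: str
    bands: frozenset[str]
    source: str = "family_phased"  # family_phased | panel_inferred | simulated_truth

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", frozenset(self.bands))
        if not self.bands:
            raise ValidationError(f"haplotype {self.id!r}: empty band set")
        if self.source not in {"family_phased", "panel_inferred", "simulated_truth"}:
            raise ValidationError(f"haplotype {self.id!r}: bad source {self.source!r}")


@dataclass
class HaplotypeCatalog:
    """A band registry plus the haplotypes defined over it.

    Invariants: haplotype ids unique; every referenced band registered; every
    monomorphic band of the registry present in every haplotype.
    """

    haplotypes: list[Haplotype]
    bands: list[Band]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [h.id for h in self.haplotypes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate haplotype ids: {dup}")
        band_ids = [b.id for b in self.bands]
        if len(band_ids) != len(set(band_ids)):
            dup = sorted({i for i in band_ids if band_ids.count(i) > 1})
            raise ValidationError(f"duplicate band ids: {dup}")
        registered = set(band_ids)
        for h in self.haplotypes:
            missing = h.bands - registered
            if missing:
                raise ValidationError(
                    f"haplotype {h.id!r} references unregistered bands {sorted(missing)}"
                )
        mono = self.monomorphic_bands()
        for h in self.haplotypes:
            absent = mono - h.bands
            if absent:
                raise ValidationError(
                    f"haplotype {h.id!r} lacks monomorphic band(s) {sorted(absent)}"
                )

    def monomorphic_bands(self) -> frozenset[str]:
        return frozenset(b.id for b in self.bands if b.monomorphic)

    def band(self, band_id: str) -> Band:
        for b in self.bands:
            if b.id == band_id:
                return b
        raise KeyError(band_id)

    def haplotype(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(hap_id)

    def with_haplotype(self, hap: Haplotype) -> "HaplotypeCatalog":
        """Return a new catalog extended by one haplotype (registry unchanged)."""
        return HaplotypeCatalog(haplotypes=[*self.haplotypes, hap], bands=list(self.bands))


@dataclass
class Diplotype:
    """The (unordered) pair of haplotypes explaining an accession's band set.

    ``status`` is ``explained`` when exactly one catalog pair unions to the
    observed band set, ``ambiguous`` when several do (all listed in
    ``alternatives``), and ``unexplained`` otherwise.
    """

    accession: str
    pair: tuple[str, str] | None
    status: str
    alternatives: list[tuple[str, str]] = field(default_factory=list)
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status not in {"explained", "ambiguous", "unexplained"}:
            raise ValidationError(f"diplotype {self.accession!r}: bad status {self.status!r}")
        if self.pair is not None:
            self.pair = tuple(sorted(self.pair))  # type: ignore[assignment]
        self.alternatives = [tuple(sorted(p)) for p in self.alternatives]


@dataclass
class Family:
    """An F1 biparental family: two parents with known band genotypes plus progeny.

    Progeny bands absent from both parents are recorded in
    ``genotyping_errors`` (band -> offending progeny accessions) rather than
    raising, since isolated scoring errors are expected in real fragment data.
    """

    id: str
    seed_parent: BandGenotype
    pollen_parent: BandGenotype
    progeny: list[BandGenotype]
    genotyping_errors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.progeny) < 1:
            raise ValidationError(f"family {self.id!r}: needs at least one progeny")
        parental = self.seed_parent.bands | self.pollen_parent.bands
        errors: dict[str, list[str]] = {}
        for child in self.progeny:
            for band in child.bands - parental:
                errors.setdefault(band, []).append(child.accession)
        self.genotyping_errors = errors

    @property
    def n_progeny(self) -> int:
        return len(self.progeny)


SKIN_COLORS = ("yellow", "green", "mottled", "pale_red", "red", "purple", "black")
FLESH_COLORS = ("white", "green", "yellow", "orange", "red", "purple")

# Anthocyanin presence under the binary recode.  pale_red is configurable
# (an anthocyanin hue, so presence by default); mottled fruit have coloured
# patches over a yellow/green background but are scored as absence.
SKIN_PRESENCE = frozenset({"red", "purple", "black"})
FLESH_PRESENCE = frozenset({"red", "purple"})


@dataclass(frozen=True)
class PhenotypeRecord:
    """Skin and flesh colour descriptors plus their binary anthocyanin recodes."""

    accession: str
    skin_color: str
    flesh_color: str
    skin_binary: bool | None = None
    flesh_binary: bool | None = None

    def __post_init__(self) -> None:
        if self.skin_color not in SKIN_COLORS:
            raise ValidationError(
                f"{self.accession!r}: unknown skin colour {self.skin_color!r}; "
                f"vocabulary is {SKIN_COLORS}"
            )
        if self.flesh_color not in FLESH_COLORS:
            raise ValidationError(
                f"{self.accession!r}: unknown flesh colour {self.flesh_color!r}; "
                f"vocabulary is {FLESH_COLORS}"
            )

    def recoded(self, pale_red_presence: bool = True) -> "PhenotypeRecord":
        return replace(
            self,
            skin_binary=recode_binary(self, "skin", pale_red_presence=pale_red_presence),
            flesh_binary=recode_binary(self, "flesh"),
        )


def recode_binary(record: PhenotypeRecord, tissue: str, *, pale_red_presence: bool = True) -> bool:
    """Binary anthocyanin recode of a colour descriptor.

    Skin red/purple/black (and pale_red when ``pale_red_presence``) map to
    presence; mottled, yellow and green to absence.  Flesh red/purple map to
    presence; white, green, yellow, orange to absence.
    """
    if tissue == "skin":
        if record.skin_color == "pale_red":
            return pale_red_presence
        return record.skin_color in SKIN_PRESENCE
    if tissue == "flesh":
        return record.flesh_color in FLESH_PRESENCE
    raise ValidationError(f"tissue must be 'skin' or 'flesh', got {tissue!r}")


# ---------------------------------------------------------------------------
# Genomic regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A genomic interval stored 0-based half-open."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"region {self.sequence}:{self.start}-{self.end}: start must be < end")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Region") -> bool:
        return (
            self.sequence == other.sequence
            and self.start <= other.start
            and other.end <= self.end
        )


_REGION_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*([\d,]+)\s*[-–—]\s*([\d,]+)\s*$")


def parse_region(text: str) -> Region:
    """Parse 1-based inclusive region text like ``"LG3:18183274-18256025"``.

    Accepts hyphen or en/em dash separators and thousands separators; the
    result is converted to 0-based half-open coordinates exactly once, here.
    """
    m = _REGION_RE.match(text)
    if not m:
        raise ValidationError(f"cannot parse region text {text!r} (expected seq:start-end)")
    seq, lo, hi = m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    if lo < 1 or hi < lo:
        raise ValidationError(f"region {text!r}: need 1 <= start <= end")
    return Region(seq, lo - 1, hi)


# ---------------------------------------------------------------------------
# Fragment-size binning
# ---------------------------------------------------------------------------

@dataclass
class BinResult:
    """Outcome of binning raw fragment sizes against a band registry."""

    bands: set[str]
    unmatched: list[float]
    collisions: list[tuple[str, list[float]]]  # band id -> fragments sharing its bin


def bin_fragments(
    fragment_sizes: list[float],
    band_registry: list[Band],
    tolerance_bp: float = 0.5,
) -> BinResult:
    """Map fractional fragment sizes to registry bands within ``tolerance_bp``.

    Two fragments landing in the same bin produce a single band call plus a
    collision warning (co-migrating alleles are indistinguishable on the
    profile).  Fragments outside every bin are reported, never dropped.

    Raises
    ------
    ConfigurationError
        If tolerance is non-positive or two registry bands sit within
        ``2 * tolerance_bp`` of each other (their bins would overlap).
    """
    if tolerance_bp <= 0:
        raise ConfigurationError("tolerance_bp must be > 0")
    by_size = sorted(band_registry, key=lambda b: b.size_bp)
    for a, b in zip(by_size, by_size[1:]):
        if b.size_bp - a.size_bp <= 2 * tolerance_bp:
            raise ConfigurationError(
                f"registry bands {a.id!r} ({a.size_bp} bp) and {b.id!r} ({b.size_bp} bp) "
                f"are within 2*tolerance ({2 * tolerance_bp} bp); bins overlap"
            )
    hits: dict[str, list[float]] = {}
    unmatched: list[float] = []
    for size in fragment_sizes:
        for band in by_size:
            if abs(size - band.size_bp) <= tolerance_bp:
                hits.setdefault(band.id, []).append(size)
                break
        else:
            unmatched.append(size)
    collisions = [(bid, frags) for bid, frags in hits.items() if len(frags) > 1]
    return BinResult(bands=set(hits), unmatched=unmatched, collisions=collisions)


# ---------------------------------------------------------------------------
# Published plum MYB10 reference catalog
# ---------------------------------------------------------------------------

# The six family-phased haplotypes of the Japanese plum MYB10 cluster and the
# homology-group assignment of the twelve common bands (G1 = MYB10.1,
# G2 = MYB10.2, G3 = MYB10.3).  a466 is the single monomorphic band.
_REFERENCE_HAPLOTYPES: dict[str, frozenset[str]] = {
    "H1": frozenset({"a350", "a356", "a454", "a466", "a492"}),
    "H2": frozenset({"a470", "a466", "a492"}),
    "H3": frozenset({"a356", "a462", "a473", "a466", "a495"}),
    "H4": frozenset({"a462", "a470", "a466", "a443"}),
    "H5": frozenset({"a470", "a466", "a477"}),
    "H6": frozenset({"a462", "a466", "a477"}),
}

_REFERENCE_GENE_MAP: dict[str, str] = {
    "a243": "G1", "a350": "G1", "a356": "G1", "a454": "G1",
    "a462": "G1", "a470": "G1", "a473": "G1",
    "a466": "G2",
    "a443": "G3", "a477": "G3", "a492": "G3", "a495": "G3",
}


def reference_gene_map() -> dict[str, str]:
    """Band -> homology-group map for the twelve common plum MYB10 bands."""
    return dict(_REFERENCE_GENE_MAP)


def reference_catalog(source: str = "family_phased") -> HaplotypeCatalog:
    """The published six-haplotype plum MYB10 catalog (H1-H6) over 12 bands."""
    bands = [
        Band(bid, int(bid[1:]), gene_group=_REFERENCE_GENE_MAP[bid], monomorphic=(bid == "a466"))
        for bid in sorted(_REFERENCE_GENE_MAP)
    ]
    haps = [Haplotype(hid, bset, source=source) for hid, bset in _REFERENCE_HAPLOTYPES.items()]
    return HaplotypeCatalog(haplotypes=haps, bands=bands)
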
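"""Synthetic-data generator for the plum MYB10 inference chain.

Emulates the statistical structure the downstream analyses assume: a catalog of
haplotypes over a three-gene tandem cluster (1-3 copies of gene G1 per
haplotype, exactly one G2 and one G3 allele), dominant band genotypes as unions
of two haplotypes with configurable dropout / false-positive / band-collision
noise, Mendelian F1 families, a dominant colour band with incomplete
penetrance, Poisson read-depth tracks proportional to copy number, and gapped
allele alignments whose intron evolves faster than the exons.

All generators draw from per-component substreams of one global seed, so any
stage can be regenerated independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    Band,
    BandGenotype,
    ConfigurationError,
    Family,
    FLESH_PRESENCE,
    Haplotype,
    HaplotypeCatalog,
    PhenotypeRecord,
    Region,
    SKIN_PRESENCE,
    reference_catalog,
    reference_gene_map,
)

__all__ = [
    "SimulationConfig",
    "PanelResult",
    "FamilyResult",
    "rare_haplotype_definitions",
    "simulate_catalog",
    "simulate_panel",
    "simulate_family",
    "simulate_families",
    "simulate_depth",
    "simulate_alignment",
]


# Rare haplotypes carried by the seven panel accessions that the six common
# haplotypes cannot explain.  Each carries at least one band with population
# frequency below the 5% cloning threshold; Hi10 and Hi11 share the rare a243
# band and occur together in one accession.  Gene groups: one G2 (the
# monomorphic a466), one G3, and 1-3 G1 bands per haplotype.
_RARE_HAPLOTYPES: dict[str, frozenset[str]] = {
    "Hi7": frozenset({"a248", "a466", "a477"}),
    "Hi8": frozenset({"a356", "a259", "a454", "a466", "a495"}),
    "Hi9": frozenset({"a283", "a470", "a466", "a443"}),
    "Hi10": frozenset({"a243", "a462", "a466", "a310"}),
    "Hi11": frozenset({"a243", "a470", "a466", "a331"}),
}

_RARE_GENE_MAP: dict[str, str] = {
    "a248": "G1", "a259": "G1", "a283": "G1", "a310": "G3", "a331": "G3",
}

# Default biparental family design: the six crosses of the study panel with
# their published progeny counts.
_DEFAULT_FAMILIES: list[tuple[str, tuple[str, str], tuple[str, str], int]] = [
    ("P1", ("H1", "H5"), ("H3", "H3"), 83),
    ("P2", ("H2", "H4"), ("H1", "H2"), 111),
    ("P3", ("H3", "H4"), ("H1", "H2"), 48),
    ("P4", ("H3", "H6"), ("H1", "H2"), 43),
    ("P5", ("H1", "H2"), ("H1", "H3"), 64),
    ("P6", ("H3", "H6"), ("H2", "H3"), 33),
]

# Common-haplotype frequencies in the unrelated panel.  Chosen so that roughly
# 65% of accessions carry a colour haplotype (H1 or H3), matching the fraction
# of skin-coloured accessions in the discovery panel.
_DEFAULT_FREQUENCIES: dict[str, float] = {
    "H1": 0.22, "H2": 0.26, "H3": 0.20, "H4": 0.13, "H5": 0.09, "H6": 0.10,
}

# The seven rare-carrying accessions: six combine a rare haplotype with a
# common one and one accession carries two rare haplotypes.
_DEFAULT_RARE_ACCESSIONS: list[tuple[str, str]] = [
    ("Hi7", "H1"),
    ("Hi8", "H2"),
    ("Hi9", "H1"),
    ("Hi10", "H1"),
    ("Hi11", "H3"),
    ("Hi10", "Hi11"),
    ("Hi7", "H2"),
]


def rare_haplotype_definitions() -> dict[str, frozenset[str]]:
    return dict(_RARE_HAPLOTYPES)


@dataclass
class SimulationConfig:
    """Study-condition defaults for every generator.

    ``haplotype_compositions`` pins the catalog to explicit band sets (the
    default mirrors the published six-haplotype catalog); set it to ``None``
    to draw a random structured catalog instead.
    """

    seed: int = 0
    n_genes: int = 3
    g1_copy_range: tuple[int, int] = (1, 3)
    n_haplotypes: int = 6
    haplotype_compositions: dict[str, frozenset[str]] | None = None
    haplotype_frequencies: dict[str, float] | None = None
    n_accessions: int = 81
    families: list[tuple[str, tuple[str, str], tuple[str, str], int]] = field(
        default_factory=lambda: [f for f in _DEFAULT_FAMILIES]
    )
    band_size_range: tuple[int, int] = (243, 500)
    dropout_rate: float = 0.0
    false_positive_rate: float = 0.0
    collision_pairs: list[tuple[str, str]] = field(default_factory=list)  # (hidden, visible)
    color_band: str = "a356"
    penetrance: float = 0.95
    flesh_color_rate: float = 0.382
    rare_haplotypes: dict[str, frozenset[str]] | None = None
    rare_accessions: list[tuple[str, str]] = field(
        default_factory=lambda: [p for p in _DEFAULT_RARE_ACCESSIONS]
    )
    mean_coverage: float = 30.0
    poisson_noise: bool = True
    # alignment generator
    n_alleles: int = 12
    exon_sub_rate: float = 0.036
    intron_sub_rate: float = 0.11
    intron_indel_prob: float = 0.5
    alignment_length: int = 600
    intron_span: tuple[int, int] = (84, 514)  # 0-based half-open
    alignment_groups: int = 1                 # ancestral homology groups
    group_divergence_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.haplotype_compositions is None:
            # default truth: the published catalog plus the rare haplotypes
            self.haplotype_compositions = {
                h.id: h.bands for h in reference_catalog().haplotypes
            }
        if self.rare_haplotypes is None:
            self.rare_haplotypes = dict(_RARE_HAPLOTYPES)
        if self.haplotype_frequencies is None:
            self.haplotype_frequencies = dict(_DEFAULT_FREQUENCIES)
        total = sum(self.haplotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"haplotype frequencies sum to {total}, expected 1")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigurationError("penetrance must be in [0, 1]")
        for name in ("dropout_rate", "false_positive_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1)")

    def rng(self, component: str, extra: int = 0) -> np.random.Generator:
        """Deterministic per-component substream of the global seed."""
        key = {"catalog": 0, "panel": 1, "family": 2, "depth": 3, "alignment": 4}[component]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key, extra))
        )


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def _registry_from_compositions(
    compositions: dict[str, frozenset[str]],
    gene_map: dict[str, str],
    monomorphic: frozenset[str],
) -> list[Band]:
    band_ids = sorted(set().union(*compositions.values()))
    return [
        Band(bid, int(bid[1:]), gene_group=gene_map.get(bid, "unknown"), monomorphic=bid in monomorphic)
        for bid in band_ids
    ]


def simulate_catalog(config: SimulationConfig) -> tuple[HaplotypeCatalog, dict[str, str]]:
    """Generate the truth haplotype catalog plus its band -> gene-group map.

    With pinned ``haplotype_compositions`` (the default) the catalog is the
    fixed study structure; otherwise haplotypes are drawn at random subject to
    the cluster constraints (1-3 G1 bands, exactly one G2 = the shared
    monomorphic band, exactly one G3 band per haplotype).
    """
    if config.haplotype_compositions is not None:
        gene_map = {**reference_gene_map(), **_RARE_GENE_MAP}
        mono = frozenset(
            bid
            for bid in set().union(*config.haplotype_compositions.values())
            if all(bid in bands for bands in config.haplotype_compositions.values())
        )
        bands = _registry_from_compositions(config.haplotype_compositions, gene_map, mono)
        haps = [
            Haplotype(hid, bset, source="simulated_truth")
            for hid, bset in sorted(config.haplotype_compositions.items())
        ]
        catalog = HaplotypeCatalog(haplotypes=haps, bands=bands)
        return catalog, {b.id: b.gene_group for b in bands}

    rng = config.rng("catalog")
    lo, hi = config.band_size_range
    kmin, kmax = config.g1_copy_range
    # distinct sizes at >=2 bp spacing; enough for the G1 pool, one G2, G3 pool
    n_g1 = kmax * config.n_haplotypes
    n_g3 = config.n_haplotypes
    n_sizes = n_g1 + 1 + n_g3
    candidates = np.arange(lo, hi + 1, 2)
    if n_sizes > len(candidates):
        raise ConfigurationError(
            f"cannot place {n_sizes} bands at 2 bp spacing within {lo}-{hi} bp"
        )
    sizes = sorted(rng.choice(candidates, size=n_sizes, replace=False).tolist())
    band_ids = [f"a{s}" for s in sizes]
    g1_pool = band_ids[:n_g1]
    g2_band = band_ids[n_g1]
    g3_pool = band_ids[n_g1 + 1:]
    gene_map = {b: "G1" for b in g1_pool}
    gene_map[g2_band] = "G2"
    gene_map.update({b: "G3" for b in g3_pool})
    compositions: dict[str, frozenset[str]] = {}
    while len(compositions) < config.n_haplotypes:
        hid = f"H{len(compositions) + 1}"
        k = int(rng.integers(kmin, kmax + 1))
        g1 = rng.choice(g1_pool, size=k, replace=False).tolist()
        g3 = str(rng.choice(g3_pool))
        bset = frozenset([*g1, g2_band, g3])
        if bset in compositions.values():
            continue
        compositions[hid] = bset
    bands = _registry_from_compositions(compositions, gene_map, frozenset({g2_band}))
    haps = [Haplotype(h, b, source="simulated_truth") for h, b in compositions.items()]
    return HaplotypeCatalog(haplotypes=haps, bands=bands), gene_map


# ---------------------------------------------------------------------------
# Observation noise
# ---------------------------------------------------------------------------

def _observe(
    truth_bands: frozenset[str],
    registry: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Apply collision, dropout and false-positive noise to a truth band union."""
    bands = set(truth_bands)
    for hidden, visible in config.collision_pairs:
        if hidden in bands:
            bands.discard(hidden)
            bands.add(visible)
    if config.dropout_rate > 0:
        bands = {b for b in bands if rng.random() >= config.dropout_rate}
    if config.false_positive_rate > 0:
        for b in registry:
            if b not in bands and rng.random() < config.false_positive_rate:
                bands.add(b)
    if not bands:  # pathological full dropout: keep one true band
        bands = {sorted(truth_bands)[0]}
    return frozenset(bands)


def _visible_registry(catalog: HaplotypeCatalog, config: SimulationConfig) -> list[str]:
    hidden = {h for h, _ in config.collision_pairs}
    return [b.id for b in catalog.bands if b.id not in hidden]


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class PanelResult:
    genotypes: list[BandGenotype]
    truth_diplotypes: dict[str, tuple[str, str]]
    phenotypes: list[PhenotypeRecord]


def simulate_panel(config: SimulationConfig, catalog: HaplotypeCatalog) -> PanelResult:
    """Unrelated panel: diplotypes from haplotype frequencies plus the fixed
    rare-carrying accessions, dominant band observation noise, and a binary
    anthocyanin skin phenotype driven by the colour band at the configured
    penetrance."""
    rng = config.rng("panel")
    freqs = config.haplotype_frequencies
    common_ids = sorted(freqs)
    probs = np.array([freqs[h] for h in common_ids])
    all_haps = {h.id: h.bands for h in catalog.haplotypes}
    for hid, bset in (config.rare_haplotypes or {}).items():
        all_haps.setdefault(hid, bset)
    registry = _visible_registry(catalog, config)

    n_rare = len(config.rare_accessions)
    if n_rare > config.n_accessions:
        raise ConfigurationError("more rare accessions than panel size")
    diplotypes: list[tuple[str, str]] = []
    for _ in range(config.n_accessions - n_rare):
        a, b = rng.choice(common_ids, size=2, replace=True, p=probs)
        diplotypes.append(tuple(sorted((str(a), str(b)))))
    for pair in config.rare_accessions:
        unknown = [h for h in pair if h not in all_haps]
        if unknown:
            raise ConfigurationError(f"unknown haplotype id(s) {unknown} in rare accessions")
        diplotypes.append(tuple(sorted(pair)))

    genotypes, phenotypes = [], []
    truth: dict[str, tuple[str, str]] = {}
    skin_colored = sorted(SKIN_PRESENCE)
    skin_plain = ["yellow", "green", "mottled"]
    flesh_colored = sorted(FLESH_PRESENCE)
    flesh_plain = ["white", "green", "yellow", "orange"]
    for i, (ha, hb) in enumerate(diplotypes):
        acc = f"C{i + 1:03d}"
        truth[acc] = (ha, hb)
        union = all_haps[ha] | all_haps[hb]
        genotypes.append(BandGenotype(acc, _observe(union, registry, config, rng)))
        carries = config.color_band in union
        colored = rng.random() < (config.penetrance if carries else 1 - config.penetrance)
        skin = str(rng.choice(skin_colored if colored else skin_plain))
        flesh_col = rng.random() < config.flesh_color_rate
        flesh = str(rng.choice(flesh_colored if flesh_col else flesh_plain))
        phenotypes.append(PhenotypeRecord(acc, skin, flesh).recoded())
    return PanelResult(genotypes=genotypes, truth_diplotypes=truth, phenotypes=phenotypes)


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

@dataclass
class FamilyResult:
    family: Family
    truth_transmissions: list[tuple[str, str]]  # (seed hap, pollen hap) per progeny
    truth_parents: tuple[tuple[str, str], tuple[str, str]]


def simulate_family(
    family_id: str,
    seed_diplotype: tuple[str, str],
    pollen_diplotype: tuple[str, str],
    n_progeny: int,
    config: SimulationConfig,
    catalog: HaplotypeCatalog,
    substream: int = 0,
) -> FamilyResult:
    """One F1 family: each progeny inherits one haplotype per parent uniformly
    and independently; observation noise applies to progeny only (parental
    genotypes are treated as verified by replicate genotyping)."""
    rng = config.rng("family", substream)
    haps = {h.id: h.bands for h in catalog.haplotypes}
    for hid in (*seed_diplotype, *pollen_diplotype):
        if hid not in haps:
            raise ConfigurationError(f"unknown haplotype id {hid!r}")
    registry = _visible_registry(catalog, config)

    def observe_parent(bands: frozenset[str]) -> frozenset[str]:
        out = set(bands)
        for hidden, visible in config.collision_pairs:
            if hidden in out:
                out.discard(hidden)
                out.add(visible)
        return frozenset(out)

    seed_bands = observe_parent(haps[seed_diplotype[0]] | haps[seed_diplotype[1]])
    pollen_bands = observe_parent(haps[pollen_diplotype[0]] | haps[pollen_diplotype[1]])
    progeny, transmissions = [], []
    for i in range(n_progeny):
        hs = seed_diplotype[int(rng.integers(2))]
        hp = pollen_diplotype[int(rng.integers(2))]
        transmissions.append((hs, hp))
        union = haps[hs] | haps[hp]
        progeny.append(
            BandGenotype(f"{family_id}_{i + 1:03d}", _observe(union, registry, config, rng))
        )
    fam = Family(
        id=family_id,
        seed_parent=BandGenotype(f"{family_id}_seed", seed_bands),
        pollen_parent=BandGenotype(f"{family_id}_pollen", pollen_bands),
        progeny=progeny,
    )
    return FamilyResult(fam, transmissions, (tuple(seed_diplotype), tuple(pollen_diplotype)))


def simulate_families(
    config: SimulationConfig,
    catalog: HaplotypeCatalog,
    n_progeny: int | None = None,
) -> list[FamilyResult]:
    """All configured families; ``n_progeny`` overrides every family size."""
    return [
        simulate_family(fid, seed, pollen, n_progeny or n, config, catalog, substream=i)
        for i, (fid, seed, pollen, n) in enumerate(config.families)
    ]


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def simulate_depth(
    config: SimulationConfig,
    cluster: Region,
    genes: dict[str, Region],
    gene_copies: dict[str, int],
    track_region: Region | None = None,
):
    """Per-base Poisson depth over ``track_region`` (default: the cluster's
    sequence from 0 to 2x cluster end, providing a diploid-baseline genome
    context).  Genes with ``k`` total haplotype copies get mean multiplier
    ``k/2`` relative to the diploid baseline.  With ``poisson_noise=False``
    the exact per-base means are returned."""
    from .depth import DepthTrack

    if not genes:
        raise ConfigurationError("empty gene layout")
    for name, g in genes.items():
        if not cluster.contains(g):
            raise ConfigurationError(f"gene {name!r} outside cluster region")
    if track_region is None:
        track_region = Region(cluster.sequence, 0, cluster.end * 2)
    rng = config.rng("depth")
    n = len(track_region)
    mult = np.ones(n)
    for name, g in genes.items():
        copies = gene_copies.get(name, 2)
        mult[g.start - track_region.start : g.end - track_region.start] = copies / 2.0
    means = config.mean_coverage * mult
    depths = rng.poisson(means).astype(float) if config.poisson_noise else means
    positions = np.arange(track_region.start, track_region.end)
    return DepthTrack({track_region.sequence: (positions, depths)})


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_alignment(config: SimulationConfig) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Gapped allele alignment mutated from a common ancestor.

    Returns (records, intron_mask).  The intron accumulates substitutions and
    indels at a higher rate than the exons, so intron diversity exceeds exon
    diversity as in real amplicon data.  Indels are realised as gap runs, so
    all sequences stay aligned and equal-length.
    """
    rng = config.rng("alignment")
    L = config.alignment_length
    s, e = config.intron_span
    root = rng.choice(_BASES, size=L)
    intron_mask = np.zeros(L, dtype=bool)
    intron_mask[s:e] = True

    def mutate(seq: np.ndarray, rates: np.ndarray) -> np.ndarray:
        out = seq.copy()
        hit = rng.random(L) < rates
        for pos in np.nonzero(hit)[0]:
            out[pos] = rng.choice(_BASES[_BASES != out[pos]])
        return out

    # with >1 ancestral groups (the tandem-duplicate structure), alleles
    # radiate from strongly diverged group ancestors
    n_groups = max(1, config.alignment_groups)
    group_rates = np.full(L, config.group_divergence_rate)
    ancestors = [root if n_groups == 1 else mutate(root, group_rates) for _ in range(n_groups)]
    within_rates = np.where(intron_mask, config.intron_sub_rate, config.exon_sub_rate)
    records = []
    for i in range(config.n_alleles):
        group = i % n_groups
        seq = mutate(ancestors[group], within_rates)
        if config.intron_indel_prob > 0 and rng.random() < config.intron_indel_prob:
            length = int(rng.integers(5, 41))
            start = int(rng.integers(s, max(s + 1, e - length)))
            seq[start : start + length] = "-"
        name = f"allele_{i + 1:02d}" if n_groups == 1 else f"G{group + 1}_allele_{i + 1:02d}"
        records.append((name, "".join(seq)))
    return records, intron_mask
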
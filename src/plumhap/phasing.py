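"""Family-based phasing of dominant bands into haplotypes.

The principle: two bands carried on the same parental chromosome are
co-transmitted to progeny, so their presence patterns across an F1 family
agree; bands on opposite chromosomes of one parent complement each other.
Because the cluster does not recombine, every informative band pair of a
parent is either fully in phase or fully in anti-phase, and the parent's
bands 2-colour into at most two haplotypes.

Decision rules are framed against the Mendelian expectations for dominant
markers: a band heterozygous in one parent appears in ~50% of progeny, a band
on both chromosomes of a parent (or on one chromosome of each parent) in
~100% / ~75%.  Observed frequencies are classified to the nearest expectation
(boundaries at the category midpoints), which tolerates realistic per-band
dropout without hard cliffs.

A band present in both parents and in essentially all progeny cannot be
placed from that family alone (it may sit on both chromosomes of either
parent); such bands are carried as *ambiguous* and resolved when haplotypes
are merged across families in :func:`build_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    Band,
    Family,
    Haplotype,
    HaplotypeCatalog,
    PlumhapError,
    ValidationError,
)

__all__ = [
    "PhasingConfig",
    "PhasingConflict",
    "SegregationStats",
    "PhasedHaplotype",
    "PhasedParent",
    "CatalogBuild",
    "segregation_stats",
    "phase_parent",
    "build_catalog",
]

# Frequency decision boundaries against the Mendelian expectations for
# dominant-band presence in F1 progeny (0 / 0.5 / 1.0 up to a few percent of
# band dropout).  The boundary separating "always transmitted" (expected
# ~1 - dropout) from "heterozygous" (~0.5) sits at 0.85 — nearer the upper
# hypothesis because realistic dropout rates are small, which keeps both
# misclassification tails negligible at family sizes of 30-110.
_LOW = 0.25      # below: too rare to be a real heterozygous parental band
_ON = 0.85       # above: transmitted by (that chromosome of) the parent always
_GUARANTEED = 0.875  # segregation_stats reporting label for family-monomorphic bands


class PhasingConflict(PlumhapError):
    """The band co-segregation pattern admits no two-haplotype explanation."""


@dataclass
class PhasingConfig:
    """epsilon: tolerated fraction of discordant progeny per band pair before a
    pair is flagged as noisy; min_informative_progeny: below this family size
    phasing is downgraded to low confidence."""

    epsilon: float = 0.05
    min_informative_progeny: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ValidationError("epsilon must be in [0, 0.5)")


@dataclass
class SegregationStats:
    """Per-band segregation summary for one family."""

    family_id: str
    n_progeny: int
    present: dict[str, int]            # band -> progeny count carrying it
    in_seed: dict[str, bool]
    in_pollen: dict[str, bool]
    classification: dict[str, str]     # monomorphic | seed-informative |
    #                                    pollen-informative | shared | conflicting
    conflicting_progeny: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def frequency(self, band: str) -> float:
        return self.present[band] / self.n_progeny


def segregation_stats(family: Family, config: PhasingConfig | None = None) -> SegregationStats:
    """Classify every band seen in a family by its parental origin and
    progeny frequency."""
    config = config or PhasingConfig()
    bands = sorted(
        family.seed_parent.bands
        | family.pollen_parent.bands
        | set().union(*(p.bands for p in family.progeny))
    )
    n = family.n_progeny
    present = {b: sum(b in p.bands for p in family.progeny) for b in bands}
    in_seed = {b: b in family.seed_parent.bands for b in bands}
    in_pollen = {b: b in family.pollen_parent.bands for b in bands}
    classification: dict[str, str] = {}
    conflicting: dict[str, list[str]] = {}
    for b in bands:
        if in_seed[b] and in_pollen[b]:
            freq = present[b] / n
            classification[b] = "monomorphic" if freq >= _GUARANTEED else "shared"
        elif in_seed[b]:
            classification[b] = "seed-informative"
        elif in_pollen[b]:
            classification[b] = "pollen-informative"
        else:
            classification[b] = "conflicting"
            conflicting[b] = [p.accession for p in family.progeny if b in p.bands]
    warnings = []
    if n < config.min_informative_progeny:
        warnings.append(
            f"family {family.id}: only {n} progeny (< {config.min_informative_progeny}); "
            "phasing downgraded to low confidence"
        )
    return SegregationStats(
        family_id=family.id,
        n_progeny=n,
        present=present,
        in_seed=in_seed,
        in_pollen=in_pollen,
        classification=classification,
        conflicting_progeny=conflicting,
        warnings=warnings,
    )


@dataclass
class PhasedHaplotype:
    """One parental haplotype: definitely assigned bands plus bands whose
    presence is consistent with, but not proven by, this family."""

    bands: frozenset[str]
    ambiguous: frozenset[str] = frozenset()

    @property
    def possible(self) -> frozenset[str]:
        return self.bands | self.ambiguous


@dataclass
class PhasedParent:
    parent_accession: str
    family_id: str
    haplotypes: list[PhasedHaplotype]
    homozygous: bool
    low_confidence: bool = False
    warnings: list[str] = field(default_factory=list)


def _progeny_backbone(
    family: Family, group_a: list[str], group_b: list[str]
) -> tuple[list[int], list[int]]:
    """Assign each progeny to the parental haplotype whose informative-band
    pattern it matches; ties (noise-corrupted patterns) are left out."""
    idx_a, idx_b = [], []
    for i, child in enumerate(family.progeny):
        score_a = sum(b in child.bands for b in group_a) + sum(b not in child.bands for b in group_b)
        score_b = sum(b in child.bands for b in group_b) + sum(b not in child.bands for b in group_a)
        if score_a > score_b:
            idx_a.append(i)
        elif score_b > score_a:
            idx_b.append(i)
    return idx_a, idx_b


def phase_parent(
    family: Family,
    parent: str,
    config: PhasingConfig | None = None,
    monomorphic_bands: frozenset[str] | None = None,
) -> PhasedParent:
    """Phase one parent of a family into one (homozygote) or two haplotypes.

    Parameters
    ----------
    parent : "seed" or "pollen"
    monomorphic_bands : study-wide monomorphic bands, if known.  These join
        both haplotypes definitively; without this knowledge a band that is
        merely family-monomorphic is carried as ambiguous.
    """
    config = config or PhasingConfig()
    if parent not in {"seed", "pollen"}:
        raise ValidationError(f"parent must be 'seed' or 'pollen', got {parent!r}")
    stats = segregation_stats(family, config)
    mono_known = monomorphic_bands or frozenset()
    mine = family.seed_parent.bands if parent == "seed" else family.pollen_parent.bands
    my_class = f"{parent}-informative"
    n = stats.n_progeny
    warnings = list(stats.warnings)

    het: list[str] = []            # heterozygous informative bands (~50%)
    both_definite: set[str] = set()
    shared: list[str] = []         # bands in both parents, placed by backbone below
    for b in sorted(mine):
        cls = stats.classification[b]
        freq = stats.frequency(b)
        if b in mono_known:
            both_definite.add(b)
        elif cls == my_class:
            if freq >= _ON:
                both_definite.add(b)      # on both chromosomes of this parent
            elif freq >= _LOW:
                het.append(b)
            else:
                warnings.append(
                    f"{family.id}/{parent}: band {b} at progeny frequency {freq:.2f} "
                    "is too rare for a parental band; left unassigned"
                )
        else:  # carried by both parents
            shared.append(b)

    if not het:
        # no heterozygous informative band: the parent is homozygous and its
        # single haplotype is its full band set
        hap = PhasedHaplotype(bands=frozenset(both_definite) | frozenset(shared))
        if not hap.possible:
            raise ValidationError(f"{family.id}/{parent}: no bands to phase")
        return PhasedParent(
            parent_accession=(family.seed_parent if parent == "seed" else family.pollen_parent).accession,
            family_id=family.id,
            haplotypes=[hap],
            homozygous=True,
            low_confidence=n < config.min_informative_progeny,
            warnings=warnings,
        )

    # 2-colour the heterozygous bands: same phase when presence patterns agree
    # in the majority of progeny, anti-phase when they complement.
    presence = {b: [b in p.bands for p in family.progeny] for b in het}
    anchor = het[0]
    color = {anchor: 0}
    for b in het[1:]:
        agree = sum(x == y for x, y in zip(presence[anchor], presence[b])) / n
        color[b] = 0 if agree > 0.5 else 1
    # verify the signing is balanced; report pairs that contradict the colouring
    conflicts = []
    for i, a in enumerate(het):
        for b in het[i + 1 :]:
            agree = sum(x == y for x, y in zip(presence[a], presence[b])) / n
            same_expected = color[a] == color[b]
            if (agree > 0.5) != same_expected:
                discordant = [
                    family.progeny[k].accession
                    for k in range(n)
                    if (presence[a][k] == presence[b][k]) != same_expected
                ]
                conflicts.append((a, b, discordant))
            elif min(agree, 1 - agree) > config.epsilon:
                warnings.append(
                    f"{family.id}/{parent}: noisy pair ({a}, {b}); "
                    f"{min(agree, 1 - agree):.2f} discordant progeny"
                )
    if conflicts:
        detail = "; ".join(f"{a}~{b} ({len(d)} discordant progeny: {d[:5]})" for a, b, d in conflicts)
        raise PhasingConflict(
            f"{family.id}/{parent}: band pairs admit no two-haplotype phase: {detail}"
        )

    group_a = [b for b in het if color[b] == 0]
    group_b = [b for b in het if color[b] == 1]
    idx_a, idx_b = _progeny_backbone(family, group_a, group_b)

    hap_a_bands = set(group_a) | both_definite
    hap_b_bands = set(group_b) | both_definite
    hap_a_amb: set[str] = set()
    hap_b_amb: set[str] = set()
    for b in shared:
        # a shared band sits on at least one of this parent's haplotypes;
        # condition it on the two phased backbones.  If only one backbone
        # always shows it, that haplotype carries it; if both do, the other
        # parent guarantees transmission and the family cannot localise it —
        # record the ambiguity instead of guessing.
        def q(idx: list[int]) -> float | None:
            if not idx:
                return None
            return sum(b in family.progeny[k].bands for k in idx) / len(idx)

        qa, qb = q(idx_a), q(idx_b)
        on_a = qa is not None and qa >= _ON
        on_b = qb is not None and qb >= _ON
        if on_a and not on_b:
            hap_a_bands.add(b)
        elif on_b and not on_a:
            hap_b_bands.add(b)
        else:
            if not (on_a or on_b):
                warnings.append(
                    f"{family.id}/{parent}: shared band {b} fits neither backbone "
                    "cleanly; recorded as ambiguous on both haplotypes"
                )
            hap_a_amb.add(b)
            hap_b_amb.add(b)

    haps = [
        PhasedHaplotype(frozenset(hap_a_bands), frozenset(hap_a_amb)),
        PhasedHaplotype(frozenset(hap_b_bands), frozenset(hap_b_amb)),
    ]
    haps.sort(key=lambda h: sorted(h.bands))
    return PhasedParent(
        parent_accession=(family.seed_parent if parent == "seed" else family.pollen_parent).accession,
        family_id=family.id,
        haplotypes=haps,
        homozygous=False,
        low_confidence=n < config.min_informative_progeny,
        warnings=warnings,
    )


@dataclass
class CatalogBuild:
    catalog: HaplotypeCatalog
    provenance: dict[str, list[str]]          # haplotype id -> parent carriers
    phased_parents: list[PhasedParent]
    monomorphic_bands: frozenset[str]
    unresolved_ambiguities: list[tuple[str, frozenset[str], frozenset[str]]]
    near_identical: list[tuple[str, str]]     # candidate genotyping errors
    warnings: list[str] = field(default_factory=list)


def _study_monomorphic(families: list[Family]) -> frozenset[str]:
    """Bands present in every parent and in essentially all progeny of every
    family are monomorphic at the study level and join every haplotype."""
    candidates: set[str] | None = None
    for fam in families:
        stats = segregation_stats(fam)
        mono = {b for b, c in stats.classification.items() if c == "monomorphic"}
        candidates = mono if candidates is None else candidates & mono
    return frozenset(candidates or set())


def build_catalog(
    families: list[Family], config: PhasingConfig | None = None
) -> CatalogBuild:
    """Phase every parent of every family and merge the results into one
    haplotype catalog.

    Haplotypes with identical definite band sets merge under one id.  A
    haplotype carrying ambiguous bands is matched against the definite pool:
    if exactly one definite haplotype lies between its definite and possible
    band sets, the ambiguity resolves to it; otherwise the definite set
    stands and the open ambiguity is reported.  The result is independent of
    family and progeny ordering.
    """
    config = config or PhasingConfig()
    mono = _study_monomorphic(families)
    phased: list[PhasedParent] = []
    warnings: list[str] = []
    for fam in sorted(families, key=lambda f: f.id):
        for parent in ("seed", "pollen"):
            pp = phase_parent(fam, parent, config, monomorphic_bands=mono)
            phased.append(pp)
            warnings.extend(pp.warnings)

    # mutable working entries with sibling links: a parent's two haplotypes
    # jointly cover the parent's band set, so resolving one constrains the other
    entries: list[dict] = []
    for pp in phased:
        group = [
            {"pp": pp, "bands": set(h.bands), "amb": set(h.ambiguous), "sibling": None,
             "done": False}
            for h in pp.haplotypes
        ]
        if len(group) == 2:
            group[0]["sibling"], group[1]["sibling"] = group[1], group[0]
        entries.extend(group)

    carriers: dict[frozenset[str], list[str]] = {}
    unresolved: list[tuple[str, frozenset[str], frozenset[str]]] = []

    def finish(entry: dict, bands: frozenset[str]) -> None:
        carriers.setdefault(bands, []).append(entry["pp"].parent_accession)
        entry["done"] = True

    def sort_key(entry: dict):
        return (-len(entry["bands"]), sorted(entry["bands"]), sorted(entry["amb"]))

    while any(not e["done"] for e in entries):
        progress = False
        for e in sorted((e for e in entries if not e["done"]), key=sort_key):
            if not e["amb"]:
                finish(e, frozenset(e["bands"]))
                progress = True
        for e in sorted((e for e in entries if not e["done"]), key=sort_key):
            lo, hi = frozenset(e["bands"]), frozenset(e["bands"] | e["amb"])
            matches = [known for known in carriers if lo <= known <= hi]
            if len(matches) == 1:
                resolved = matches[0]
                finish(e, resolved)
                sib = e["sibling"]
                if sib is not None and not sib["done"]:
                    # any ambiguous band absent from the resolved haplotype
                    # must sit on the parent's other haplotype
                    for b in sorted(e["amb"] - resolved):
                        if b in sib["amb"]:
                            sib["amb"].discard(b)
                            sib["bands"].add(b)
                progress = True
            elif len(matches) > 1:
                unresolved.append(
                    (e["pp"].parent_accession, frozenset(e["bands"]), frozenset(e["amb"]))
                )
                warnings.append(
                    f"{e['pp'].family_id}/{e['pp'].parent_accession}: haplotype with "
                    f"ambiguous bands {sorted(e['amb'])} matches several catalog "
                    "haplotypes; not merged"
                )
                e["done"] = True
                progress = True
        if not progress:
            # nothing resolves: promote the most constrained pending entry,
            # taking its definite band set as a haplotype
            e = sorted((e for e in entries if not e["done"]), key=sort_key)[0]
            unresolved.append(
                (e["pp"].parent_accession, frozenset(e["bands"]), frozenset(e["amb"]))
            )
            finish(e, frozenset(e["bands"]))

    ordered = sorted(carriers, key=lambda s: sorted(s))
    hap_ids = {bands: f"H{i + 1}" for i, bands in enumerate(ordered)}
    near = [
        (hap_ids[a], hap_ids[b])
        for i, a in enumerate(ordered)
        for b in ordered[i + 1 :]
        if len(a ^ b) == 1
    ]

    all_bands = sorted(set().union(*ordered)) if ordered else []
    registry = [
        Band(b, _band_size(b), monomorphic=b in mono) for b in all_bands
    ]
    haplotypes = [
        Haplotype(hap_ids[bands], bands, source="family_phased") for bands in ordered
    ]
    catalog = HaplotypeCatalog(haplotypes=haplotypes, bands=registry)
    provenance = {hap_ids[bands]: sorted(set(carriers[bands])) for bands in ordered}
    return CatalogBuild(
        catalog=catalog,
        provenance=provenance,
        phased_parents=phased,
        monomorphic_bands=mono,
        unresolved_ambiguities=unresolved,
        near_identical=near,
        warnings=warnings,
    )


def _band_size(band_id: str) -> int:
    try:
        return int(band_id.lstrip("a"))
    except ValueError:
        return 1
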
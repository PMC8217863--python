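"""Explain unrelated accessions as unions of two catalog haplotypes.

Because the cluster is effectively non-recombining and bands are dominant, an
accession's genotype is exactly the union of its two haplotypes' band sets.
Explaining a panel therefore reduces to set arithmetic: try all unordered
catalog pairs (including self-pairs for homozygotes), and for the remainder
infer a minimal number of new haplotypes by parsimony — preferring a pair of
existing haplotypes, then one existing plus one new, then two new.

Ambiguous accessions (several pairs produce the same union — e.g. when two
haplotypes differ only by a band the partner also carries) are reported as
ambiguous, never resolved by frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

from .model import BandGenotype, Diplotype, Haplotype, HaplotypeCatalog

__all__ = [
    "PanelCallResult",
    "explain_accession",
    "infer_panel_haplotypes",
    "exhaustive_min_new_haplotypes",
]


def explain_accession(genotype: BandGenotype, catalog: HaplotypeCatalog) -> Diplotype:
    """Exhaustively test all unordered catalog pairs against an accession.

    status=explained with the unique pair when exactly one union matches,
    ambiguous with all matching pairs listed when several do, unexplained
    otherwise.
    """
    matches = [
        (a.id, b.id)
        for a, b in combinations_with_replacement(
            sorted(catalog.haplotypes, key=lambda h: h.id), 2
        )
        if a.bands | b.bands == genotype.bands
    ]
    if len(matches) == 1:
        return Diplotype(genotype.accession, matches[0], "explained")
    if matches:
        return Diplotype(genotype.accession, matches[0], "ambiguous", alternatives=matches)
    return Diplotype(genotype.accession, None, "unexplained")


def _gene_counts(bands: frozenset[str], gene_map: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for b in bands:
        counts[gene_map.get(b, "unknown")] = counts.get(gene_map.get(b, "unknown"), 0) + 1
    return counts


def _valid_new_haplotype(
    bands: frozenset[str],
    monomorphic: frozenset[str],
    gene_map: dict[str, str] | None,
    g1_copy_range: tuple[int, int],
) -> bool:
    """Upper-bound gene-group constraints only: G2/G3 are single-copy, G1 at
    most the configured maximum.  No lower bounds — bands of unknown homology
    (typically rare, uncloned alleles) may stand in for any gene."""
    if not bands or not monomorphic <= bands:
        return False
    if gene_map is None:
        return True
    counts = _gene_counts(bands, gene_map)
    if counts.get("G2", 0) > 1 or counts.get("G3", 0) > 1:
        return False
    return counts.get("G1", 0) <= g1_copy_range[1]


def _candidate_new(
    genotype: BandGenotype,
    catalog_haps: dict[str, frozenset[str]],
    monomorphic: frozenset[str],
    gene_map: dict[str, str] | None,
    g1_copy_range: tuple[int, int],
) -> list[tuple[str, frozenset[str]]]:
    """All (existing haplotype, residual new haplotype) explanations of an
    accession, residual = observed bands minus the existing haplotype plus the
    monomorphic backbone."""
    out = []
    for hid, hbands in sorted(catalog_haps.items()):
        if hbands <= genotype.bands:
            residual = frozenset((genotype.bands - hbands) | (monomorphic & genotype.bands))
            if residual and _valid_new_haplotype(residual, monomorphic, gene_map, g1_copy_range):
                out.append((hid, residual))
    return out


def _bipartitions(
    genotype: BandGenotype,
    monomorphic: frozenset[str],
    gene_map: dict[str, str] | None,
    g1_copy_range: tuple[int, int],
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """All two-new-haplotype explanations: unordered covers (N1, N2) with
    N1 | N2 = bands, both containing the monomorphic backbone."""
    mono = monomorphic & genotype.bands
    free = sorted(genotype.bands - mono)
    seen = set()
    out = []
    # each free band goes to N1, N2 or both
    for assign in range(3 ** len(free)):
        n1, n2 = set(mono), set(mono)
        x = assign
        for b in free:
            x, r = divmod(x, 3)
            if r == 0:
                n1.add(b)
            elif r == 1:
                n2.add(b)
            else:
                n1.add(b)
                n2.add(b)
        key = frozenset((frozenset(n1), frozenset(n2)))
        if key in seen:
            continue
        seen.add(key)
        f1, f2 = frozenset(n1), frozenset(n2)
        if _valid_new_haplotype(f1, monomorphic, gene_map, g1_copy_range) and _valid_new_haplotype(
            f2, monomorphic, gene_map, g1_copy_range
        ):
            out.append((f1, f2))
    return out


@dataclass
class PanelCallResult:
    extended_catalog: HaplotypeCatalog
    diplotypes: dict[str, Diplotype]
    explained_fraction: float              # on the original catalog only
    new_haplotypes: list[Haplotype]
    unexplained: list[str] = field(default_factory=list)
    greedy: bool = True


def infer_panel_haplotypes(
    panel: list[BandGenotype],
    catalog: HaplotypeCatalog,
    gene_map: dict[str, str] | None = None,
    g1_copy_range: tuple[int, int] = (1, 3),
) -> PanelCallResult:
    """Greedy parsimony haplotype calling over a panel.

    Accessions are first tested against the original catalog; the explained
    fraction reported refers to that catalog only.  Unexplained accessions
    are processed in descending band-count order (ties by accession id) and
    each accepted new haplotype joins the working catalog before the next
    accession is considered.  New haplotypes prefer the smallest residual
    (ties by sorted band content) for reproducibility.
    """
    monomorphic = catalog.monomorphic_bands()
    base_explained = {g.accession: explain_accession(g, catalog) for g in panel}
    n_explained = sum(
        1 for d in base_explained.values() if d.status in {"explained", "ambiguous"}
    )
    explained_fraction = n_explained / len(panel) if panel else 0.0

    working = catalog
    diplotypes = dict(base_explained)
    new_haps: list[Haplotype] = []
    unexplained_final: list[str] = []
    todo = sorted(
        (g for g in panel if base_explained[g.accession].status == "unexplained"),
        key=lambda g: (-len(g.bands), g.accession),
    )
    next_id = 7
    existing_sets = {h.id: h.bands for h in working.haplotypes}

    def add_new(bands: frozenset[str]) -> str:
        nonlocal next_id
        for hid, hbands in existing_sets.items():
            if hbands == bands:
                return hid
        hid = f"Hi{next_id}"
        next_id += 1
        existing_sets[hid] = bands
        hap = Haplotype(hid, bands, source="panel_inferred")
        new_haps.append(hap)
        return hid

    for g in todo:
        # (i) a pair of now-existing haplotypes
        call = explain_accession(g, _as_catalog(working, existing_sets))
        if call.status != "unexplained":
            diplotypes[g.accession] = call
            continue
        # (ii) one existing + one new (smallest residual wins)
        candidates = _candidate_new(g, existing_sets, monomorphic, gene_map, g1_copy_range)
        if candidates:
            hid, residual = min(candidates, key=lambda c: (len(c[1]), sorted(c[1]), c[0]))
            new_id = add_new(residual)
            diplotypes[g.accession] = Diplotype(
                g.accession, tuple(sorted((hid, new_id))), "explained"
            )
            continue
        # (iii) two new haplotypes
        pairs = _bipartitions(g, monomorphic, gene_map, g1_copy_range)
        if pairs:
            n1, n2 = min(
                pairs, key=lambda p: (len(p[0]) + len(p[1]), sorted(sorted(b) for b in p))
            )
            id1, id2 = add_new(n1), add_new(n2)
            diplotypes[g.accession] = Diplotype(
                g.accession, tuple(sorted((id1, id2))), "explained"
            )
            continue
        diplotypes[g.accession] = Diplotype(
            g.accession,
            None,
            "unexplained",
            reason="no residual satisfies the monomorphic-band / gene-group constraints",
        )
        unexplained_final.append(g.accession)

    extended = _as_catalog(working, existing_sets)
    return PanelCallResult(
        extended_catalog=extended,
        diplotypes=diplotypes,
        explained_fraction=explained_fraction,
        new_haplotypes=new_haps,
        unexplained=unexplained_final,
        greedy=True,
    )


def _as_catalog(
    base: HaplotypeCatalog,
    existing_sets: dict[str, frozenset[str]],
) -> HaplotypeCatalog:
    from .model import Band

    known = {h.id for h in base.haplotypes}
    registry_ids = {b.id for b in base.bands}
    extra_bands = sorted(
        set().union(*existing_sets.values()) - registry_ids
    ) if existing_sets else []
    registry = list(base.bands) + [
        Band(b, int(b.lstrip("a")) if b.lstrip("a").isdigit() else 1) for b in extra_bands
    ]
    haps = list(base.haplotypes) + [
        Haplotype(hid, bands, source="panel_inferred")
        for hid, bands in sorted(existing_sets.items())
        if hid not in known
    ]
    return HaplotypeCatalog(haplotypes=haps, bands=registry)


def exhaustive_min_new_haplotypes(
    unexplained: list[BandGenotype],
    catalog: HaplotypeCatalog,
    gene_map: dict[str, str] | None = None,
    g1_copy_range: tuple[int, int] = (1, 3),
    max_new: int = 8,
) -> int:
    """Exact minimum number of new haplotypes explaining every unexplained
    accession, by depth-first search with iterative deepening.

    Any haplotype pair explaining an accession is a two-set cover of its band
    union, so branching enumerates the precomputed valid covers of each
    accession and counts how many cover halves are new.  Only feasible for
    small instances (<= ~8 accessions); used to audit the greedy inference.
    """
    monomorphic = catalog.monomorphic_bands()
    base = frozenset(h.bands for h in catalog.haplotypes)
    order = sorted(unexplained, key=lambda g: (-len(g.bands), g.accession))
    covers = {
        g.accession: _bipartitions(g, monomorphic, gene_map, g1_copy_range) for g in order
    }

    def explained_by(g: BandGenotype, sets: frozenset[frozenset[str]]) -> bool:
        items = sorted(sets, key=sorted)
        return any(
            a | b == g.bands for a, b in combinations_with_replacement(items, 2)
        )

    def search(i: int, sets: frozenset[frozenset[str]], budget: int) -> bool:
        while i < len(order) and explained_by(order[i], sets):
            i += 1
        if i == len(order):
            return True
        if budget == 0:
            return False
        g = order[i]
        options = []
        for n1, n2 in covers[g.accession]:
            cost = (n1 not in sets) + (n2 not in sets and n2 != n1)
            if 0 < cost <= budget:
                options.append((cost, n1, n2))
        options.sort(key=lambda o: (o[0], sorted(sorted(b) for b in o[1:])))
        for cost, n1, n2 in options:
            if search(i + 1, sets | {n1, n2}, budget - cost):
                return True
        return False

    for k in range(max_new + 1):
        if search(0, base, k):
            return k
    raise RuntimeError(f"no solution with <= {max_new} new haplotypes")
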
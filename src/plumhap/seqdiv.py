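"""Sequence statistics of cloned amplicon alleles.

Covers nucleotide diversity (pi) with explicit gap handling, pairwise Ka/Ks
by Nei-Gojobori (1986) pathway counting with Jukes-Cantor correction,
Tamura-Nei (1993) distances, and UPGMA clustering with column-resampling
bootstrap supports.  Trees are scikit-bio ``TreeNode`` objects, so Newick
output and manipulation come for free.

Gap semantics for pi are deliberately explicit because tooling conventions
differ: ``gap_as_state`` (default) scores a base-gap mismatch as a difference
and ignores gap-gap sites, so indel variation contributes to diversity;
``pairwise_deletion`` drops any site gapped in either sequence of a pair;
``complete_deletion`` drops columns gapped in any sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from skbio import TreeNode

from .model import PlumhapError, ValidationError

__all__ = [
    "AlignedSet",
    "DiversityResult",
    "KaKsResult",
    "KaKsPanel",
    "TreeResult",
    "nucleotide_diversity",
    "ka_ks_pair",
    "ka_ks_panel",
    "tn93_distance",
    "distance_matrix",
    "upgma",
    "bootstrap_supports",
]

_ALPHABET = set("ACGT-N")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class AlignedSet:
    """Equal-length gapped sequences over {A,C,G,T,-,N} with an optional
    boolean partition mask (True marks e.g. intron columns)."""

    ids: list[str]
    sequences: list[str]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError(f"sequences are not aligned (lengths {sorted(lengths)})")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _ALPHABET
        if bad:
            raise ValidationError(f"unexpected characters in alignment: {sorted(bad)}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != self.length:
                raise ValidationError("mask length does not match alignment length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_records(cls, records: list[tuple[str, str]], mask=None) -> "AlignedSet":
        return cls([r[0] for r in records], [r[1] for r in records], mask)

    def subset_columns(self, keep: np.ndarray) -> "AlignedSet":
        keep = np.asarray(keep)
        idx = np.nonzero(keep)[0] if keep.dtype == bool else keep
        seqs = ["".join(s[i] for i in idx) for s in self.sequences]
        return AlignedSet(list(self.ids), seqs)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    pi: float
    n_sequences: int
    sites_used: float          # mean per-pair site count
    gap_mode: str
    partitions: dict[str, "DiversityResult"] = field(default_factory=dict)


def _pair_diff(s1: str, s2: str, gap_mode: str) -> tuple[int, int]:
    """(differences, comparable sites) for one sequence pair."""
    diffs = sites = 0
    for x, y in zip(s1, s2):
        if "N" in (x, y):
            continue
        if gap_mode == "gap_as_state":
            if x == "-" and y == "-":
                continue
            sites += 1
            diffs += x != y
        else:  # pairwise deletion semantics (complete handled by column subset)
            if "-" in (x, y):
                continue
            sites += 1
            diffs += x != y
    return diffs, sites


def nucleotide_diversity(
    aln: AlignedSet,
    gap_mode: str = "gap_as_state",
    partition_mask: np.ndarray | None = None,
    partition_names: tuple[str, str] = ("intron", "exon"),
) -> DiversityResult:
    """Average pairwise nucleotide differences per site.

    pi is the mean over all sequence pairs of (differences / comparable
    sites).  With a partition mask, per-partition pi is computed on the
    masked / unmasked columns (mask True -> first partition name).
    """
    if gap_mode not in {"gap_as_state", "pairwise_deletion", "complete_deletion"}:
        raise ValidationError(f"unknown gap_mode {gap_mode!r}")
    if aln.n < 2:
        raise ValidationError("diversity requires at least 2 sequences")
    work = aln
    if gap_mode == "complete_deletion":
        keep = np.array(
            [all(s[i] != "-" for s in aln.sequences) for i in range(aln.length)]
        )
        work = aln.subset_columns(keep)
        if partition_mask is not None:
            partition_mask = np.asarray(partition_mask, dtype=bool)[keep]
    props, sites_used = [], []
    for s1, s2 in combinations(work.sequences, 2):
        d, L = _pair_diff(s1, s2, gap_mode)
        if L > 0:
            props.append(d / L)
            sites_used.append(L)
    if not props:
        raise ValidationError("no comparable sites in any pair")
    result = DiversityResult(
        pi=float(np.mean(props)),
        n_sequences=aln.n,
        sites_used=float(np.mean(sites_used)),
        gap_mode=gap_mode,
    )
    mask = partition_mask if partition_mask is not None else (
        aln.mask if gap_mode != "complete_deletion" else None
    )
    if gap_mode == "complete_deletion" and partition_mask is None and aln.mask is not None:
        keep = np.array([all(s[i] != "-" for s in aln.sequences) for i in range(aln.length)])
        mask = aln.mask[keep]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        for name, sel in ((partition_names[0], mask), (partition_names[1], ~mask)):
            if not sel.any():
                raise ValidationError(f"partition {name!r} selects no columns")
            sub = work.subset_columns(sel)
            result.partitions[name] = nucleotide_diversity(
                sub, "pairwise_deletion" if gap_mode == "complete_deletion" else gap_mode
            )
    return result


# ---------------------------------------------------------------------------
# Ka/Ks (Nei-Gojobori 1986, Jukes-Cantor corrected)
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon."""
    syn = 0.0
    aa = _CODON_TABLE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons,
    averaged over all substitution pathways with equal weight; pathways that
    pass through a stop codon are excluded when any stop-free pathway exists."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        syn = non = 0.0
        current = c1
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if _CODON_TABLE[nxt] == "*" and nxt != c2:
                blocked = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                syn += 1
            else:
                non += 1
            current = nxt
        pathways.append((syn, non, blocked))
    open_paths = [(s, n) for s, n, b in pathways if not b]
    use = open_paths or [(s, n) for s, n, _ in pathways]
    syn = sum(s for s, _ in use) / len(use)
    non = sum(n for _, n in use) / len(use)
    return syn, non


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise PlumhapError(f"proportion {p:.3f} saturates the Jukes-Cantor correction")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None          # None when Ks = 0 (undefined)
    codons_used: int
    method: str = "NG86+JC"


def ka_ks_pair(seq1: str, seq2: str) -> KaKsResult:
    """Nei-Gojobori Ka and Ks for one coding sequence pair.

    Codons containing gaps or N in either sequence are excluded pairwise;
    internal stop codons are rejected.
    """
    if len(seq1) != len(seq2):
        raise ValidationError("coding sequences must be aligned (equal length)")
    if len(seq1) % 3:
        raise ValidationError("aligned coding length must be a multiple of 3")
    seq1, seq2 = seq1.upper(), seq2.upper()
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue
        if _CODON_TABLE[c1] == "*" or _CODON_TABLE[c2] == "*":
            raise ValidationError(f"internal stop codon at position {i}")
        used += 1
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pathway_changes(c1, c2)
        Sd += sd
        Nd += nd
    if used == 0:
        raise ValidationError("no comparable codons")
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ka, ks = _jc_correct(pn), _jc_correct(ps)
    return KaKsResult(ka=ka, ks=ks, ratio=(ka / ks if ks > 0 else None), codons_used=used)


@dataclass
class KaKsPanel:
    pairs: dict[tuple[str, str], KaKsResult]
    mean_ratio: float | None
    n_pairs: int
    n_undefined: int


def ka_ks_panel(aln: AlignedSet) -> KaKsPanel:
    """All C(n,2) pairwise Ka/Ks comparisons; the panel mean averages the
    defined ratios and discloses how many pairs were excluded (Ks = 0)."""
    pairs: dict[tuple[str, str], KaKsResult] = {}
    for (i1, s1), (i2, s2) in combinations(zip(aln.ids, aln.sequences), 2):
        pairs[(i1, i2)] = ka_ks_pair(s1, s2)
    ratios = [r.ratio for r in pairs.values() if r.ratio is not None]
    return KaKsPanel(
        pairs=pairs,
        mean_ratio=float(np.mean(ratios)) if ratios else None,
        n_pairs=len(pairs),
        n_undefined=sum(1 for r in pairs.values() if r.ratio is None),
    )


# ---------------------------------------------------------------------------
# Tamura-Nei 1993 distance
# ---------------------------------------------------------------------------

def tn93_distance(seq1: str, seq2: str) -> float:
    """Closed-form TN93 distance with empirical base frequencies from the
    pair.  Gapped or N sites are pairwise-deleted.  A saturated pair (any
    logarithm argument <= 0) returns ``inf``."""
    pairs = [
        (x, y)
        for x, y in zip(seq1.upper(), seq2.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        raise ValidationError("no comparable sites for TN93")
    L = len(pairs)
    counts = {b: 0 for b in "ACGT"}
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
    g = {b: counts[b] / (2 * L) for b in "ACGT"}
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    p1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / L
    p2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / L
    q = sum(1 for x, y in pairs if (x in "AG") != (y in "AG")) / L
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    try:
        k1 = 2 * g["A"] * g["G"] / gR
        k2 = 2 * g["T"] * g["C"] / gY
        k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["T"] * g["C"] * gR / gY)
        w1 = 1 - p1 / k1 - q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - p2 / k2 - q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - q / (2 * gR * gY)
        if min(w1, w2, w3) <= 0:
            return float("inf")
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    except (ValueError, ZeroDivisionError):
        return float("inf")


def distance_matrix(aln: AlignedSet, metric=tn93_distance) -> tuple[list[str], np.ndarray]:
    n = aln.n
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = metric(aln.sequences[i], aln.sequences[j])
        mat[i, j] = mat[j, i] = d
    return list(aln.ids), mat


# ---------------------------------------------------------------------------
# UPGMA and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class TreeResult:
    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_replicates: int = 0
    seed: int | None = None

    def newick(self) -> str:
        tree = self.tree.copy()
        if self.supports:
            for node in tree.non_tips():
                clade = frozenset(t.name for t in node.tips())
                if clade in self.supports:
                    node.name = f"{self.supports[clade]:.2f}"
        return str(tree)


def upgma(ids: list[str], matrix: np.ndarray) -> TreeResult:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Ties between equally close cluster pairs break on the lexicographically
    lowest (sorted member id) pair, so output is deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(ids), len(ids)):
        raise ValidationError("matrix shape does not match ids")
    if not np.allclose(matrix, matrix.T, equal_nan=True):
        raise ValidationError("distance matrix must be symmetric")
    if (matrix < 0).any():
        raise ValidationError("distance matrix must be non-negative")
    if len(ids) == 1:
        return TreeResult(tree=TreeNode(name=ids[0]))
    clusters: dict[int, dict] = {
        i: {"members": (ids[i],), "height": 0.0, "node": TreeNode(name=ids[i]), "size": 1}
        for i in range(len(ids))
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(matrix[i, j]) for i, j in combinations(range(len(ids)), 2)
    }
    next_key = len(ids)
    while len(clusters) > 1:
        best_key = min(
            dist,
            key=lambda k: (
                dist[k],
                sorted((clusters[k[0]]["members"], clusters[k[1]]["members"])),
            ),
        )
        i, j = best_key
        d = dist[best_key]
        hi, hj = clusters.pop(i), clusters.pop(j)
        height = d / 2
        hi["node"].length = max(0.0, height - hi["height"])
        hj["node"].length = max(0.0, height - hj["height"])
        ordered = sorted((hi, hj), key=lambda c: c["members"])
        node = TreeNode(children=[c["node"] for c in ordered])
        old = {}
        for (a, b), val in list(dist.items()):
            if i in (a, b) or j in (a, b):
                other = b if a in (i, j) else a
                old.setdefault(other, {})[a if a in (i, j) else b] = val
                del dist[(a, b)]
        merged = {
            "members": tuple(sorted(hi["members"] + hj["members"])),
            "height": height,
            "node": node,
            "size": hi["size"] + hj["size"],
        }
        for k in clusters:
            d_ik, d_jk = old[k][i], old[k][j]
            new_d = (hi["size"] * d_ik + hj["size"] * d_jk) / (hi["size"] + hj["size"])
            dist[(min(k, next_key), max(k, next_key))] = new_d
        clusters[next_key] = merged
        next_key += 1
    root = next(iter(clusters.values()))["node"]
    root.length = None
    return TreeResult(tree=root)


def _clades(tree: TreeNode) -> set[frozenset]:
    out = set()
    for node in tree.non_tips(include_self=False):
        out.add(frozenset(t.name for t in node.tips()))
    return out


def bootstrap_supports(
    aln: AlignedSet,
    B: int = 500,
    seed: int = 0,
    metric=tn93_distance,
) -> TreeResult:
    """UPGMA tree of the full alignment with column-resampling bootstrap.

    Each replicate resamples alignment columns with replacement, rebuilds the
    distance matrix and the UPGMA tree; support of an internal node is the
    fraction of replicate trees containing the same leaf clade.
    """
    ids, mat = distance_matrix(aln, metric)
    result = upgma(ids, mat)
    clades = _clades(result.tree)
    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    L = aln.length
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep = aln.subset_columns(cols)
        rep_ids, rep_mat = distance_matrix(rep, metric)
        if not np.isfinite(rep_mat).all():
            continue  # saturated replicate: contributes no support
        rep_clades = _clades(upgma(rep_ids, rep_mat).tree)
        for c in clades & rep_clades:
            counts[c] += 1
    result.supports = {c: counts[c] / B for c in clades}
    result.n_replicates = B
    result.seed = seed
    return result
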
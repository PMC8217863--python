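"""Marker-trait association and the diplotype colour-prediction rule.

Band- or haplotype-carrier status is crossed with the binary anthocyanin
phenotype in a 2x2 table and tested with Pearson's chi-squared statistic
(1 df, upper tail, no continuity correction by default; a Yates-corrected
variant is available behind a flag).  Prediction: an accession is called
coloured iff it carries at least one haplotype bearing the predictive band
(or, without a diplotype call, iff the band itself is present).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _st

from .model import BandGenotype, Diplotype, HaplotypeCatalog, PhenotypeRecord, PlumhapError

__all__ = [
    "AssociationResult",
    "chisq_2x2",
    "scan_associations",
    "predict_from_diplotype",
    "evaluate_predictions",
    "ConfusionMatrix",
]


@dataclass
class AssociationResult:
    marker: str
    table: tuple[tuple[int, int], tuple[int, int]]  # carrier/non-carrier x presence/absence
    chi_squared: float
    p_value: float
    p_adjusted: float | None = None
    degenerate: bool = False

    @property
    def counts(self) -> tuple[int, int, int, int]:
        (a, b), (c, d) = self.table
        return a, b, c, d


def chisq_2x2(
    table: tuple[tuple[float, float], tuple[float, float]],
    yates: bool = False,
) -> tuple[float, float, bool]:
    """Pearson chi-squared test of a 2x2 table.

    Returns (statistic, upper-tail p at 1 df, degenerate flag).  The statistic
    uses the closed form n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); a zero row or
    column margin makes the table degenerate (statistic 0, p 1).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise PlumhapError("2x2 table cells must be non-negative")
    n = a + b + c + d
    if n <= 0:
        raise PlumhapError("2x2 table must have positive total")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        return 0.0, 1.0, True
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(_st.chi2.sf(chi2, df=1))
    return float(chi2), max(p, 5e-324), False


def _carrier(marker: str, genotype: BandGenotype | None, diplotype: Diplotype | None,
             catalog: HaplotypeCatalog | None) -> bool:
    if diplotype is not None and diplotype.pair is not None and catalog is not None:
        if marker in {h.id for h in catalog.haplotypes}:
            return marker in diplotype.pair
        return any(marker in catalog.haplotype(h).bands for h in diplotype.pair)
    if genotype is None:
        raise PlumhapError(f"no genotype or diplotype available to score marker {marker!r}")
    return marker in genotype.bands


def scan_associations(
    genotypes: list[BandGenotype],
    phenotypes: list[PhenotypeRecord],
    tissue: str = "skin",
    markers: list[str] | None = None,
    min_frequency: float = 0.05,
    bonferroni: bool = False,
    diplotypes: dict[str, Diplotype] | None = None,
    catalog: HaplotypeCatalog | None = None,
) -> list[AssociationResult]:
    """Chi-squared association of every marker with the binary phenotype.

    Markers below ``min_frequency`` carrier frequency or monomorphic across
    the panel (carried by everyone) are excluded from testing.  Results are
    sorted by ascending p; Bonferroni adjustment over the tested markers is
    off by default.
    """
    pheno = {p.accession: p for p in phenotypes}
    shared = [g for g in genotypes if g.accession in pheno]
    if not shared:
        return []
    if markers is None:
        markers = sorted(set().union(*(g.bands for g in shared)))
    results = []
    for marker in markers:
        carriers = {
            g.accession: _carrier(
                marker, g, (diplotypes or {}).get(g.accession), catalog
            )
            for g in shared
        }
        freq = sum(carriers.values()) / len(shared)
        if freq < min_frequency or freq == 1.0:
            continue  # too rare, or monomorphic hence untestable
        a = b = c = d = 0
        for g in shared:
            rec = pheno[g.accession]
            colored = rec.skin_binary if tissue == "skin" else rec.flesh_binary
            if colored is None:
                raise PlumhapError(f"phenotype for {g.accession!r} not binary-recoded")
            if carriers[g.accession]:
                a, b = (a + 1, b) if colored else (a, b + 1)
            else:
                c, d = (c + 1, d) if colored else (c, d + 1)
        chi2, p, degenerate = chisq_2x2(((a, b), (c, d)))
        results.append(AssociationResult(marker, ((a, b), (c, d)), chi2, p, degenerate=degenerate))
    if bonferroni:
        m = len(results)
        for r in results:
            r.p_adjusted = min(1.0, r.p_value * m)
    results.sort(key=lambda r: (r.p_value, r.marker))
    return results


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def predict_from_diplotype(
    predictive_band: str,
    genotype: BandGenotype | None = None,
    diplotype: Diplotype | None = None,
    catalog: HaplotypeCatalog | None = None,
) -> bool:
    """Predict coloured iff a carried haplotype contains the predictive band
    (falling back to raw band presence without a diplotype call)."""
    if catalog is not None and predictive_band not in {b.id for b in catalog.bands}:
        raise PlumhapError(f"predictive band {predictive_band!r} not in the band registry")
    return _carrier(predictive_band, genotype, diplotype, catalog)


def evaluate_predictions(
    predictive_band: str,
    genotypes: list[BandGenotype],
    phenotypes: list[PhenotypeRecord],
    diplotypes: dict[str, Diplotype] | None = None,
    catalog: HaplotypeCatalog | None = None,
    tissue: str = "skin",
) -> ConfusionMatrix:
    """Confusion matrix of the colour-prediction rule over a panel."""
    pheno = {p.accession: p for p in phenotypes}
    cm = ConfusionMatrix()
    for g in genotypes:
        rec = pheno.get(g.accession)
        if rec is None:
            continue
        observed = rec.skin_binary if tissue == "skin" else rec.flesh_binary
        predicted = predict_from_diplotype(
            predictive_band, g, (diplotypes or {}).get(g.accession), catalog
        )
        if predicted and observed:
            cm.tp += 1
        elif predicted and not observed:
            cm.fp += 1
        elif not predicted and not observed:
            cm.tn += 1
        else:
            cm.fn += 1
    return cm
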
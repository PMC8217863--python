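"""Read-depth summaries over the MYB10 cluster region.

Input is a per-base depth table (the samtools-depth dialect: sequence,
1-based position, depth; positions with zero depth may be absent and count
as zero).  Summaries report region mean depth, depth normalised to the
whole-track mean, breadth of coverage, and genic vs intergenic splits when a
gene annotation is supplied — the raw material for calling extra gene copies
from coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PlumhapError, Region, ValidationError, parse_region

__all__ = [
    "DepthTrack",
    "RegionSummary",
    "GenicIntergenicSummary",
    "normalized_depth",
    "breadth_of_coverage",
    "genic_intergenic_summary",
    "CLUSTER_REGIONS",
]

# Published MYB10 cluster spans (first base of the MYB10.2 5'UTR to the end of
# the MYB10.3 3'UTR) in the three reference genomes, as 1-based inclusive text.
CLUSTER_REGIONS: dict[str, Region] = {
    "peach": parse_region("LG3:18183274-18256025"),
    "sweet_cherry": parse_region("chr3:12147156-12215700"),
    "almond": parse_region("Pd03:15372325-15392346"),
}


@dataclass
class DepthTrack:
    """Per-sequence (positions, depths) arrays, 0-based internally.

    Positions must be strictly increasing per sequence; positions absent from
    the track have depth zero.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for seq, (pos, dep) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            dep = np.asarray(dep, dtype=float)
            if pos.size != dep.size:
                raise ValidationError(f"{seq}: positions and depths differ in length")
            if (np.diff(pos) <= 0).any():
                raise ValidationError(f"{seq}: positions must be strictly increasing")
            if (dep < 0).any():
                raise ValidationError(f"{seq}: negative depth")
            clean[seq] = (pos, dep)
        self.data = clean

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, one_based: bool = True) -> "DepthTrack":
        data = {}
        for seq, grp in df.groupby(df.columns[0], sort=False):
            pos = grp.iloc[:, 1].to_numpy(dtype=np.int64)
            if one_based:
                pos = pos - 1
            data[str(seq)] = (pos, grp.iloc[:, 2].to_numpy(dtype=float))
        return cls(data)

    def to_dataframe(self, one_based: bool = True) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"sequence": seq, "pos": pos + (1 if one_based else 0), "depth": dep}
            )
            for seq, (pos, dep) in self.data.items()
        ]
        return pd.concat(frames, ignore_index=True)

    @property
    def genome_mean(self) -> float:
        """Mean depth over all recorded track positions."""
        total = sum(dep.sum() for _, dep in self.data.values())
        n = sum(len(dep) for _, dep in self.data.values())
        if n == 0:
            raise ValidationError("empty depth track")
        return total / n

    def region_depths(self, region: Region) -> np.ndarray:
        """Per-base depth across a region, zeros for absent positions."""
        if region.sequence not in self.data:
            raise PlumhapError(f"sequence {region.sequence!r} not in depth track")
        pos, dep = self.data[region.sequence]
        out = np.zeros(len(region))
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        out[pos[lo:hi] - region.start] = dep[lo:hi]
        return out


@dataclass
class RegionSummary:
    region: Region
    mean_depth: float
    normalized_depth: float      # region mean / whole-track mean
    breadth: float               # fraction of positions with depth >= threshold
    min_depth_threshold: int = 1
    empty: bool = False


def normalized_depth(track: DepthTrack, region: Region, min_depth: int = 1) -> RegionSummary:
    """Region summary with depth normalised to the whole-track mean."""
    if len(region) == 0:
        raise ValidationError("empty region")
    gmean = track.genome_mean
    if gmean == 0:
        raise PlumhapError("whole-track mean depth is zero; cannot normalise")
    depths = track.region_depths(region)
    mean = float(depths.mean())
    return RegionSummary(
        region=region,
        mean_depth=mean,
        normalized_depth=mean / gmean,
        breadth=float((depths >= min_depth).mean()),
        min_depth_threshold=min_depth,
    )


def breadth_of_coverage(track: DepthTrack, region: Region, min_depth: int = 1) -> float:
    """Fraction of region positions covered at >= ``min_depth``."""
    return float((track.region_depths(region) >= min_depth).mean())


@dataclass
class GenicIntergenicSummary:
    genic: RegionSummary
    intergenic: RegionSummary | None
    genic_over_intergenic: float | None   # ratio of normalised depths
    genic_over_genome: float              # genic normalised depth itself
    genes: list[Region] = field(default_factory=list)


def genic_intergenic_summary(
    track: DepthTrack,
    cluster: Region,
    genes: list[Region],
    min_depth: int = 1,
) -> GenicIntergenicSummary:
    """Split the cluster into genic and intergenic parts and summarise both.

    The genic/genome ratio is the genic normalised depth; genic/intergenic
    divides the two normalised depths (both denominators are the whole-track
    mean, so the ratio equals the raw mean-depth ratio).
    """
    outside = [g for g in genes if not cluster.contains(g)]
    if outside:
        raise ValidationError(
            f"genes outside cluster region: {[f'{g.sequence}:{g.start}-{g.end}' for g in outside]}"
        )
    if not genes:
        raise ValidationError("no genes supplied")
    gmean = track.genome_mean
    if gmean == 0:
        raise PlumhapError("whole-track mean depth is zero; cannot normalise")
    genic_mask = np.zeros(len(cluster), dtype=bool)
    for g in genes:
        genic_mask[g.start - cluster.start : g.end - cluster.start] = True
    depths = track.region_depths(cluster)

    def summarise(mask: np.ndarray) -> RegionSummary:
        sub = depths[mask]
        return RegionSummary(
            region=cluster,
            mean_depth=float(sub.mean()),
            normalized_depth=float(sub.mean()) / gmean,
            breadth=float((sub >= min_depth).mean()),
            min_depth_threshold=min_depth,
        )

    genic = summarise(genic_mask)
    if (~genic_mask).any():
        intergenic = summarise(~genic_mask)
        ratio = (
            genic.normalized_depth / intergenic.normalized_depth
            if intergenic.normalized_depth > 0
            else None
        )
    else:
        intergenic = None
        ratio = None
    return GenicIntergenicSummary(
        genic=genic,
        intergenic=intergenic,
        genic_over_intergenic=ratio,
        genic_over_genome=genic.normalized_depth,
        genes=list(genes),
    )
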
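"""Loss-of-heterozygosity scan: homozygosity ratio per scaffold or window.

For every region the scan counts the putative SNPs it contains (nt) and
how many of those are homozygous in the mutant pool (nh), and reports
the homozygosity ratio r = nh / nt.  Regions are whole scaffolds for
short assembly units and consecutive non-overlapping windows (default
0.5 Mb) for scaffolds longer than ``long_scaffold_cutoff``.  Regions
with fewer than ``min_region_snps`` SNPs (default 20) are excluded from
ranking to avoid bias from sparsely covered, falsely called sites.
Candidate LOH regions are the non-excluded regions ranked by ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

from .pileup_io import _open_text
from .snp_caller import SNPCall, ZYG_HOM

MODE_SCAFFOLD = "scaffold"
MODE_WINDOW = "window"


@dataclass(frozen=True)
class ScanParams:
    window_size: int = 500_000
    min_region_snps: int = 20
    long_scaffold_cutoff: int | None = None  # None -> window_size

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError(f"need window_size >= 1, got {self.window_size}")
        if self.min_region_snps < 1:
            raise ValueError(f"need min_region_snps >= 1, got {self.min_region_snps}")

    @property
    def cutoff(self) -> int:
        return self.window_size if self.long_scaffold_cutoff is None else self.long_scaffold_cutoff


@dataclass(frozen=True)
class Region:
    """A scan unit: 1-based inclusive interval on one scaffold."""

    chrom: str
    start: int
    end: int
    mode: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad region bounds [{self.start}, {self.end}]")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class RegionStat:
    """nt, nh and the homozygosity ratio for one region.

    ``ratio`` is None when the region holds no SNPs; ``excluded`` flags
    regions below the minimum SNP count.
    """

    region: Region
    nt: int
    nh: int
    ratio: float | None
    excluded: bool


def make_regions(
    scaffold_lengths: dict[str, int], params: ScanParams | None = None
) -> list[Region]:
    """Partition each scaffold into scan regions.

    Scaffolds no longer than the cutoff become a single scaffold-mode
    region; longer ones are tiled with consecutive windows, the last
    truncated at the scaffold end.  The regions of one scaffold are
    disjoint and cover [1, length] exactly.
    """
    params = params or ScanParams()
    regions: list[Region] = []
    for name, length in scaffold_lengths.items():
        if length < 1:
            raise ValueError(f"scaffold {name!r} has non-positive length {length}")
        if length <= params.cutoff:
            regions.append(Region(name, 1, length, MODE_SCAFFOLD))
        else:
            start = 1
            while start <= length:
                end = min(start + params.window_size - 1, length)
                regions.append(Region(name, start, end, MODE_WINDOW))
                start = end + 1
    return regions


def region_stats(
    calls: Iterable[SNPCall],
    regions: Sequence[Region],
    params: ScanParams | None = None,
) -> list[RegionStat]:
    """Assign each SNP call to its region and compute nt, nh, r = nh/nt."""
    params = params or ScanParams()
    by_chrom: dict[str, list[tuple[int, Region]]] = {}
    order: dict[Region, int] = {}
    for i, region in enumerate(regions):
        by_chrom.setdefault(region.chrom, []).append((i, region))
        order[region] = i
    nt = [0] * len(regions)
    nh = [0] * len(regions)
    for call in calls:
        if call.chrom not in by_chrom:
            raise ValueError(f"SNP call on unknown scaffold {call.chrom!r} at {call.pos}")
        for i, region in by_chrom[call.chrom]:
            if region.contains(call.pos):
                nt[i] += 1
                if call.mut_zygosity == ZYG_HOM:
                    nh[i] += 1
                break
        else:
            raise ValueError(
                f"SNP call at {call.chrom}:{call.pos} outside all regions of its scaffold"
            )
    return [
        RegionStat(
            region=region,
            nt=nt[i],
            nh=nh[i],
            ratio=(nh[i] / nt[i]) if nt[i] > 0 else None,
            excluded=nt[i] < params.min_region_snps,
        )
        for i, region in enumerate(regions)
    ]


def rank_regions(stats: Iterable[RegionStat]) -> list[RegionStat]:
    """Non-excluded regions by descending ratio.

    Ties break by nt descending then (chrom, start) ascending, so the
    ranking is deterministic; excluded regions are omitted.
    """
    kept = [s for s in stats if not s.excluded and s.ratio is not None]
    return sorted(
        kept,
        key=lambda s: (-s.ratio, -s.nt, s.region.chrom, s.region.start),
    )


def excluded_genome_fraction(
    stats: Iterable[RegionStat], scaffold_lengths: dict[str, int]
) -> float:
    """Fraction of the genome lying in excluded regions (a log metric)."""
    total = sum(scaffold_lengths.values())
    if total == 0:
        return 0.0
    excluded_bp = sum(
        s.region.end - s.region.start + 1 for s in stats if s.excluded
    )
    return excluded_bp / total


# ---------------------------------------------------------------------------
# export

def write_region_tsv(stats: Iterable[RegionStat], dest: Union[str, IO]) -> None:
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        handle.write("chrom\tstart\tend\tmode\tnt\tnh\tratio\texcluded\n")
        for s in stats:
            ratio = "NA" if s.ratio is None else f"{s.ratio:.6g}"
            handle.write(
                f"{s.region.chrom}\t{s.region.start}\t{s.region.end}\t{s.region.mode}\t"
                f"{s.nt}\t{s.nh}\t{ratio}\t{int(s.excluded)}\n"
            )
    finally:
        if close:
            handle.close()


def write_region_bed(stats: Iterable[RegionStat], dest: Union[str, IO]) -> None:
    """BED export: 0-based half-open, score = 1000 * ratio rounded."""
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        for s in stats:
            score = 0 if s.ratio is None else round(1000 * s.ratio)
            name = f"nt={s.nt};nh={s.nh}" + (";excluded" if s.excluded else "")
            handle.write(
                f"{s.region.chrom}\t{s.region.start - 1}\t{s.region.end}\t{name}\t{score}\t.\n"
            )
    finally:
        if close:
            handle.close()
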
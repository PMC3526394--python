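"""Fine-mapping arithmetic: recombinants, genetic distance, misassembly flags.

In a het x het intercross scored on homozygous-mutant progeny, both
chromosomes of every mutant embryo are informative meioses, so a bulk
of N embryos represents 2N meioses.  A marker's genetic distance from
the causal locus is estimated directly from the recombination
fraction: distance_cM = 100 * recombinants / meioses.  No map function
is applied — at the sub-centimorgan distances relevant to fine mapping
the recombination fraction and the map distance coincide to well below
scoring error.

A multi-scaffold LOH signal at near-complete homozygosity is the
signature of a reference misassembly: a single recessive locus cannot
produce independent high-homozygosity peaks on two unlinked scaffolds,
so when more than one scaffold carries such a peak the extra
scaffold(s) likely belong, in part, next to the causal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

from .loh_scan import RegionStat
from .pileup_io import _open_text

GT_N_HOM = "N_hom"
GT_HET = "het"
GT_MAPCROSS_HOM = "mapcross_hom"

#: recombinant chromosomes carried by a mutant embryo with this marker genotype
_RECOMBINANT_CHROMS = {GT_N_HOM: 0, GT_HET: 1, GT_MAPCROSS_HOM: 2}


@dataclass
class MarkerResult:
    marker_id: str
    chrom: str
    pos: int
    recombinants: int
    meioses: int

    def __post_init__(self) -> None:
        if not (0 <= self.recombinants <= self.meioses):
            raise ValueError(
                f"need 0 <= recombinants <= meioses, got {self.recombinants}/{self.meioses}"
            )

    @property
    def distance_cM(self) -> float:
        return genetic_distance(self.recombinants, self.meioses)


@dataclass
class MisassemblyFlag:
    """Scaffolds carrying a non-excluded region at or above the LOH threshold."""

    scaffolds: set[str]
    threshold: float

    @property
    def raised(self) -> bool:
        return len(self.scaffolds) > 1


def meioses_from_embryos(n_embryos: int, per_embryo: int = 2) -> int:
    """Number of informative meioses in a bulk of mutant embryos.

    Defaults to 2 per embryo (recessive intercross scored on
    homozygotes: both chromosomes are meiotic products of a carrier).
    """
    if n_embryos < 1:
        raise ValueError(f"need n_embryos >= 1, got {n_embryos}")
    if per_embryo < 1:
        raise ValueError(f"need per_embryo >= 1, got {per_embryo}")
    return per_embryo * n_embryos


def genetic_distance(recombinants: int, meioses: int) -> float:
    """Genetic distance in cM: 100 * recombinants / meioses."""
    if meioses < 1:
        raise ValueError(f"need meioses >= 1, got {meioses}")
    if not (0 <= recombinants <= meioses):
        raise ValueError(
            f"need 0 <= recombinants <= meioses, got {recombinants}/{meioses}"
        )
    return 100.0 * recombinants / meioses


def score_recombinants(
    genotypes: Iterable[tuple[str, str, str]],
    marker_positions: dict[str, tuple[str, int]] | None = None,
) -> list[MarkerResult]:
    """Score recombinants from per-embryo marker genotypes.

    ``genotypes`` yields (embryo_id, marker_id, genotype) with genotype
    one of N_hom / het / mapcross_hom for a *mutant* embryo.  An embryo
    is recombinant at a marker when it is not N-homozygous there; it
    contributes 1 recombinant chromosome if het and 2 if
    mapcross-homozygous.  Meioses per marker = 2 x embryos typed there.
    """
    per_marker: dict[str, tuple[int, int]] = {}
    for embryo_id, marker_id, gt in genotypes:
        if gt not in _RECOMBINANT_CHROMS:
            raise ValueError(
                f"unknown genotype {gt!r} for embryo {embryo_id!r} at {marker_id!r}"
            )
        rec, n = per_marker.get(marker_id, (0, 0))
        per_marker[marker_id] = (rec + _RECOMBINANT_CHROMS[gt], n + 1)
    results = []
    for marker_id, (rec, n) in per_marker.items():
        chrom, pos = (marker_positions or {}).get(marker_id, ("NA", 0))
        results.append(
            MarkerResult(
                marker_id=marker_id,
                chrom=chrom,
                pos=pos,
                recombinants=rec,
                meioses=meioses_from_embryos(n),
            )
        )
    return results


def read_genotype_tsv(source: Union[str, IO]) -> list[tuple[str, str, str]]:
    """Read (embryo_id, marker_id, genotype) rows; a header line is allowed."""
    handle = _open_text(source)
    close = isinstance(source, (str, bytes))
    rows: list[tuple[str, str, str]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"expected 3 columns at line {lineno}")
            if lineno == 1 and fields[2] not in _RECOMBINANT_CHROMS:
                continue  # header
            rows.append((fields[0], fields[1], fields[2]))
    finally:
        if close:
            handle.close()
    return rows


def write_marker_tsv(results: Sequence[MarkerResult], dest: Union[str, IO]) -> None:
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        handle.write("marker_id\tchrom\tpos\trecombinants\tmeioses\tdistance_cM\n")
        for r in results:
            handle.write(
                f"{r.marker_id}\t{r.chrom}\t{r.pos}\t{r.recombinants}\t"
                f"{r.meioses}\t{r.distance_cM:.6g}\n"
            )
    finally:
        if close:
            handle.close()


def flag_misassembly(
    stats: Iterable[RegionStat], threshold: float = 0.9
) -> MisassemblyFlag:
    """Collect scaffolds with any non-excluded region at ratio >= threshold.

    The flag is raised when more than one scaffold qualifies: a single
    recessive locus explains at most one scaffold of near-complete LOH.
    """
    scaffolds = {
        s.region.chrom
        for s in stats
        if not s.excluded and s.ratio is not None and s.ratio >= threshold
    }
    return MisassemblyFlag(scaffolds=scaffolds, threshold=threshold)
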
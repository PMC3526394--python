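"""Reading and writing samtools pileup text and per-base allele counting.

A pileup line summarises the reads covering one reference position:

    chrom  pos  ref  depth  bases  qualities

The bases column is a compact per-read encoding: ``.``/``,`` are
reference matches on the forward/reverse strand, ``ACGT``/``acgt`` are
substitutions, ``^X`` marks a read start (X is the mapping quality),
``$`` a read end, ``+n``/``-n`` an indel of n bases following this
position, ``*`` a deleted base and ``<``/``>`` reference skips.  This
module decodes that string into substitution-allele counts per base,
merging strands, which is the representation the pooled SNP caller
works from.  The six-column dialect is the common subset of classic
``samtools pileup`` and single-sample ``samtools mpileup`` output.

Positions are 1-based throughout, matching the pileup convention.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from itertools import groupby
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: quality placeholder written for synthetic pileups
_QUAL_CHAR = "I"

#: symbols that contribute to ``skipped`` rather than to an allele count
_SKIP_SYMBOLS = frozenset("*<>Nn")


class PileupFormatError(ValueError):
    """A pileup record or stream violates the expected format."""


@dataclass
class SiteCounts:
    """Per-base read counts for one pool at one genomic position.

    ``counts`` holds substitution-allele counts over A/C/G/T with
    strands merged; symbols that do not represent a substitution allele
    (deletions, reference skips, N calls) are tallied in ``skipped``.
    For a well-formed record ``sum(counts.values()) + skipped`` equals
    the pileup depth column.
    """

    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BASES, 0))
    depth_reported: int = 0
    skipped: int = 0

    @property
    def depth(self) -> int:
        """Total substitution-allele depth (the MAF denominator)."""
        return sum(self.counts.values())


@dataclass
class PooledSite:
    """Position-matched allele counts from the WT and MUT pools."""

    chrom: str
    pos: int
    ref_base: str
    wt: dict[str, int]
    mut: dict[str, int]


def _decode_bases(bases: str, ref_base: str, lineno: int | None) -> tuple[dict[str, int], int]:
    counts = dict.fromkeys(BASES, 0)
    skipped = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # '^' plus the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(
                    f"indel length missing after '{c}'"
                    + (f" at line {lineno}" if lineno else "")
                )
            indel_len = int(bases[i + 1 : j])
            i = j + indel_len  # indel sequence is not a new allele at this position
            continue
        if c in ".,":
            if ref_base in BASES:
                counts[ref_base] += 1
            else:
                skipped += 1  # ref N: match carries no allele information
        elif c.upper() in BASES:
            counts[c.upper()] += 1
        elif c in _SKIP_SYMBOLS:
            skipped += 1
        else:
            raise PileupFormatError(
                f"unrecognised pileup symbol {c!r}"
                + (f" at line {lineno}" if lineno else "")
            )
        i += 1
    return counts, skipped


def parse_pileup_line(line: str, lineno: int | None = None) -> SiteCounts:
    """Decode one pileup record into :class:`SiteCounts`.

    Raises :class:`PileupFormatError` on malformed position, depth or
    bases columns; the message names ``lineno`` when given.  If the
    decoded symbol count disagrees with the depth column the decoded
    counts are trusted and the discrepancy is logged.
    """
    fields = line.split()
    if len(fields) < 6:
        raise PileupFormatError(
            f"expected >= 6 columns, got {len(fields)}"
            + (f" at line {lineno}" if lineno else "")
        )
    chrom, pos_s, ref, depth_s, bases = fields[0], fields[1], fields[2], fields[3], fields[4]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise PileupFormatError(
            f"non-integer position/depth ({pos_s!r}, {depth_s!r})"
            + (f" at line {lineno}" if lineno else "")
        ) from exc
    if pos < 1:
        raise PileupFormatError(
            f"position must be >= 1, got {pos}" + (f" at line {lineno}" if lineno else "")
        )
    ref_base = ref.upper()
    if depth == 0 and bases == "*":
        # zero-coverage placeholder record ("0 * *")
        return SiteCounts(chrom=chrom, pos=pos, ref_base=ref_base,
                          depth_reported=0, skipped=0)
    counts, skipped = _decode_bases(bases, ref_base, lineno)
    decoded = sum(counts.values()) + skipped
    if decoded != depth:
        logger.warning(
            "pileup depth mismatch at %s:%d: depth column %d, decoded %d symbols; "
            "trusting decoded counts",
            chrom,
            pos,
            depth,
            decoded,
        )
    return SiteCounts(
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        counts=counts,
        depth_reported=depth,
        skipped=skipped,
    )


def _open_text(source: Union[str, IO], mode: str = "rt") -> IO:
    if isinstance(source, (str, bytes)):
        if str(source).endswith(".gz"):
            return gzip.open(source, mode)
        return open(source, mode)
    return source


def read_pileup(source: Union[str, IO, Iterable[str]]) -> Iterator[SiteCounts]:
    """Stream :class:`SiteCounts` from a pileup file, path or line iterable.

    Records must be position-sorted within each scaffold; duplicated
    (chrom, pos) pairs raise :class:`PileupFormatError`.
    """
    handle = _open_text(source) if isinstance(source, (str, bytes)) else source
    close = isinstance(source, (str, bytes))
    prev: tuple[str, int] | None = None
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            site = parse_pileup_line(line, lineno=lineno)
            key = (site.chrom, site.pos)
            if prev is not None and site.chrom == prev[0] and site.pos <= prev[1]:
                kind = "duplicate" if site.pos == prev[1] else "unsorted"
                raise PileupFormatError(
                    f"{kind} position {site.chrom}:{site.pos} at line {lineno}"
                )
            prev = key
            yield site
    finally:
        if close:
            handle.close()


def write_pileup(sites: Iterable[SiteCounts], dest: Union[str, IO]) -> None:
    """Write sites as six-column pileup text (gzip if the path ends .gz).

    Only substitution-allele content is emitted: reference matches as
    ``.``, other alleles as upper-case letters, skipped symbols as
    ``*``; qualities are a constant placeholder.  ``parse_pileup_line``
    round-trips the counts exactly.
    """
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        for site in sites:
            parts = []
            for base in BASES:
                n = site.counts.get(base, 0)
                if n:
                    parts.append(("." if base == site.ref_base else base) * n)
            parts.append("*" * site.skipped)
            bases = "".join(parts)
            depth = sum(site.counts.values()) + site.skipped
            if depth == 0:
                bases = quals = "*"  # zero-coverage placeholder
            else:
                quals = _QUAL_CHAR * depth
            handle.write(
                f"{site.chrom}\t{site.pos}\t{site.ref_base}\t{depth}\t"
                f"{bases}\t{quals}\n"
            )
    finally:
        if close:
            handle.close()


def _scaffold_groups(sites: Iterable[SiteCounts]) -> Iterator[tuple[str, list[SiteCounts]]]:
    for chrom, group in groupby(sites, key=lambda s: s.chrom):
        yield chrom, list(group)


def join_pools(
    wt: Iterable[SiteCounts], mut: Iterable[SiteCounts]
) -> Iterator[PooledSite]:
    """Inner-join two sorted pools on (chrom, pos).

    Positions covered in only one pool are dropped: they can never meet
    the caller's joint depth requirement.  The two inputs must list
    shared scaffolds in the same relative order, otherwise a
    :class:`PileupFormatError` is raised.
    """
    wt_groups = dict(_scaffold_groups(wt))
    mut_groups = dict(_scaffold_groups(mut))
    shared = [c for c in wt_groups if c in mut_groups]
    shared_in_mut = [c for c in mut_groups if c in wt_groups]
    if shared != shared_in_mut:
        raise PileupFormatError(
            "inconsistent scaffold ordering between pools: "
            f"WT order {shared}, MUT order {shared_in_mut}"
        )
    for chrom in shared:
        a = wt_groups[chrom]
        b = mut_groups[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            if a[i].pos == b[j].pos:
                yield PooledSite(
                    chrom=chrom,
                    pos=a[i].pos,
                    ref_base=a[i].ref_base,
                    wt=a[i].counts,
                    mut=b[j].counts,
                )
                i += 1
                j += 1
            elif a[i].pos < b[j].pos:
                i += 1
            else:
                j += 1


def read_scaffold_lengths(source: Union[str, IO]) -> dict[str, int]:
    """Read a FASTA .fai-style TSV (name and length in the first two columns)."""
    handle = _open_text(source)
    close = isinstance(source, (str, bytes))
    lengths: dict[str, int] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise PileupFormatError(f"expected >= 2 columns at line {lineno}")
            name = fields[0]
            if name in lengths:
                raise PileupFormatError(f"duplicate scaffold name {name!r} at line {lineno}")
            try:
                lengths[name] = int(fields[1])
            except ValueError as exc:
                raise PileupFormatError(
                    f"non-integer length {fields[1]!r} at line {lineno}"
                ) from exc
    finally:
        if close:
            handle.close()
    return lengths


def write_scaffold_lengths(lengths: dict[str, int], dest: Union[str, IO]) -> None:
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        for name, length in lengths.items():
            handle.write(f"{name}\t{length}\n")
    finally:
        if close:
            handle.close()
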
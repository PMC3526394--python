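"""Pooled putative-SNP calling from position-matched WT/MUT allele counts.

In a bulk-segregant design the wildtype pool stays heterozygous at
informative markers while the mutant pool loses heterozygosity near the
causal locus.  A site is a putative SNP when, with at least
``min_depth`` reads in *both* pools, either

(i)  the wildtype pool's major allele fraction (MAF, the most frequent
     base's share of A/C/G/T reads) lies in the band
     [``wt_maf_lo``, ``wt_maf_hi``] — the heterozygous signature, or
(ii) the wildtype and mutant major alleles differ.

A called SNP is classed homozygous in the mutant pool when its mutant
MAF is at least ``hom_threshold``.  Both band endpoints and the
homozygosity threshold are inclusive.  The reference base never enters
the criteria; it is carried through for VCF export only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Union

from .pileup_io import BASES, PooledSite, _open_text

logger = logging.getLogger(__name__)

CRIT_WT_BAND = "wt_het_band"
CRIT_MAJOR_DIFFERS = "major_allele_differs"
CRIT_BOTH = "both"

ZYG_HOM = "homozygous"
ZYG_HET = "heterozygous"


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the pooled SNP caller.

    Defaults are the standard operating point: >= 10 reads per pool,
    WT MAF band [0.50, 0.75], mutant homozygosity at MAF >= 0.90.
    """

    min_depth: int = 10
    wt_maf_lo: float = 0.50
    wt_maf_hi: float = 0.75
    hom_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 <= self.wt_maf_lo <= self.wt_maf_hi <= 1.0):
            raise ValueError(f"need 0 <= wt_maf_lo <= wt_maf_hi <= 1, got {self}")
        if not (0.0 < self.hom_threshold <= 1.0):
            raise ValueError(f"need 0 < hom_threshold <= 1, got {self.hom_threshold}")
        if self.min_depth < 1:
            raise ValueError(f"need min_depth >= 1, got {self.min_depth}")


@dataclass
class SNPCall:
    """A putative SNP with both pools' major alleles and fractions.

    ``tie`` marks sites where either pool's major allele was decided by
    the alphabetical tie rule rather than by a strict count majority.
    """

    chrom: str
    pos: int
    ref_base: str
    wt_major: str
    wt_maf: float
    wt_depth: int
    mut_major: str
    mut_maf: float
    mut_depth: int
    criterion: str
    mut_zygosity: str
    tie: bool = False


@dataclass
class CallSummary:
    examined: int = 0
    called: int = 0
    homozygous: int = 0


def major_allele(counts: dict[str, int]) -> tuple[str, float]:
    """Return the majority base and its fraction of A/C/G/T reads.

    Ties are broken in fixed alphabetical order A < C < G < T so the
    result is deterministic.  Raises ``ValueError`` on all-zero counts;
    callers are expected to depth-filter first.
    """
    total = sum(counts.get(b, 0) for b in BASES)
    if total == 0:
        raise ValueError("major_allele undefined for all-zero counts")
    best = max(BASES, key=lambda b: (counts.get(b, 0), -BASES.index(b)))
    return best, counts.get(best, 0) / total


def _is_tie(counts: dict[str, int], major: str) -> bool:
    top = counts.get(major, 0)
    return sum(1 for b in BASES if counts.get(b, 0) == top) > 1


def call_site(site: PooledSite, params: CallerParams) -> SNPCall | None:
    """Apply the putative-SNP criteria to one position; None if not called."""
    wt_depth = sum(site.wt.get(b, 0) for b in BASES)
    mut_depth = sum(site.mut.get(b, 0) for b in BASES)
    if wt_depth < params.min_depth or mut_depth < params.min_depth:
        return None
    wt_major, wt_maf = major_allele(site.wt)
    mut_major, mut_maf = major_allele(site.mut)
    in_band = params.wt_maf_lo <= wt_maf <= params.wt_maf_hi
    differs = wt_major != mut_major
    if not in_band and not differs:
        return None
    if in_band and differs:
        criterion = CRIT_BOTH
    elif in_band:
        criterion = CRIT_WT_BAND
    else:
        criterion = CRIT_MAJOR_DIFFERS
    return SNPCall(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=site.ref_base,
        wt_major=wt_major,
        wt_maf=wt_maf,
        wt_depth=wt_depth,
        mut_major=mut_major,
        mut_maf=mut_maf,
        mut_depth=mut_depth,
        criterion=criterion,
        mut_zygosity=ZYG_HOM if mut_maf >= params.hom_threshold else ZYG_HET,
        tie=_is_tie(site.wt, wt_major) or _is_tie(site.mut, mut_major),
    )


def call_snps(
    sites: Iterable[PooledSite], params: CallerParams | None = None
) -> tuple[list[SNPCall], CallSummary]:
    """Order-preserving filter-map of :func:`call_site` over sorted sites."""
    params = params or CallerParams()
    summary = CallSummary()
    calls: list[SNPCall] = []
    for site in sites:
        summary.examined += 1
        call = call_site(site, params)
        if call is not None:
            calls.append(call)
            summary.called += 1
            if call.mut_zygosity == ZYG_HOM:
                summary.homozygous += 1
    logger.info(
        "examined %d sites, called %d putative SNPs (%d homozygous in MUT pool)",
        summary.examined,
        summary.called,
        summary.homozygous,
    )
    return calls, summary


# ---------------------------------------------------------------------------
# TSV / VCF export

_TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "wt_major",
    "wt_maf",
    "wt_depth",
    "mut_major",
    "mut_maf",
    "mut_depth",
    "criterion",
    "zygosity",
    "tie",
)


def write_calls_tsv(calls: Iterable[SNPCall], dest: Union[str, IO]) -> None:
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        handle.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in calls:
            handle.write(
                f"{c.chrom}\t{c.pos}\t{c.ref_base}\t{c.wt_major}\t{c.wt_maf:.6g}\t"
                f"{c.wt_depth}\t{c.mut_major}\t{c.mut_maf:.6g}\t{c.mut_depth}\t"
                f"{c.criterion}\t{c.mut_zygosity}\t{int(c.tie)}\n"
            )
    finally:
        if close:
            handle.close()


def read_calls_tsv(source: Union[str, IO]) -> list[SNPCall]:
    handle = _open_text(source)
    close = isinstance(source, (str, bytes))
    calls: list[SNPCall] = []
    try:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in handle:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                SNPCall(
                    chrom=f[idx["chrom"]],
                    pos=int(f[idx["pos"]]),
                    ref_base=f[idx["ref"]],
                    wt_major=f[idx["wt_major"]],
                    wt_maf=float(f[idx["wt_maf"]]),
                    wt_depth=int(f[idx["wt_depth"]]),
                    mut_major=f[idx["mut_major"]],
                    mut_maf=float(f[idx["mut_maf"]]),
                    mut_depth=int(f[idx["mut_depth"]]),
                    criterion=f[idx["criterion"]],
                    mut_zygosity=f[idx["zygosity"]],
                    tie=bool(int(f[idx.get("tie", 0)])) if "tie" in idx else False,
                )
            )
    finally:
        if close:
            handle.close()
    return calls


def write_calls_vcf(calls: Iterable[SNPCall], dest: Union[str, IO]) -> None:
    """Minimal VCF 4.2: ALT is the mutant-pool major allele, or the
    non-reference major allele when the mutant major equals REF."""
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=WTD,Number=1,Type=Integer,Description="WT pool allele depth">\n')
        handle.write('##INFO=<ID=WTMAF,Number=1,Type=Float,Description="WT pool major allele fraction">\n')
        handle.write('##INFO=<ID=MUTD,Number=1,Type=Integer,Description="MUT pool allele depth">\n')
        handle.write('##INFO=<ID=MUTMAF,Number=1,Type=Float,Description="MUT pool major allele fraction">\n')
        handle.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="MUT pool zygosity class">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alt = c.mut_major if c.mut_major != c.ref_base else c.wt_major
            if alt == c.ref_base:
                alt = "."
            info = (
                f"WTD={c.wt_depth};WTMAF={c.wt_maf:.4f};MUTD={c.mut_depth};"
                f"MUTMAF={c.mut_maf:.4f};ZYG={c.mut_zygosity}"
            )
            handle.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref_base}\t{alt}\t.\tPASS\t{info}\n")
    finally:
        if close:
            handle.close()
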
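"""CAPS/RFLP marker design: restriction sites created or abolished by a SNP.

A SNP is genotypable on a gel when one of its alleles carries a
restriction-enzyme recognition site the other lacks: PCR the flanking
region, digest, and the two alleles give different band patterns.  This
module scans both allele variants of a SNP's flanking sequence against
an enzyme panel (recognition sites in IUPAC code, both strands for
non-palindromic sites) and reports each site present in exactly one
allele, with digest fragment lengths for gel-resolvability triage.

Cut positions are taken from the enzyme's cut offset when known and
default to the site midpoint otherwise: fragment lengths here guide
marker selection, they are not a substitute for an exact digest map.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

from .pileup_io import _open_text

_IUPAC_SETS = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site (IUPAC) and cut offset.

    ``cut_offset`` is the 0-based position within the site after which
    the enzyme cleaves the given strand; None means unknown (the site
    midpoint is then used for fragment arithmetic).
    """

    name: str
    site: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.site:
            raise ValueError(f"enzyme {self.name!r} has an empty site")
        bad = set(self.site.upper()) - set(_IUPAC_SETS)
        if bad:
            raise ValueError(f"enzyme {self.name!r} site has non-IUPAC symbols {bad}")
        object.__setattr__(self, "site", self.site.upper())
        if self.cut_offset is not None and not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError(f"enzyme {self.name!r} cut_offset outside site")


@dataclass
class SNPContext:
    """A SNP embedded in its flanking sequence.

    ``offset`` is the 0-based index of the SNP within ``flank``;
    ``allele_a``/``allele_b`` are the two substitution alleles.
    """

    chrom: str
    pos: int
    flank: str
    offset: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        self.flank = self.flank.upper()
        self.allele_a = self.allele_a.upper()
        self.allele_b = self.allele_b.upper()
        if not (0 <= self.offset < len(self.flank)):
            raise ValueError("SNP offset outside flank")
        if self.flank[self.offset] not in (self.allele_a, self.allele_b):
            raise ValueError(
                f"flank base {self.flank[self.offset]!r} at offset {self.offset} "
                f"matches neither allele {self.allele_a!r}/{self.allele_b!r}"
            )

    def with_allele(self, base: str) -> str:
        return self.flank[: self.offset] + base + self.flank[self.offset + 1 :]


@dataclass
class RFLPResult:
    """One differential restriction site at a SNP.

    ``fragments_cut`` is the full digest of the allele carrying the
    site (constitutive sites elsewhere in the flank included), so its
    lengths always sum to the flank length; ``fragments_uncut`` is the
    digest of the other allele ([flank length] when the enzyme has no
    constitutive site).  ``amplicon_feasible`` is True when the
    differential site sits at least ``margin`` bp from both flank ends,
    leaving room for a 100-250 bp amplicon around the SNP.
    """

    snp: SNPContext
    enzyme: Enzyme
    cutting_allele: str
    site_position: int
    strand: str
    fragments_cut: list[int] = field(default_factory=list)
    fragments_uncut: list[int] = field(default_factory=list)
    amplicon_feasible: bool = True


def iupac_match(site: str, seq: str, start: int) -> bool:
    """True iff ``seq[start:start+len(site)]`` matches the IUPAC pattern."""
    if start + len(site) > len(seq):
        raise ValueError("match window extends past sequence end")
    for i, code in enumerate(site):
        sets = _IUPAC_SETS.get(code.upper())
        if sets is None:
            raise ValueError(f"non-IUPAC symbol {code!r} in site")
        if seq[start + i].upper() not in sets:
            return False
    return True


def reverse_complement_iupac(site: str) -> str:
    return "".join(ambiguous_dna_complement[c] for c in reversed(site.upper()))


def _match_positions(seq: str, enzyme: Enzyme) -> list[tuple[int, str]]:
    """All (1-based start, strand) matches of the site in given-strand
    coordinates; palindromic sites are scanned once."""
    site = enzyme.site
    rc = reverse_complement_iupac(site)
    hits: list[tuple[int, str]] = []
    for i in range(len(seq) - len(site) + 1):
        if iupac_match(site, seq, i):
            hits.append((i + 1, "+"))
        elif rc != site and iupac_match(rc, seq, i):
            hits.append((i + 1, "-"))
    return hits


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Sorted 1-based start positions of recognition sites on either strand."""
    return sorted({pos for pos, _ in _match_positions(seq, enzyme)})


def _cut_points(seq: str, enzyme: Enzyme) -> list[int]:
    """0-based cut coordinates strictly inside the sequence."""
    width = len(enzyme.site)
    offset = enzyme.cut_offset if enzyme.cut_offset is not None else width // 2
    cuts = set()
    for pos, strand in _match_positions(seq, enzyme):
        local = offset if strand == "+" else width - offset
        cut = pos - 1 + local
        if 0 < cut < len(seq):
            cuts.add(cut)
    return sorted(cuts)


def digest_lengths(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths of a complete digest of ``seq``."""
    cuts = _cut_points(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def differential_enzymes(
    snp: SNPContext,
    enzymes: Iterable[Enzyme] | None = None,
    margin: int = 50,
) -> list[RFLPResult]:
    """Enzymes whose recognition site is created or abolished by the SNP.

    For each enzyme the two allele variants of the flank are scanned;
    every site present in exactly one variant yields an
    :class:`RFLPResult`.  Each differential site necessarily overlaps
    the SNP position — this is checked for every emitted result.
    """
    enzymes = load_enzymes() if enzymes is None else list(enzymes)
    flank_a = snp.with_allele(snp.allele_a)
    flank_b = snp.with_allele(snp.allele_b)
    results: list[RFLPResult] = []
    for enzyme in enzymes:
        hits_a = dict(_match_positions(flank_a, enzyme))
        hits_b = dict(_match_positions(flank_b, enzyme))
        width = len(enzyme.site)
        for pos in sorted(set(hits_a) ^ set(hits_b)):
            cutting = snp.allele_a if pos in hits_a else snp.allele_b
            strand = hits_a.get(pos, hits_b.get(pos))
            span = (pos - 1, pos - 1 + width - 1)  # 0-based inclusive
            if not (span[0] <= snp.offset <= span[1]):
                raise AssertionError(
                    f"differential {enzyme.name} site at {pos} does not overlap "
                    f"the SNP offset {snp.offset}"
                )
            cut_flank = flank_a if cutting == snp.allele_a else flank_b
            uncut_flank = flank_b if cutting == snp.allele_a else flank_a
            results.append(
                RFLPResult(
                    snp=snp,
                    enzyme=enzyme,
                    cutting_allele=cutting,
                    site_position=pos,
                    strand=strand,
                    fragments_cut=digest_lengths(cut_flank, enzyme),
                    fragments_uncut=digest_lengths(uncut_flank, enzyme),
                    amplicon_feasible=(
                        span[0] >= margin and len(snp.flank) - 1 - span[1] >= margin
                    ),
                )
            )
    return results


# ---------------------------------------------------------------------------
# enzyme panel and flank I/O

def load_enzymes(source: Union[str, IO, None] = None) -> list[Enzyme]:
    """Load an enzyme panel from a TSV (name, site[, cut_offset]).

    With no argument the built-in panel of common 4- and 6-cutters is
    returned.  The format mirrors a minimal REBASE export.
    """
    if source is None:
        ref = importlib.resources.files("bsamap").joinpath("data/enzymes.tsv")
        text = ref.read_text()
        return _parse_enzyme_tsv(text.splitlines())
    handle = _open_text(source)
    close = isinstance(source, (str, bytes))
    try:
        return _parse_enzyme_tsv(handle)
    finally:
        if close:
            handle.close()


def _parse_enzyme_tsv(lines: Iterable[str]) -> list[Enzyme]:
    enzymes = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"enzyme line needs name and site: {line!r}")
        cut = int(fields[2]) if len(fields) > 2 and fields[2] != "" else None
        enzymes.append(Enzyme(name=fields[0], site=fields[1], cut_offset=cut))
    return enzymes


def snp_context_from_fasta(
    fasta: "str | object",
    chrom: str,
    pos: int,
    allele_a: str,
    allele_b: str,
    flank_bp: int = 150,
) -> SNPContext:
    """Extract a SNP's flank from an indexed FASTA (path or pyfaidx.Fasta)."""
    from pyfaidx import Fasta

    fa = Fasta(fasta) if isinstance(fasta, (str, bytes)) else fasta
    length = len(fa[chrom])
    start = max(1, pos - flank_bp)
    end = min(length, pos + flank_bp)
    seq = str(fa[chrom][start - 1 : end]).upper()
    return SNPContext(
        chrom=chrom,
        pos=pos,
        flank=seq,
        offset=pos - start,
        allele_a=allele_a,
        allele_b=allele_b,
    )


def write_rflp_tsv(results: Sequence[RFLPResult], dest: Union[str, IO]) -> None:
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, bytes))
    try:
        handle.write(
            "chrom\tpos\tenzyme\tsite\tcutting_allele\tsite_position\tstrand\t"
            "fragments_cut\tfragments_uncut\tamplicon_feasible\n"
        )
        for r in results:
            handle.write(
                f"{r.snp.chrom}\t{r.snp.pos}\t{r.enzyme.name}\t{r.enzyme.site}\t"
                f"{r.cutting_allele}\t{r.site_position}\t{r.strand}\t"
                f"{','.join(map(str, r.fragments_cut))}\t"
                f"{','.join(map(str, r.fragments_uncut))}\t{int(r.amplicon_feasible)}\n"
            )
    finally:
        if close:
            handle.close()
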
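"""Synthetic bulk-segregant pooled-sequencing datasets with known truth.

The generator emulates the mapping design the rest of the package
analyses: a mutagenized strain (N) carrying a recessive mutation is
crossed to a divergent mapcross strain; F1 carriers (N/mapcross, and
heterozygous at every informative marker) are intercrossed; progeny are
phenotype-sorted into a mutant bulk (N-homozygous at the causal locus)
and a wildtype bulk (het or mapcross-homozygous there, in the 2:1
Mendelian conditional ratio).  Each bulk is sequenced as a pool at
finite depth with base-call error, and the exome's sparsity is modelled
by emitting only marker positions.

Meiosis follows the Haldane model (no crossover interference): between
markers separated by d bp at map density ``cm_per_mb``, a gamete
switches parental origin with probability

    theta = (1 - exp(-2 m)) / 2,   m = d * cm_per_mb / 1e6 / 100 Morgans

which gives closed-form expectations for every marker: the mutant pool
carries the mapcross allele at frequency theta(d) per chromosome at
distance d from the causal locus, and the wildtype pool carries the N
allele at frequency (1 + theta)/3 (1/3 at the causal locus, 1/2
unlinked).  These analytic expectations are written into the truth
table so downstream checks never hard-code them.

Default parameters are the desk-scale study conditions used throughout
the test suite: 10 scaffolds x 2 Mb, mean marker spacing 10 kb, one
recessive causal locus, 50 embryos per bulk, Poisson depth 30,
per-base error 0.002, 1.2 cM/Mb.

An optional block relocation mimics a reference misassembly: markers in
a chosen interval keep their genotypes but are reported under another
scaffold's coordinates, appended past that scaffold's true end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pileup_io import BASES, SiteCounts, write_pileup, write_scaffold_lengths

#: allele codes in genotype arrays
N_ALLELE = 0
MAPCROSS_ALLELE = 1


def default_scaffolds() -> dict[str, int]:
    return {f"s{i:02d}": 2_000_000 for i in range(1, 11)}


@dataclass(frozen=True)
class RelocatedBlock:
    """A coordinate-relocation fixture emulating a reference misassembly."""

    scaffold: str
    start: int
    end: int
    dest_scaffold: str


@dataclass
class SimConfig:
    scaffolds: dict[str, int] = field(default_factory=default_scaffolds)
    snp_spacing_bp: int = 10_000
    causal: tuple[str, int] = ("s01", 1_250_000)
    n_mut_embryos: int = 50
    n_wt_embryos: int = 50
    depth_mean: float = 30.0
    error_rate: float = 0.002
    cm_per_mb: float = 1.2
    seed: int = 0
    emit_invariant_sites: bool = False
    relocate_block: RelocatedBlock | None = None
    max_rejection_draws: int | None = None

    def __post_init__(self) -> None:
        chrom, pos = self.causal
        if chrom not in self.scaffolds:
            raise ValueError(f"causal scaffold {chrom!r} not in scaffold table")
        if not (1 <= pos <= self.scaffolds[chrom]):
            raise ValueError(f"causal position {pos} outside scaffold {chrom!r}")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError(f"error_rate must be in [0, 1], got {self.error_rate}")
        if self.n_mut_embryos < 1 or self.n_wt_embryos < 1:
            raise ValueError("need at least one embryo per pool")

    @property
    def draw_budget(self) -> int:
        if self.max_rejection_draws is not None:
            return self.max_rejection_draws
        # a mutant embryo occurs with probability 1/4; leave ample headroom
        return max(10_000, 100 * (self.n_mut_embryos + self.n_wt_embryos))


def haldane_theta(distance_bp: float, cm_per_mb: float) -> float:
    """Recombination fraction between loci ``distance_bp`` apart (Haldane)."""
    morgans = distance_bp * cm_per_mb / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


@dataclass
class TruthTable:
    """Ground truth of one simulated cross.

    ``markers`` has one row per marker with its alleles and analytic
    allele-frequency expectations; ``mut_genotypes``/``wt_genotypes``
    are (embryos, 2 gametes, markers) arrays of allele codes (0 = N,
    1 = mapcross) with marker columns aligned to ``markers`` rows.
    """

    config: SimConfig
    markers: pd.DataFrame
    mut_genotypes: np.ndarray
    wt_genotypes: np.ndarray

    @property
    def causal_index(self) -> int:
        chrom, pos = self.config.causal
        hit = self.markers.index[
            (self.markers["chrom"] == chrom) & (self.markers["pos"] == pos)
        ]
        return int(hit[0])

    def pool_n_freq(self, pool: str) -> np.ndarray:
        """Empirical N-allele frequency per marker in one pool's chromosomes."""
        g = self.mut_genotypes if pool == "mut" else self.wt_genotypes
        return 1.0 - g.reshape(-1, g.shape[2]).mean(axis=0)

    def genotype_codes(self, pool: str) -> np.ndarray:
        """(embryos, markers) mapcross-allele dosage: 0=N hom, 1=het, 2=mapcross hom."""
        g = self.mut_genotypes if pool == "mut" else self.wt_genotypes
        return g.sum(axis=1)


def place_markers(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place informative markers with exponential spacing; the causal
    position is always a marker.  Each marker gets distinct N and
    mapcross alleles drawn uniformly."""
    rows: list[tuple[str, int]] = []
    causal_chrom, causal_pos = config.causal
    for chrom, length in config.scaffolds.items():
        positions: list[int] = []
        pos = 0.0
        while True:
            pos += rng.exponential(config.snp_spacing_bp)
            ipos = int(np.ceil(pos))
            if ipos > length:
                break
            if not positions or ipos > positions[-1]:
                positions.append(ipos)
        if chrom == causal_chrom and causal_pos not in positions:
            positions.append(causal_pos)
            positions.sort()
        rows.extend((chrom, p) for p in positions)
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    n_idx = rng.integers(0, 4, size=len(df))
    shift = rng.integers(1, 4, size=len(df))
    map_idx = (n_idx + shift) % 4
    df["n_allele"] = [BASES[i] for i in n_idx]
    df["map_allele"] = [BASES[i] for i in map_idx]
    dist = np.where(
        df["chrom"] == causal_chrom, np.abs(df["pos"] - causal_pos), np.nan
    )
    df["dist_bp"] = dist
    theta = np.where(
        np.isnan(dist), 0.5, haldane_theta(np.nan_to_num(dist), config.cm_per_mb)
    )
    df["theta"] = theta
    df["exp_mut_n_freq"] = 1.0 - theta
    df["exp_wt_n_freq"] = (1.0 + theta) / 3.0
    return df


def simulate_gametes(
    positions: np.ndarray, cm_per_mb: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw n gametes over sorted marker positions of one scaffold.

    Sequential Markov walk: the first marker's parental origin is a
    fair coin; between adjacent markers the origin switches with the
    Haldane probability for their separation.  Returns (n, m) allele
    codes (0 = N, 1 = mapcross).
    """
    m = len(positions)
    if m == 0:
        return np.zeros((n, 0), dtype=np.uint8)
    first = rng.integers(0, 2, size=n, dtype=np.uint8)
    if m == 1:
        return first[:, None]
    theta = haldane_theta(np.diff(positions).astype(float), cm_per_mb)
    switches = (rng.random((n, m - 1)) < theta).astype(np.uint8)
    flips = np.cumsum(switches, axis=1, dtype=np.int64) & 1
    return np.concatenate([first[:, None], first[:, None] ^ flips], axis=1).astype(
        np.uint8
    )


def simulate_cross(
    config: SimConfig, rng: np.random.Generator, markers: pd.DataFrame
) -> TruthTable:
    """Rejection-sample embryos until both phenotype pools are filled.

    An embryo is two independent gametes; it is a mutant iff N-hom at
    the causal marker.  Wildtype embryos are kept as drawn, so their
    causal-locus composition is the Mendelian 2:1 het:mapcross-hom.
    """
    causal_chrom, causal_pos = config.causal
    chrom_index = {
        chrom: np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        for chrom in config.scaffolds
    }
    causal_col = int(
        markers.index[
            (markers["chrom"] == causal_chrom) & (markers["pos"] == causal_pos)
        ][0]
    )
    n_markers = len(markers)
    mut: list[np.ndarray] = []
    wt: list[np.ndarray] = []
    drawn = 0
    batch_size = max(64, 4 * (config.n_mut_embryos + config.n_wt_embryos))
    while len(mut) < config.n_mut_embryos or len(wt) < config.n_wt_embryos:
        batch = min(batch_size, config.draw_budget - drawn)
        if batch <= 0:
            raise RuntimeError(
                f"rejection budget exceeded after {drawn} embryo draws; "
                "pathological simulation config"
            )
        g = np.zeros((batch, 2, n_markers), dtype=np.uint8)
        for chrom, cols in chrom_index.items():
            positions = markers["pos"].to_numpy()[cols]
            g[:, 0, cols] = simulate_gametes(positions, config.cm_per_mb, rng, batch)
            g[:, 1, cols] = simulate_gametes(positions, config.cm_per_mb, rng, batch)
        drawn += batch
        is_mut = (g[:, 0, causal_col] == N_ALLELE) & (g[:, 1, causal_col] == N_ALLELE)
        for i in range(batch):
            if is_mut[i]:
                if len(mut) < config.n_mut_embryos:
                    mut.append(g[i])
            elif len(wt) < config.n_wt_embryos:
                wt.append(g[i])
    return TruthTable(
        config=config,
        markers=markers,
        mut_genotypes=np.stack(mut),
        wt_genotypes=np.stack(wt),
    )


def sequence_pool(
    truth: TruthTable, pool: str, rng: np.random.Generator
) -> list[SiteCounts]:
    """Sequence one pool: per marker, Poisson depth, reads drawn
    uniformly from the pool's 2n chromosomes, uniform miscall error.

    Sites are returned in assembly coordinates (the relocation fixture
    applied), sorted ready for pileup output.
    """
    config = truth.config
    markers = assembly_coordinates(truth.markers, config)
    n_freq = truth.pool_n_freq(pool)
    m = len(markers)
    depth = rng.poisson(config.depth_mean, size=m)
    n_reads = rng.binomial(depth, n_freq)
    map_reads = depth - n_reads
    err_n = rng.binomial(n_reads, config.error_rate)
    err_m = rng.binomial(map_reads, config.error_rate)
    third = np.full(3, 1.0 / 3.0)
    dest_n = rng.multinomial(err_n, third)
    dest_m = rng.multinomial(err_m, third)
    n_alleles = markers["n_allele"].to_numpy()
    map_alleles = markers["map_allele"].to_numpy()
    sites: list[SiteCounts] = []
    for j in range(m):
        counts = dict.fromkeys(BASES, 0)
        na, ma = n_alleles[j], map_alleles[j]
        counts[na] += int(n_reads[j] - err_n[j])
        counts[ma] += int(map_reads[j] - err_m[j])
        others_n = [b for b in BASES if b != na]
        others_m = [b for b in BASES if b != ma]
        for k in range(3):
            counts[others_n[k]] += int(dest_n[j, k])
            counts[others_m[k]] += int(dest_m[j, k])
        total = int(depth[j])
        sites.append(
            SiteCounts(
                chrom=markers["asm_chrom"].iloc[j],
                pos=int(markers["asm_pos"].iloc[j]),
                ref_base=na,  # reference carries the mutagenized-strain background
                counts=counts,
                depth_reported=total,
                skipped=0,
            )
        )
    if config.emit_invariant_sites:
        sites.extend(_invariant_sites(markers, config, rng))
    order = _assembly_order(config)
    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    return sites


def _invariant_sites(
    markers: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> list[SiteCounts]:
    """Monomorphic reference positions midway between adjacent markers
    (parser stress material, off by default)."""
    sites = []
    for chrom, group in markers.groupby("asm_chrom", sort=False):
        pos = group["asm_pos"].to_numpy()
        mids = ((pos[:-1] + pos[1:]) // 2).astype(int)
        mids = mids[(mids > pos[:-1]) & (mids < pos[1:])]
        depths = rng.poisson(config.depth_mean, size=len(mids))
        for p, d in zip(mids, depths):
            counts = dict.fromkeys(BASES, 0)
            counts["A"] = int(d)
            sites.append(
                SiteCounts(
                    chrom=chrom, pos=int(p), ref_base="A", counts=counts,
                    depth_reported=int(d), skipped=0,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# assembly-coordinate fixture (misassembly emulation)

def assembly_scaffold_lengths(config: SimConfig) -> dict[str, int]:
    """Scaffold lengths as the (possibly misassembled) assembly reports them."""
    lengths = dict(config.scaffolds)
    block = config.relocate_block
    if block is not None:
        lengths[block.dest_scaffold] += block.end - block.start + 1
    return lengths


def assembly_coordinates(markers: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Add asm_chrom/asm_pos columns mapping true marker coordinates to
    the assembly's, applying the relocation fixture when configured."""
    df = markers.copy()
    df["asm_chrom"] = df["chrom"]
    df["asm_pos"] = df["pos"]
    block = config.relocate_block
    if block is not None:
        if block.dest_scaffold not in config.scaffolds:
            raise ValueError(f"unknown destination scaffold {block.dest_scaffold!r}")
        dest_len = config.scaffolds[block.dest_scaffold]
        mask = (
            (df["chrom"] == block.scaffold)
            & (df["pos"] >= block.start)
            & (df["pos"] <= block.end)
        )
        df.loc[mask, "asm_chrom"] = block.dest_scaffold
        df.loc[mask, "asm_pos"] = dest_len + (df.loc[mask, "pos"] - block.start + 1)
    return df


def _assembly_order(config: SimConfig) -> dict[str, int]:
    return {chrom: i for i, chrom in enumerate(assembly_scaffold_lengths(config))}


# ---------------------------------------------------------------------------
# top-level entry points

def simulate_dataset(
    config: SimConfig,
) -> tuple[TruthTable, list[SiteCounts], list[SiteCounts]]:
    """Run the full generator in memory: truth plus both pools' sites."""
    rng = np.random.default_rng(config.seed)
    markers = place_markers(config, rng)
    truth = simulate_cross(config, rng, markers)
    wt_sites = sequence_pool(truth, "wt", rng)
    mut_sites = sequence_pool(truth, "mut", rng)
    return truth, wt_sites, mut_sites


def run_simulation(config: SimConfig, outdir: str | Path, gzip_output: bool = True) -> dict[str, Path]:
    """Simulate and write standard files: two pileups, truth TSVs, a
    scaffold-length table and a config manifest.  Byte-reproducible
    from the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, wt_sites, mut_sites = simulate_dataset(config)
    suffix = ".pileup.gz" if gzip_output else ".pileup"
    paths = {
        "wt_pileup": outdir / f"wt{suffix}",
        "mut_pileup": outdir / f"mut{suffix}",
        "markers": outdir / "markers.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "scaffolds": outdir / "scaffolds.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_pileup(wt_sites, str(paths["wt_pileup"]))
    write_pileup(mut_sites, str(paths["mut_pileup"]))
    markers = assembly_coordinates(truth.markers, config)
    markers.to_csv(paths["markers"], sep="\t", index=False)
    _write_genotypes(truth, paths["genotypes"])
    write_scaffold_lengths(assembly_scaffold_lengths(config), str(paths["scaffolds"]))
    manifest = dataclasses.asdict(config)
    manifest["causal"] = list(config.causal)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return paths


def _write_genotypes(truth: TruthTable, dest: Path) -> None:
    """Long-format mapcross-allele dosage per embryo per marker."""
    with open(dest, "w") as fh:
        fh.write("pool\tembryo\tchrom\tpos\tdosage\n")
        for pool in ("mut", "wt"):
            codes = truth.genotype_codes(pool)
            chroms = truth.markers["chrom"].to_numpy()
            positions = truth.markers["pos"].to_numpy()
            for e in range(codes.shape[0]):
                row = codes[e]
                for j in range(codes.shape[1]):
                    fh.write(f"{pool}\t{pool}{e:03d}\t{chroms[j]}\t{positions[j]}\t{row[j]}\n")
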
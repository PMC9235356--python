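"""Synthetic duplicated-locus generator.

Emulates the statistical structure of a ~1 Mb gene cluster whose central
gene carries an 18 kb tandem segmental duplication: contact frequency
decays as a power law of genomic distance, a planted TAD boundary inside
the duplication depletes cross-boundary contacts, every duplication copy
carries a reverse-orientation CTCF site, and sequencing reads whose ends
fall in the duplicated block are ambiguous among the copies
(multi-mapping).  Because the copies are exact, ambiguity is the worst
case for mappability.

Coordinates are 0-based half-open base pairs; bins are ``bp // bin_size``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .matrix import ContactMatrix

__all__ = [
    "Gene",
    "CtcfSite",
    "RegionLayout",
    "ReadPair",
    "build_layout",
    "simulate_contacts",
    "write_fixture",
    "read_fixture",
    "CHROM_NAME",
]

CHROM_NAME = "chrS"

# Seven-gene cluster mimicking a regulator-of-complement-activation locus:
# five genes upstream of the duplication-bearing gene's boundary, two below.
DEFAULT_GENES = (
    ("C4BPB", 40_000, 80_000, "+"),
    ("C4BPA", 100_000, 140_000, "+"),
    ("CD55", 180_000, 220_000, "+"),
    ("CR2", 300_000, 340_000, "+"),
    ("CR1", 480_000, 620_000, "+"),
    ("CR1L", 700_000, 760_000, "+"),
    ("CD46", 820_000, 860_000, "+"),
)


@dataclass(frozen=True)
class Gene:
    name: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class CtcfSite:
    pos: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class RegionLayout:
    """Blueprint of the synthetic locus.

    ``dup_unit`` is the (start, end) of the *first* copy; copies are
    tandem and contiguous, so the duplicated block spans
    ``[dup_unit.start, dup_unit.start + dup_copies * unit_length)``.
    """

    region_length: int
    bin_size: int
    genes: tuple[Gene, ...]
    dup_unit: tuple[int, int]
    dup_copies: int
    ctcf_sites: tuple[CtcfSite, ...]
    tad_boundaries_truth: tuple[int, ...]

    def __post_init__(self):
        if self.region_length % self.bin_size != 0:
            raise ValueError("region_length must be a multiple of bin_size")
        s, e = self.dup_unit
        if not (0 <= s < e <= self.region_length):
            raise ValueError("dup_unit outside region")
        if self.dup_copies < 1:
            raise ValueError("dup_copies must be >= 1")
        if self.dup_block[1] > self.region_length:
            raise ValueError("duplication copies extend past the region end")
        bounds = self.tad_boundaries_truth
        if list(bounds) != sorted(set(bounds)):
            raise ValueError("tad_boundaries_truth must be strictly increasing")
        for b in bounds:
            if not (0 < b < self.region_length):
                raise ValueError(f"boundary {b} outside (0, region_length)")
        for k in range(self.dup_copies):
            cs, ce = self.copy_span(k)
            if not any(cs <= site.pos < ce and site.strand == "-"
                       for site in self.ctcf_sites):
                raise ValueError(f"duplication copy {k} lacks a '-' CTCF site")

    # -- derived geometry --------------------------------------------
    @property
    def unit_length(self) -> int:
        return self.dup_unit[1] - self.dup_unit[0]

    @property
    def dup_block(self) -> tuple[int, int]:
        s = self.dup_unit[0]
        return (s, s + self.dup_copies * self.unit_length)

    def copy_span(self, k: int) -> tuple[int, int]:
        s = self.dup_unit[0] + k * self.unit_length
        return (s, s + self.unit_length)

    @property
    def n_bins(self) -> int:
        return self.region_length // self.bin_size

    @property
    def dup_interior_bins(self) -> tuple[int, ...]:
        """Bins lying entirely inside the duplicated block."""
        s, e = self.dup_block
        first = -(-s // self.bin_size)  # ceil
        last = e // self.bin_size       # exclusive
        return tuple(range(first, last))

    def in_dup_block(self, bp: int) -> bool:
        s, e = self.dup_block
        return s <= bp < e

    def homologous_positions(self, bp: int) -> tuple[int, ...]:
        """All copy-equivalent bp positions of ``bp`` (itself if unique)."""
        if not self.in_dup_block(bp):
            return (bp,)
        offset = (bp - self.dup_unit[0]) % self.unit_length
        return tuple(self.dup_unit[0] + k * self.unit_length + offset
                     for k in range(self.dup_copies))


@dataclass(frozen=True)
class ReadPair:
    """One Hi-C ligation product at bin resolution.

    ``candidates`` are the bin pairs the read could map to; a read is
    multi-mapping iff it has more than one candidate.  The true origin is
    always among the candidates.
    """

    read_id: str
    true_bin_pair: tuple[int, int]
    candidates: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.true_bin_pair not in self.candidates:
            raise ValueError("true_bin_pair must be among candidates")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("candidate bin pairs must be unique")

    @property
    def is_multi(self) -> bool:
        return len(self.candidates) > 1


def build_layout(
    region_length: int = 1_000_000,
    bin_size: int = 5_000,
    dup_unit_length: int = 18_000,
    dup_copies: int = 2,
    dup_start: int = 560_000,
    boundary_positions: tuple[int, ...] | None = None,
    ctcf_spec: tuple[tuple[int, str], ...] | None = None,
    genes: tuple[tuple[str, int, int, str], ...] | None = None,
    seed: int = 0,
) -> RegionLayout:
    """Construct a validated :class:`RegionLayout`.

    Defaults emulate the study locus: a 1 Mb region at 5 kb bins, an
    18 kb duplication unit in two tandem copies inside the central gene,
    the planted TAD boundary at the midpoint of the second copy, a
    reverse-orientation CTCF site at the same within-copy offset of every
    copy, and convergent CTCF at the outer TAD anchors.

    ``boundary_positions=None`` plants the default intra-duplication
    boundary; pass an explicit tuple to override.  ``seed`` is accepted
    for interface symmetry; the default layout is fully deterministic.
    """
    del seed  # layout construction is deterministic
    if region_length % bin_size != 0:
        raise ValueError("region_length must be a multiple of bin_size")
    if dup_unit_length < 2 * bin_size:
        raise ValueError("dup_unit_length must be >= 2 * bin_size")

    block_end = dup_start + dup_copies * dup_unit_length
    if block_end > region_length:
        raise ValueError("duplicated block does not fit in the region")

    if boundary_positions is None:
        # midpoint of the second copy (or of the single copy), echoing a
        # boundary refined to the interior of the repeat
        k = 1 if dup_copies >= 2 else 0
        cs = dup_start + k * dup_unit_length
        boundary_positions = (cs + dup_unit_length // 2,)
    boundary_positions = tuple(sorted(int(b) for b in boundary_positions))
    for b in boundary_positions:
        if not (0 < b < region_length):
            raise ValueError(f"boundary {b} outside region")
    if dup_copies >= 2 and not any(dup_start <= b < block_end
                                   for b in boundary_positions):
        raise ValueError("with >=2 copies, one boundary must lie inside "
                         "the duplicated block")

    if ctcf_spec is None:
        sites = [(10_000, "+")]
        # one reverse-orientation site per copy, equal within-copy offset
        for k in range(dup_copies):
            sites.append((dup_start + k * dup_unit_length + dup_unit_length // 2,
                          "-"))
        sites.append((min(block_end + 5_000, region_length - 20_000), "+"))
        sites.append((region_length - 10_000, "-"))
        ctcf_spec = tuple(sites)
    ctcf = tuple(CtcfSite(int(p), s) for p, s in sorted(ctcf_spec))

    gene_rows = DEFAULT_GENES if genes is None else genes
    gene_tuple = tuple(Gene(*row) for row in gene_rows)

    return RegionLayout(
        region_length=region_length,
        bin_size=bin_size,
        genes=gene_tuple,
        dup_unit=(dup_start, dup_start + dup_unit_length),
        dup_copies=dup_copies,
        ctcf_sites=ctcf,
        tad_boundaries_truth=boundary_positions,
    )


def pair_sampling_distribution(
    layout: RegionLayout, decay_alpha: float, insulation: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin-pair arrays (i, j, probability) of the contact sampling law.

    Probability of the cis pair (i < j) is proportional to
    ``(d + 1) ** -decay_alpha`` with ``d = j - i`` bins, multiplied by
    ``insulation`` once per planted boundary the pair straddles
    (straddling judged at bin midpoints).  Self-pairs (d = 0) are
    excluded, mirroring standard short-range Hi-C filtering.
    """
    n = layout.n_bins
    iu, ju = np.triu_indices(n, k=1)
    d = ju - iu
    w = (d + 1.0) ** (-decay_alpha)
    mids = (np.arange(n) + 0.5) * layout.bin_size
    for b in layout.tad_boundaries_truth:
        straddle = (mids[iu] < b) & (mids[ju] > b)
        w = np.where(straddle, w * insulation, w)
    return iu, ju, w / w.sum()


def simulate_contacts(
    layout: RegionLayout,
    n_reads: int = 200_000,
    decay_alpha: float = 1.0,
    insulation: float = 0.2,
    seed: int = 0,
) -> tuple[list[ReadPair], ContactMatrix]:
    """Draw read pairs from the layout's contact law.

    Each read's true bin pair is sampled from
    :func:`pair_sampling_distribution`; a base-pair position is then drawn
    uniformly within each end's bin.  Ends falling in the duplicated
    block receive a candidate at the homologous position of every copy,
    making the read multi-mapping.  The returned truth matrix records
    true bin pairs only (total mass = ``n_reads``).

    Uses ``numpy.random.default_rng`` (PCG64), so identical seeds give
    identical reads on any platform.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not (0.0 < insulation <= 1.0):
        raise ValueError("insulation must be in (0, 1]")
    if decay_alpha <= 0:
        raise ValueError("decay_alpha must be > 0")

    rng = np.random.default_rng(seed)
    iu, ju, p = pair_sampling_distribution(layout, decay_alpha, insulation)
    idx = rng.choice(len(p), size=n_reads, p=p)
    bi, bj = iu[idx], ju[idx]
    bs = layout.bin_size
    bp1 = bi * bs + rng.integers(0, bs, size=n_reads)
    bp2 = bj * bs + rng.integers(0, bs, size=n_reads)

    blk_s, blk_e = layout.dup_block
    amb1 = (bp1 >= blk_s) & (bp1 < blk_e)
    amb2 = (bp2 >= blk_s) & (bp2 < blk_e)
    ambiguous = amb1 | amb2
    width = len(str(max(n_reads - 1, 1)))

    reads: list[ReadPair] = []
    for r in range(n_reads):
        true_pair = (int(bi[r]), int(bj[r]))
        if ambiguous[r]:
            c1 = [pos // bs for pos in layout.homologous_positions(int(bp1[r]))]
            c2 = [pos // bs for pos in layout.homologous_positions(int(bp2[r]))]
            cands = sorted({(a, b) if a <= b else (b, a)
                            for a in c1 for b in c2})
        else:
            cands = [true_pair]
        reads.append(ReadPair(f"r{r:0{width}d}", true_pair, tuple(cands)))

    truth = ContactMatrix(bs, layout.n_bins)
    counts = np.bincount(idx, minlength=len(p))
    for k in np.nonzero(counts)[0]:
        truth.add(int(iu[k]), int(ju[k]), int(counts[k]))
    return reads, truth


# ---------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------

def _bed_line(chrom, start, end, name, score=0, strand=None):
    cols = [chrom, str(start), str(end), name, str(score)]
    if strand is not None:
        cols.append(strand)
    return "\t".join(cols)


def write_fixture(reads: list[ReadPair], layout: RegionLayout,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the read-pair table, truth BEDs and a layout manifest.

    All intervals are 0-based half-open.  The pair table has one line per
    candidate (``read_id  bin_i  bin_j  n_candidates``); true origins go
    to a separate truth table so the fixture round-trips losslessly.
    Output is byte-deterministic for a fixed input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    buf = io.StringIO()
    buf.write("read_id\tbin_i\tbin_j\tn_candidates\n")
    for r in reads:
        for (i, j) in r.candidates:
            buf.write(f"{r.read_id}\t{i}\t{j}\t{len(r.candidates)}\n")
    paths["pairs"] = out_dir / "pairs.tsv"
    paths["pairs"].write_text(buf.getvalue())

    buf = io.StringIO()
    buf.write("read_id\tbin_i\tbin_j\n")
    for r in reads:
        buf.write(f"{r.read_id}\t{r.true_bin_pair[0]}\t{r.true_bin_pair[1]}\n")
    paths["truth_pairs"] = out_dir / "truth_pairs.tsv"
    paths["truth_pairs"].write_text(buf.getvalue())

    paths["boundaries"] = out_dir / "boundaries_truth.bed"
    paths["boundaries"].write_text("".join(
        _bed_line(CHROM_NAME, b, b + 1, f"boundary_{k}") + "\n"
        for k, b in enumerate(layout.tad_boundaries_truth)))

    paths["genes"] = out_dir / "genes.bed"
    paths["genes"].write_text("".join(
        _bed_line(CHROM_NAME, g.start, g.end, g.name, 0, g.strand) + "\n"
        for g in layout.genes))

    paths["ctcf"] = out_dir / "ctcf_sites.bed"
    paths["ctcf"].write_text("".join(
        _bed_line(CHROM_NAME, s.pos, s.pos + 1, f"ctcf_{k}", 0, s.strand) + "\n"
        for k, s in enumerate(layout.ctcf_sites)))

    manifest = {
        "region_length": layout.region_length,
        "bin_size": layout.bin_size,
        "dup_unit": list(layout.dup_unit),
        "dup_copies": layout.dup_copies,
        "genes": [[g.name, g.start, g.end, g.strand] for g in layout.genes],
        "ctcf_sites": [[s.pos, s.strand] for s in layout.ctcf_sites],
        "tad_boundaries_truth": list(layout.tad_boundaries_truth),
    }
    paths["manifest"] = out_dir / "layout.yaml"
    paths["manifest"].write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False))
    return paths


def read_fixture(out_dir: str | Path) -> tuple[list[ReadPair], RegionLayout]:
    """Inverse of :func:`write_fixture`."""
    out_dir = Path(out_dir)
    m = yaml.safe_load((out_dir / "layout.yaml").read_text())
    layout = RegionLayout(
        region_length=m["region_length"],
        bin_size=m["bin_size"],
        genes=tuple(Gene(*row) for row in m["genes"]),
        dup_unit=tuple(m["dup_unit"]),
        dup_copies=m["dup_copies"],
        ctcf_sites=tuple(CtcfSite(p, s) for p, s in m["ctcf_sites"]),
        tad_boundaries_truth=tuple(m["tad_boundaries_truth"]),
    )

    truth: dict[str, tuple[int, int]] = {}
    lines = (out_dir / "truth_pairs.tsv").read_text().splitlines()
    for line in lines[1:]:
        rid, i_s, j_s = line.split("\t")
        truth[rid] = (int(i_s), int(j_s))

    cands: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    lines = (out_dir / "pairs.tsv").read_text().splitlines()
    for line in lines[1:]:
        rid, i_s, j_s, _n = line.split("\t")
        if rid not in cands:
            cands[rid] = []
            order.append(rid)
        cands[rid].append((int(i_s), int(j_s)))

    return [ReadPair(rid, truth[rid], tuple(cands[rid])) for rid in order], layout


def read_pairs_table(path: str | Path) -> list[ReadPair]:
    """Read a bare candidate table (no truth file): the first candidate
    of each read is taken as a placeholder true pair — downstream rescue
    never consults the truth."""
    path = Path(path)
    cands: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        rid, i_s, j_s, _n = line.split("\t")
        if rid not in cands:
            cands[rid] = []
            order.append(rid)
        cands[rid].append((int(i_s), int(j_s)))
    return [ReadPair(rid, cands[rid][0], tuple(cands[rid])) for rid in order]
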
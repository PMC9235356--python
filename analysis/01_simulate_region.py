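#!/usr/bin/env python
"""Build the synthetic duplicated locus and simulate Hi-C read pairs.

The default layout is a 1 Mb region at 5 kb bins holding a seven-gene
cluster; the central gene carries an 18 kb tandem duplication in two
copies, with the planted TAD boundary at the midpoint of the second copy
and a reverse-orientation CTCF site in every copy.  Reads whose ends
fall in the duplicated block are ambiguous among the copies.
"""

import sys
from pathlib import Path

from duphic.matrix import write_triplet
from duphic.region import build_layout, simulate_contacts, write_fixture

OUT = Path("results/analysis/01_simulate")
SEED = 7
N_READS = 200_000


def main():
    layout = build_layout()
    reads, truth = simulate_contacts(layout, n_reads=N_READS, seed=SEED)
    paths = write_fixture(reads, layout, OUT)
    write_triplet(truth, OUT / "truth_matrix.tsv")

    n_multi = sum(r.is_multi for r in reads)
    print(f"region: {layout.region_length:,} bp at {layout.bin_size:,} bp "
          f"bins ({layout.n_bins} bins)")
    print(f"duplication: {layout.unit_length:,} bp x {layout.dup_copies} "
          f"copies spanning {layout.dup_block[0]:,}-{layout.dup_block[1]:,}")
    print(f"planted boundary: {layout.tad_boundaries_truth[0]:,} bp "
          f"(inside duplication copy 2)")
    print(f"reads: {len(reads):,} total, {n_multi:,} multi-mapping "
          f"({100 * n_multi / len(reads):.1f}%)")
    print(f"fixture written to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
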
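#!/usr/bin/env python
"""Scan the synthetic region for CTCF motifs and classify TAD anchors.

Plants the shipped CTCF consensus at every layout site in a random
background sequence, scans both strands, and labels each called TAD by
the orientation of motif hits near its anchors — expecting convergent
anchors on both TADs and one reverse-orientation site per duplication
copy at the internal boundary.
"""

import sys
from pathlib import Path

import numpy as np

from duphic.motifs import (BASES, CTCF_PFM_TEXT, MotifModel,
                           classify_anchor_orientation, plant_motifs_fasta,
                           scan_pwm, write_hits_bed)
from duphic.region import read_fixture
from duphic.tads import TADSegmentation

SIM = Path("results/analysis/01_simulate")
TADS = Path("results/analysis/03_tads")
OUT = Path("results/analysis/05_motifs")
SEED = 7


def shipped_model(threshold=8.0):
    rows = [l.split("\t") for l in CTCF_PFM_TEXT.strip().splitlines()]
    lab = {r[0]: [float(x) for x in r[1:]] for r in rows}
    return MotifModel.from_counts(np.array([lab[b] for b in BASES]).T,
                                  threshold=threshold)


def main():
    if not TADS.exists():
        print("run analysis/03_call_tads.py first", file=sys.stderr)
        return 1
    _, layout = read_fixture(SIM)
    model = shipped_model()
    OUT.mkdir(parents=True, exist_ok=True)
    seq = plant_motifs_fasta(layout, model, seed=SEED,
                             out=OUT / "region.fa")
    hits = scan_pwm(seq, model)
    write_hits_bed(hits, model, OUT / "ctcf_hits.bed")

    # strong hits = planted sites (consensus scores the model maximum)
    strong = [h for h in hits if h.score > 0.75 * model.max_score]
    print(f"scan: {len(hits)} hits >= {model.threshold} bits, "
          f"{len(strong)} at planted-consensus strength")

    rows = [l.split("\t") for l
            in (TADS / "tads.bed").read_text().splitlines()]
    spans = [(int(r[1]), int(r[2])) for r in rows]
    res = 25_000
    n = max(e for _, e in spans) // res
    cuts = sorted({s // res for s, _ in spans} - {0})
    edges = [0, *cuts, n]
    seg = TADSegmentation(res, n, tuple(cuts),
                          tuple((edges[k], edges[k + 1])
                                for k in range(len(edges) - 1)),
                          tuple(0.0 for _ in range(len(edges) - 1)))
    strict = MotifModel(probs=model.probs, background=model.background,
                        threshold=20.0)
    labels = classify_anchor_orientation(scan_pwm(seq, strict), seg)
    out_lines = ["tad_start_bp\ttad_end_bp\tlabel\tn_reverse_right"]
    for row in labels:
        a, b = row["tad"]
        print(f"TAD [{a * res:,}, {b * res:,}) -> {row['label']}; "
              f"{row['n_reverse_right']} reverse-orientation hits at the "
              f"right anchor")
        out_lines.append(f"{a * res}\t{b * res}\t{row['label']}\t"
                         f"{row['n_reverse_right']}")
    (OUT / "anchor_orientation.tsv").write_text("\n".join(out_lines) + "\n")
    print(f"written to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
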
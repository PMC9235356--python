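"""PWM scanning for CTCF sites and TAD-anchor orientation classification.

Loop extrusion favours convergent CTCF motifs at domain anchors: a
forward-orientation site at the left boundary facing a reverse site at
the right boundary.  Tandem repeats can carry one site per copy, giving
periodic same-orientation hits.  This module scores both strands of a
sequence against a position weight matrix in log-odds (bits) and labels
each TAD by the orientation of motif hits near its anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tads import TADSegmentation

__all__ = ["MotifModel", "MotifHit", "scan_pwm",
           "classify_anchor_orientation", "load_motif_table",
           "write_hits_bed", "CTCF_PFM_TEXT"]

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# CTCF core position frequency matrix (19 bp, counts), JASPAR-style rows
# A/C/G/T.  Shipped so the synthetic pipeline is self-contained; any
# motif table in the same format can be supplied instead.
CTCF_PFM_TEXT = """\
A\t87\t167\t281\t56\t8\t744\t40\t107\t851\t5\t333\t54\t12\t56\t104\t372\t82\t117\t402
C\t291\t145\t49\t800\t903\t13\t528\t433\t11\t0\t3\t12\t0\t8\t733\t13\t482\t322\t181
G\t76\t414\t449\t21\t0\t65\t334\t48\t32\t903\t566\t504\t890\t775\t5\t507\t307\t73\t266
T\t459\t187\t134\t36\t2\t91\t11\t324\t18\t3\t9\t341\t8\t71\t67\t17\t37\t396\t59
"""


@dataclass(frozen=True)
class MotifModel:
    """Probability matrix over A,C,G,T per position plus background.

    ``threshold`` is the minimum log2-odds (bits) score for a hit.
    """

    probs: np.ndarray        # (width, 4), rows sum to 1
    background: np.ndarray   # (4,), sums to 1
    threshold: float

    def __post_init__(self):
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probability matrix must be (width, 4)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if np.any(self.probs <= 0) or np.any(self.background <= 0):
            raise ValueError("probabilities must be strictly positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[None, :])

    @property
    def max_score(self) -> float:
        """Score of the consensus — the global maximum."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[k] for k in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25,
                    background: np.ndarray | None = None,
                    threshold: float = 8.0) -> "MotifModel":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        rows = counts.sum(axis=1)
        if np.allclose(rows, 1.0, atol=1e-6):
            probs = counts  # already probabilities
            probs = np.clip(probs, 1e-9, None)
            probs = probs / probs.sum(axis=1, keepdims=True)
        else:
            c = counts + pseudocount
            probs = c / c.sum(axis=1, keepdims=True)
        bg = (np.full(4, 0.25) if background is None
              else np.asarray(background, dtype=float))
        return cls(probs=probs, background=bg, threshold=float(threshold))


@dataclass(frozen=True, order=True)
class MotifHit:
    position: int   # 0-based window start on the forward sequence
    strand: str     # '+' or '-'
    score: float    # log2 odds, bits

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def load_motif_table(path: str | Path, pseudocount: float = 0.25,
                     threshold: float = 8.0) -> MotifModel:
    """Parse a tab-separated motif table.

    Accepts JASPAR-style rows (4 lines labelled A/C/G/T, positions as
    columns) or a column table with header A C G T (one row per
    position); counts or probabilities, auto-detected and normalised.
    """
    rows = [line.split("\t") for line
            in Path(path).read_text().strip().splitlines()]
    if rows and [c.upper() for c in rows[0]] == list(BASES):
        counts = np.array([[float(x) for x in r] for r in rows[1:]])
    elif rows and rows[0][0].upper() in BASES:
        labelled = {r[0].upper(): [float(x) for x in r[1:]] for r in rows}
        if set(labelled) != set(BASES):
            raise ValueError("expected rows labelled A, C, G, T")
        counts = np.array([labelled[b] for b in BASES]).T
    else:
        raise ValueError(f"{path}: unrecognised motif table layout")
    return MotifModel.from_counts(counts, pseudocount=pseudocount,
                                  threshold=threshold)


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def scan_pwm(sequence: str, model: MotifModel) -> list[MotifHit]:
    """Score every window on both strands; report those above threshold.

    Windows containing N are skipped.  The reverse strand is scored on
    the reverse complement of the window; a hit's position is always the
    window start on the forward sequence.  Hits are sorted by position,
    then strand ('+' before '-').
    """
    seq = sequence.upper()
    w = model.width
    if len(seq) < w:
        warnings.warn("sequence shorter than motif width: no hits")
        return []
    code = np.full(len(seq), -1, dtype=int)
    for k, b in enumerate(BASES):
        code[np.frombuffer(seq.encode(), dtype=np.uint8)
             == ord(b)] = k
    lo = model.log_odds
    lo_rc = lo[::-1, ::-1]  # reverse-complement scan on forward coordinates

    n_win = len(seq) - w + 1
    # sliding windows of the integer code
    idx = np.arange(n_win)[:, None] + np.arange(w)[None, :]
    wins = code[idx]
    valid = (wins >= 0).all(axis=1)
    hits: list[MotifHit] = []
    pos_idx = np.arange(w)
    safe = np.where(wins < 0, 0, wins)
    fwd = lo[pos_idx[None, :], safe].sum(axis=1)
    rev = lo_rc[pos_idx[None, :], safe].sum(axis=1)
    for p in np.nonzero(valid)[0]:
        if fwd[p] >= model.threshold:
            hits.append(MotifHit(int(p), "+", float(fwd[p])))
        if rev[p] >= model.threshold:
            hits.append(MotifHit(int(p), "-", float(rev[p])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def classify_anchor_orientation(
    hits: list[MotifHit],
    seg: TADSegmentation,
    anchor_window: int = 50_000,
) -> list[dict]:
    """Label each TAD by the strand pattern of hits at its anchors.

    A hit anchors the left boundary when its position lies within
    ``anchor_window`` bp of the TAD start (and likewise for the right
    boundary / TAD end).  Labels: ``convergent`` ('+' left and '-'
    right), ``tandem`` (same strand both ends), ``divergent`` ('-' left
    and '+' right), else ``unanchored``.  The count of reverse hits at
    the right anchor is reported so repeated reverse sites in a
    duplication are visible.
    """
    res = seg.resolution
    out = []
    for (a, b) in seg.tads:
        left_bp, right_bp = a * res, b * res
        near_left = [h for h in hits
                     if abs(h.position - left_bp) <= anchor_window]
        near_right = [h for h in hits
                      if abs(h.position - right_bp) <= anchor_window]
        plus_l = any(h.strand == "+" for h in near_left)
        minus_l = any(h.strand == "-" for h in near_left)
        plus_r = any(h.strand == "+" for h in near_right)
        minus_r = any(h.strand == "-" for h in near_right)
        if plus_l and minus_r:
            label = "convergent"
        elif (plus_l and plus_r) or (minus_l and minus_r):
            label = "tandem"
        elif minus_l and plus_r:
            label = "divergent"
        else:
            label = "unanchored"
        out.append({
            "tad": (a, b),
            "label": label,
            "n_left_hits": len(near_left),
            "n_right_hits": len(near_right),
            "n_reverse_right": sum(h.strand == "-" for h in near_right),
        })
    return out


def write_hits_bed(hits: list[MotifHit], model: MotifModel,
                   out: str | Path, chrom: str = "chrS") -> Path:
    """BED6 with score scaled to 0-1000 plus the exact bit score in a
    seventh column."""
    out = Path(out)
    mx = model.max_score if model.max_score > 0 else 1.0
    lines = []
    for k, h in enumerate(hits):
        scaled = int(round(min(max(h.score / mx, 0.0), 1.0) * 1000))
        lines.append("\t".join([
            chrom, str(h.position), str(h.position + model.width),
            f"hit_{k}", str(scaled), h.strand, repr(h.score)]))
    out.write_text("\n".join(lines) + ("\n" if lines else ""))
    return out


def plant_motifs_fasta(layout, model: MotifModel, seed: int = 0,
                       out: str | Path | None = None) -> str:
    """Synthetic region sequence with the model's consensus planted at
    every CTCF site of the layout (reverse complement on '-' sites),
    uniform random background elsewhere.  Optionally written as FASTA."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(BASES), size=layout.region_length)
    cons = model.consensus
    for site in layout.ctcf_sites:
        planted = cons if site.strand == "+" else reverse_complement(cons)
        start = min(site.pos, layout.region_length - model.width)
        seq[start:start + model.width] = list(planted)
    text = "".join(seq)
    if out is not None:
        body = "\n".join(text[k:k + 80] for k in range(0, len(text), 80))
        Path(out).write_text(f">{'chrS'}\n{body}\n")
    return text
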
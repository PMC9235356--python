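"""qPCR, ChIP, chromatin-accessibility and luciferase assay arithmetic.

Pure formulas over cycle-threshold (Ct) plate tables and luminometer
readings, plus the pooled-variance unpaired t-test used for group
comparisons.  Conventions:

* expression — comparative Ct: relative level ``2**-(Ct_target -
  Ct_reference)``; fold change between samples is the ratio of their
  relative levels (the double-delta form).
* ChIP enrichment — percent input: the input Ct is first shifted by
  ``log2(1/input_fraction)`` to account for the input dilution.
* ChART accessibility — retained fraction after nuclease digestion,
  normalised to an inaccessible control locus; 0 = fully protected.
* MNase occupancy — the same retained-fraction ratio, reported so that
  1.0 means completely compacted nucleosomes.

Replicates are averaged on the Ct scale before exponentiation; the SEM
of transformed quantities is propagated with the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression", "fold_change", "percent_input",
    "chart_accessibility", "mnase_occupancy", "luciferase_relative",
    "unpaired_t", "TTestResult", "aggregate_ct", "ddct_table",
]

LN2 = math.log(2.0)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Comparative-Ct relative level, ``2**-(ct_target - ct_reference)``."""
    _check_finite(ct_target=ct_target, ct_reference=ct_reference)
    return 2.0 ** -(ct_target - ct_reference)


def fold_change(dct_sample: float, dct_control: float) -> float:
    """Double-delta Ct fold change, ``2**-(dCt_sample - dCt_control)``."""
    _check_finite(dct_sample=dct_sample, dct_control=dct_control)
    return 2.0 ** -(dct_sample - dct_control)


def percent_input(ct_ip: float, ct_input: float,
                  input_fraction: float = 0.01) -> float:
    """ChIP enrichment as percent of input chromatin.

    The input aliquot is ``input_fraction`` of the IP chromatin, so its
    Ct is adjusted by ``log2(1/input_fraction)`` cycles before the
    difference is exponentiated.
    """
    _check_finite(ct_ip=ct_ip, ct_input=ct_input)
    if not (0.0 < input_fraction < 1.0):
        raise ValueError("input_fraction must be in (0, 1)")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def _retained(ct_digested: float, ct_undigested: float) -> float:
    """Fraction of template surviving digestion, ``2**-(dig - undig)``."""
    return 2.0 ** -(ct_digested - ct_undigested)


def chart_accessibility(ct_dig_target: float, ct_undig_target: float,
                        ct_dig_control: float,
                        ct_undig_control: float) -> float:
    """Nuclease accessibility normalised to a protected control locus.

    ``1 - retained(target)/retained(control)``, clipped to [0, 1]; 0
    means the target is as protected as the control, 1 fully accessible.
    """
    _check_finite(ct_dig_target=ct_dig_target,
                  ct_undig_target=ct_undig_target,
                  ct_dig_control=ct_dig_control,
                  ct_undig_control=ct_undig_control)
    rc = _retained(ct_dig_control, ct_undig_control)
    if rc == 0:
        raise ValueError("control locus fully digested: ratio undefined")
    raw = 1.0 - _retained(ct_dig_target, ct_undig_target) / rc
    if raw < 0:
        warnings.warn("target more retained than control; clipping to 0")
    return float(min(max(raw, 0.0), 1.0))


def mnase_occupancy(ct_dig_target: float, ct_undig_target: float,
                    ct_dig_control: float,
                    ct_undig_control: float) -> float:
    """Nucleosome occupancy: ``retained(target)/retained(control)``,
    clipped to [0, 1]; 1.0 represents completely compacted nucleosomes,
    lower values reduced occupancy."""
    _check_finite(ct_dig_target=ct_dig_target,
                  ct_undig_target=ct_undig_target,
                  ct_dig_control=ct_dig_control,
                  ct_undig_control=ct_undig_control)
    rc = _retained(ct_dig_control, ct_undig_control)
    if rc == 0:
        raise ValueError("control locus fully digested: ratio undefined")
    raw = _retained(ct_dig_target, ct_undig_target) / rc
    if raw > 1.0:
        warnings.warn("target more retained than control; clipping to 1")
    return float(min(max(raw, 0.0), 1.0))


def luciferase_relative(firefly_sample: float, renilla_sample: float,
                        firefly_control: float,
                        renilla_control: float) -> float:
    """Dual-luciferase activity relative to an empty-vector control.

    Firefly readings are normalised to the co-transfected Renilla
    internal control; 1.0 means no enhancer effect.
    """
    vals = dict(firefly_sample=firefly_sample, renilla_sample=renilla_sample,
                firefly_control=firefly_control,
                renilla_control=renilla_control)
    for name, v in vals.items():
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite reading")
    return (firefly_sample / renilla_sample) / (firefly_control
                                                / renilla_control)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        """Two-sided significance at the 95% confidence level."""
        return self.p < 0.05


def unpaired_t(group_a, group_b) -> TTestResult:
    """Two-sided Student (pooled-variance) unpaired t-test.

    Degenerate inputs: identical pooled variance of zero with equal
    means gives t = 0, p = 1; zero variance with unequal means is an
    error (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means: "
                         "t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


# ---------------------------------------------------------------------
# plate-table helpers
# ---------------------------------------------------------------------

def _check_finite(**vals):
    for name, v in vals.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")


def aggregate_ct(table: pd.DataFrame,
                 by=("sample", "target")) -> pd.DataFrame:
    """Mean Ct and SEM per group of a plate table with a ``value``
    column holding Ct cycles (replicates averaged on the Ct scale)."""
    if "value" not in table.columns:
        raise ValueError("plate table needs a 'value' column")
    g = table.groupby(list(by))["value"]
    out = g.agg(ct_mean="mean", ct_sem="sem", n="count").reset_index()
    out["ct_sem"] = out["ct_sem"].fillna(0.0)
    return out


def ddct_table(table: pd.DataFrame, reference_target: str,
               control_sample: str) -> pd.DataFrame:
    """Comparative-Ct analysis of a plate table.

    Columns required: sample, target, replicate, value (Ct).  Replicate
    Cts are averaged per (sample, target); each target's dCt subtracts
    the reference target within the sample; fold change compares the
    sample's dCt with the control sample's.  SEM of the fold change is
    delta-method propagated: ``sem(2**-x) = ln2 * 2**-x * sem(x)``.
    """
    agg = aggregate_ct(table)
    ref = agg[agg["target"] == reference_target].set_index("sample")
    if ref.empty:
        raise ValueError(f"reference target {reference_target!r} not found")
    rows = []
    for (sample, target), grp in agg.groupby(["sample", "target"]):
        if target == reference_target:
            continue
        if sample not in ref.index:
            raise ValueError(f"sample {sample!r} lacks the reference target")
        dct = float(grp["ct_mean"].iloc[0] - ref.loc[sample, "ct_mean"])
        sem = float(np.hypot(grp["ct_sem"].iloc[0],
                             ref.loc[sample, "ct_sem"]))
        rows.append({"sample": sample, "target": target,
                     "dct": dct, "dct_sem": sem})
    out = pd.DataFrame(rows)
    ctrl = out[out["sample"] == control_sample].set_index("target")
    if ctrl.empty:
        raise ValueError(f"control sample {control_sample!r} not found")
    fc, fc_sem = [], []
    for _, r in out.iterrows():
        ddct = r["dct"] - float(ctrl.loc[r["target"], "dct"])
        f = 2.0 ** -ddct
        s = float(np.hypot(r["dct_sem"], ctrl.loc[r["target"], "dct_sem"]))
        fc.append(f)
        fc_sem.append(LN2 * f * s)
    out["fold_change"] = fc
    out["fold_change_sem"] = fc_sem
    return out
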
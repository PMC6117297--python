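"""Flow-style gating of event tables into GFP classes and cell-cycle fractions.

Events are classified on the log10 fluorescence scale into ``neg`` (never
labeled), ``lo`` (label diluted by divisions) and ``hi`` (label retaining)
using two thresholds, with boundary ties assigned to the higher class.
``neg`` events are excluded from the denominator of the count summaries,
mirroring the exclusion of cells that never divided during the labeling
pulse.  Cell-cycle fractions follow the Ki67/DNA convention: G0 is
Ki67-negative with 2N DNA, G1 is Ki67-positive with 2N DNA, and S-G2-M is
DNA above the 2N window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GFP_CLASSES = ("neg", "lo", "hi")
CYCLE_PHASES = ("g0", "g1", "sg2m")


@dataclass(frozen=True)
class GateSet:
    """Thresholds defining the GFP classes and cell-cycle phases.

    ``gfp_neg_threshold`` and ``gfp_hi_threshold`` are log10 fluorescence
    units; ``ki67_threshold`` is linear intensity; ``dna_2n_window`` bounds
    the 2N DNA-content peak.
    """

    gfp_neg_threshold: float
    gfp_hi_threshold: float
    ki67_threshold: float = 200.0
    dna_2n_window: tuple[float, float] = (1.6, 2.5)

    def validate(self) -> None:
        if not self.gfp_neg_threshold < self.gfp_hi_threshold:
            raise ValueError("gfp_neg_threshold must be below gfp_hi_threshold")
        lo, hi = self.dna_2n_window
        if not lo < hi:
            raise ValueError("dna_2n_window must be an increasing pair")

    def to_dict(self) -> dict:
        return {"gfp_neg_threshold": self.gfp_neg_threshold,
                "gfp_hi_threshold": self.gfp_hi_threshold,
                "ki67_threshold": self.ki67_threshold,
                "dna_2n_window": list(self.dna_2n_window)}

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        d = dict(d)
        if "dna_2n_window" in d:
            d["dna_2n_window"] = tuple(d["dna_2n_window"])
        g = cls(**d)
        g.validate()
        return g


def derive_gates(events: pd.DataFrame, *, bin_width: float = 0.05,
                 ki67_threshold: float = 200.0,
                 dna_2n_window: tuple[float, float] = (1.6, 2.5)) -> GateSet:
    """Derive default GFP gates from a freshly labeled (week-0) cohort.

    The hi threshold sits one decade below the mode of the labeled
    population; the neg threshold at the autofluorescence mode plus three
    robust SDs (1.4826 x MAD).  When no distinct autofluorescence component
    is present, the neg threshold falls back to two decades below the hi
    threshold.
    """
    gfp = events["gfp"].to_numpy()
    gfp = gfp[gfp > 0]
    if gfp.size == 0:
        raise ValueError("no positive GFP events to derive gates from")
    lg = np.log10(gfp)
    edges = np.arange(lg.min() - bin_width, lg.max() + 2 * bin_width, bin_width)
    hist, _ = np.histogram(lg, bins=edges)
    labeled_mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    hi = labeled_mode - 1.0

    low = lg[lg < hi - 0.5]
    if low.size >= 10:
        lhist, _ = np.histogram(low, bins=edges)
        low_mode = 0.5 * (edges[lhist.argmax()] + edges[lhist.argmax() + 1])
        rsd = 1.4826 * np.median(np.abs(low - np.median(low)))
        neg = min(low_mode + 3.0 * rsd, hi - 0.1)
    else:
        neg = hi - 2.0
    gates = GateSet(gfp_neg_threshold=float(neg), gfp_hi_threshold=float(hi),
                    ki67_threshold=ki67_threshold, dna_2n_window=dna_2n_window)
    gates.validate()
    return gates


def classify_gfp(events: pd.DataFrame,
                 gates: GateSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each event a GFP class and tally per-mouse class counts.

    Returns ``(labeled_events, class_counts)``.  Rows with non-positive GFP
    cannot be placed on the log scale and are rejected with a logged warning.
    Boundary ties go to the higher class: an event exactly at the hi
    threshold is ``hi``, exactly at the neg threshold is ``lo``.
    """
    gates.validate()
    bad = ~(events["gfp"] > 0)
    if bad.any():
        logger.warning("rejecting %d event(s) with non-positive GFP", int(bad.sum()))
    ev = events.loc[~bad].copy()
    lg = np.log10(ev["gfp"].to_numpy())
    label = np.where(lg < gates.gfp_neg_threshold, "neg",
                     np.where(lg >= gates.gfp_hi_threshold, "hi", "lo"))
    ev["gfp_class"] = pd.Categorical(label, categories=list(GFP_CLASSES))
    counts = (ev.groupby(["mouse_id", "group", "week"], observed=True)["gfp_class"]
                .value_counts(sort=False).unstack(fill_value=0)
                .rename(columns={c: f"n_{c}" for c in GFP_CLASSES})
                .reset_index())
    return ev, counts


def summarize_counts(labeled_events: pd.DataFrame) -> pd.DataFrame:
    """Collapse classified events into the per-mouse count series.

    ``gfphi_dn3`` counts hi events; ``dn3`` counts hi + lo events (neg
    events — cells that never divided during the pulse — are excluded from
    the denominator).  Mice with no non-neg events are emitted with
    ``dn3 = 0`` and flagged.
    """
    if "gfp_class" not in labeled_events.columns:
        raise ValueError("events must be classified first (missing gfp_class)")
    grouped = labeled_events.groupby(["mouse_id", "group", "week"], observed=True)

    def _agg(df: pd.DataFrame) -> pd.Series:
        hi = int((df["gfp_class"] == "hi").sum())
        lo = int((df["gfp_class"] == "lo").sum())
        return pd.Series({"gfphi_dn3": hi, "dn3": hi + lo,
                          "flagged": hi + lo == 0})

    out = grouped.apply(_agg, include_groups=False).reset_index()
    out["gfphi_dn3"] = out["gfphi_dn3"].astype(int)
    out["dn3"] = out["dn3"].astype(int)
    out["flagged"] = out["flagged"].astype(bool)
    n_flag = int(out["flagged"].sum())
    if n_flag:
        logger.warning("%d mouse/week rows have no non-neg events", n_flag)
    return out


def cell_cycle_fractions(labeled_events: pd.DataFrame,
                         gates: GateSet) -> pd.DataFrame:
    """Ki67/DNA cell-cycle fractions per mouse and GFP class.

    G0: Ki67 below threshold and DNA in the 2N window.  G1: Ki67 at or above
    threshold and 2N.  S-G2-M: DNA above the 2N window.  Events below the 2N
    window are counted in a flagged sub-2N bin and excluded from the
    fractions.  Empty (mouse, class) combinations are emitted explicitly
    with ``n_events = 0`` and NaN fractions rather than zeros.
    """
    gates.validate()
    if "gfp_class" not in labeled_events.columns:
        raise ValueError("events must be classified first (missing gfp_class)")
    for col in ("ki67", "dna_content"):
        if col not in labeled_events.columns:
            raise ValueError(f"missing required channel {col!r}")

    ev = labeled_events.copy()
    lo2n, hi2n = gates.dna_2n_window
    dna = ev["dna_content"].to_numpy()
    ki = ev["ki67"].to_numpy()
    sub2n = dna < lo2n
    in2n = (dna >= lo2n) & (dna <= hi2n)
    phase = np.full(len(ev), "sub2n", dtype=object)
    phase[in2n & (ki < gates.ki67_threshold)] = "g0"
    phase[in2n & (ki >= gates.ki67_threshold)] = "g1"
    phase[dna > hi2n] = "sg2m"
    ev["phase"] = phase

    mice = ev[["mouse_id", "group"]].drop_duplicates()
    rows = []
    for _, mrow in mice.iterrows():
        sel = ev[ev["mouse_id"] == mrow["mouse_id"]]
        for cls in GFP_CLASSES:
            cls_ev = sel[sel["gfp_class"] == cls]
            n_sub = int((cls_ev["phase"] == "sub2n").sum())
            used = cls_ev[cls_ev["phase"] != "sub2n"]
            n = len(used)
            rec = {"mouse_id": mrow["mouse_id"], "group": mrow["group"],
                   "gfp_class": cls, "n_events": n, "n_sub2n": n_sub}
            if n == 0:
                rec.update({f"f_{p}": np.nan for p in CYCLE_PHASES})
            else:
                for p in CYCLE_PHASES:
                    rec[f"f_{p}"] = float((used["phase"] == p).sum()) / n
            rows.append(rec)
    out = pd.DataFrame(rows)
    if out["n_sub2n"].sum():
        logger.warning("excluded %d sub-2N event(s) from cell-cycle fractions",
                       int(out["n_sub2n"].sum()))
    return out


def fold_expansion(output_count: float, input_count: float) -> float:
    """Fold expansion of a transplanted population: output / input cells."""
    if input_count <= 0:
        raise ValueError("input_count must be positive")
    if output_count < 0:
        raise ValueError("output_count must be non-negative")
    return float(output_count) / float(input_count)
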
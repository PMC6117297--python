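"""Branching-process simulation of pulse-chase label dilution.

A cohort of mice carries a dividing-cell compartment (DN3 thymocytes in the
motivating experiment) in which a fluorescent histone label is loaded during
a labeling pulse and diluted approximately twofold per division during the
chase.  The simulator produces per-cell ground truth (`CellRecord` rows) and
a flow-cytometry-like measured event table, for configurable mixtures of a
cycle-restricted (slow) and a proliferative (fast) subpopulation.

Labeling model: any cell that divides during the pulse carries the full
label ``initial_label`` at chase start; a configurable fraction of cells
that never divided stays unlabeled and is gated out downstream.  During the
chase each division splits the parent's label between the two daughters with
expectation one half each (symmetric beta split), so total label is conserved
exactly in the absence of cell death.

This module also hosts the synthetic-data generators used by the statistical
modules: log-ratio decay datasets drawn from the exponential label-loss
model, and bulk expression matrices with optional whole-chromosome dosage
spike-ins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from labelkin._units import HOURS_PER_WEEK

logger = logging.getLogger(__name__)

#: Sentinel for a subpopulation exit rate that balances its division rate
#: (ln 2 / mean division time), keeping the subpopulation near steady state.
BALANCED = "balanced"

_MEASURE_STREAM = 1_000_003  # child-stream tag for measurement noise


@dataclass(frozen=True)
class Subpopulation:
    """One kinetic compartment of the labeled population.

    Parameters
    ----------
    name:
        Label used in ground-truth tables (e.g. ``"proliferative"``).
    fraction:
        Fraction of all cells in a mouse belonging to this subpopulation.
        Together with the config's ``unlabeled_fraction`` the fractions must
        sum to one.
    mean_division_time_h:
        Mean cell-cycle length in hours.
    division_time_cv:
        Coefficient of variation of the gamma-distributed cycle length;
        0 gives deterministic cycles.
    exit_rate_per_h:
        Per-hour exponential rate of leaving the compartment (death or
        differentiation).  The default :data:`BALANCED` sets the rate to
        ``ln(2) / mean_division_time_h`` so the subpopulation size stays
        near-constant, mimicking a flux-balanced progenitor pool.  ``None``
        falls back to the config-wide ``death_rate_per_h``.
    """

    name: str
    fraction: float
    mean_division_time_h: float
    division_time_cv: float = 0.2
    exit_rate_per_h: float | str | None = BALANCED

    def resolved_exit_rate(self, default_rate: float) -> float:
        if isinstance(self.exit_rate_per_h, str):
            if self.exit_rate_per_h != BALANCED:
                raise ValueError(
                    f"unknown exit rate spec {self.exit_rate_per_h!r}")
            return math.log(2.0) / self.mean_division_time_h
        if self.exit_rate_per_h is None:
            return float(default_rate)
        return float(self.exit_rate_per_h)


def _default_subpopulations() -> dict[str, tuple[Subpopulation, ...]]:
    # Control mice: one fast-cycling compartment (measured ~18.2 h cycles).
    # Transgenic mice: slower cycling overall (~50.1 h) plus a small
    # cycle-restricted compartment that retains label through an 8-week chase.
    return {
        "control": (
            Subpopulation("proliferative", 0.98, 18.2, 0.2),
        ),
        "lmo2": (
            Subpopulation("proliferative", 0.87, 50.1, 0.2),
            Subpopulation("restricted", 0.05, 1200.0, 0.2),
        ),
    }


@dataclass
class SimConfig:
    """Full specification of a synthetic pulse-chase cohort.

    ``subpopulations`` may be a mapping from group label to a tuple of
    :class:`Subpopulation`, or a single tuple applied to every group.
    ``unlabeled_fraction`` (cells that never divided during the pulse and so
    never incorporated label) may likewise be per-group or scalar.
    """

    n_mice_per_group: int = 3
    groups: tuple[str, ...] = ("control", "lmo2")
    subpopulations: Mapping[str, tuple[Subpopulation, ...]] | tuple[Subpopulation, ...] = field(
        default_factory=_default_subpopulations)
    label_duration_h: float = 1008.0          # 6-week doxycycline pulse
    chase_weeks: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    initial_label: float = 1.0e4              # L0, arbitrary fluorescence units
    partition_cv: float = 0.1                 # CV of the daughter split fraction
    measurement_cv: float = 0.25              # log-normal measurement noise CV
    autofluorescence: float = 10.0            # additive floor, fluorescence units
    unlabeled_fraction: float | Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.02, "lmo2": 0.08})
    death_rate_per_h: float = 0.0             # fallback exit rate
    n_cells_per_mouse: int = 2000             # events sampled per mouse
    n_founders: int | None = None             # defaults to n_cells_per_mouse
    max_population: int = 50_000              # uniform-thinning cap per mouse
    g0_dwell_h: float = 30.0                  # dwell beyond which a cell reads as G0
    g1_fraction: float = 0.5                  # fraction of the cycle spent in G1
    ki67_pos_mean: float = 1000.0
    ki67_neg_mean: float = 50.0
    ki67_cv: float = 0.3
    dna_cv: float = 0.03
    seed: int = 0

    # -- accessors -------------------------------------------------------
    def subpopulations_for(self, group: str) -> tuple[Subpopulation, ...]:
        if isinstance(self.subpopulations, Mapping):
            if group not in self.subpopulations:
                raise ValueError(f"no subpopulations configured for group {group!r}")
            return tuple(self.subpopulations[group])
        return tuple(self.subpopulations)

    def unlabeled_fraction_for(self, group: str) -> float:
        if isinstance(self.unlabeled_fraction, Mapping):
            return float(self.unlabeled_fraction.get(group, 0.0))
        return float(self.unlabeled_fraction)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if not self.chase_weeks:
            raise ValueError("at least one chase week is required")
        if min(self.chase_weeks) < 0:
            raise ValueError("chase weeks must be non-negative")
        if self.n_mice_per_group < 1 or self.n_cells_per_mouse < 1:
            raise ValueError("mouse and cell counts must be positive")
        if self.n_founders is not None and self.n_founders < 1:
            raise ValueError("n_founders must be positive when given")
        if self.max_population < 2:
            raise ValueError("max_population must be at least 2")
        if self.autofluorescence <= 0:
            raise ValueError("autofluorescence floor must be positive")
        if self.initial_label <= self.autofluorescence:
            raise ValueError("initial_label must exceed the autofluorescence floor")
        if not (0 <= self.partition_cv < 1):
            raise ValueError("partition_cv must lie in [0, 1)")
        for name in ("measurement_cv", "death_rate_per_h", "label_duration_h",
                     "g0_dwell_h", "ki67_cv", "dna_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.g1_fraction < 1):
            raise ValueError("g1_fraction must lie in (0, 1)")
        for group in self.groups:
            subs = self.subpopulations_for(group)
            if not subs:
                raise ValueError(f"empty subpopulation list for group {group!r}")
            unl = self.unlabeled_fraction_for(group)
            if unl < 0:
                raise ValueError("unlabeled_fraction must be non-negative")
            total = sum(s.fraction for s in subs) + unl
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"subpopulation fractions plus unlabeled_fraction must sum "
                    f"to 1 for group {group!r} (got {total!r})")
            for s in subs:
                if s.fraction < 0:
                    raise ValueError("subpopulation fractions must be non-negative")
                if s.mean_division_time_h <= 0:
                    raise ValueError("mean division times must be positive")
                if s.division_time_cv < 0:
                    raise ValueError("division-time CVs must be non-negative")
                s.resolved_exit_rate(self.death_rate_per_h)  # validates spec

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        def subs_to_list(subs):
            return [
                {"name": s.name, "fraction": s.fraction,
                 "mean_division_time_h": s.mean_division_time_h,
                 "division_time_cv": s.division_time_cv,
                 "exit_rate_per_h": s.exit_rate_per_h}
                for s in subs]

        d = {k: v for k, v in self.__dict__.items()}
        if isinstance(self.subpopulations, Mapping):
            d["subpopulations"] = {g: subs_to_list(v)
                                   for g, v in self.subpopulations.items()}
        else:
            d["subpopulations"] = subs_to_list(self.subpopulations)
        if isinstance(self.unlabeled_fraction, Mapping):
            d["unlabeled_fraction"] = dict(self.unlabeled_fraction)
        d["groups"] = list(self.groups)
        d["chase_weeks"] = list(self.chase_weeks)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)

        def subs_from_list(lst):
            return tuple(Subpopulation(**item) for item in lst)

        if "subpopulations" in d:
            subs = d["subpopulations"]
            if isinstance(subs, Mapping):
                d["subpopulations"] = {g: subs_from_list(v) for g, v in subs.items()}
            else:
                d["subpopulations"] = subs_from_list(subs)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        if "chase_weeks" in d:
            d["chase_weeks"] = tuple(float(w) for w in d["chase_weeks"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Core branching-process engine
# ---------------------------------------------------------------------------

_UNLABELED = "unlabeled"

_TRUTH_COLUMNS = ["cell_id", "mouse_id", "group", "week", "subpopulation",
                  "true_gfp", "n_divisions", "alive",
                  "t_since_last_division_h", "cycle_length_h"]


def _split_fractions(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Daughter-1 share of the parent label: Beta(a, a), mean 1/2, CV `cv`."""
    if cv <= 0:
        return np.full(n, 0.5)
    a = 0.5 * (1.0 / cv**2 - 1.0)
    return rng.beta(a, a, n)


def _draw_cycles(rng: np.random.Generator, sub: np.ndarray,
                 mean_t: np.ndarray, cv: np.ndarray) -> np.ndarray:
    out = np.empty(sub.size)
    for k in range(mean_t.size):
        mask = sub == k
        if not mask.any():
            continue
        t = mean_t[k]
        if not np.isfinite(t):
            out[mask] = np.inf
            continue
        c = cv[k]
        if c <= 0:
            out[mask] = t
        else:
            shape = 1.0 / c**2
            out[mask] = rng.gamma(shape, t / shape, int(mask.sum()))
    finite = np.isfinite(out)
    out[finite] = np.clip(out[finite], 1e-6, None)  # guarantee forward progress
    return out


def _exit_times(rng: np.random.Generator, birth: np.ndarray,
                rates: np.ndarray) -> np.ndarray:
    e = rng.standard_exponential(birth.size)
    with np.errstate(divide="ignore"):
        wait = np.where(rates > 0, e / np.where(rates > 0, rates, 1.0), np.inf)
    return birth + wait


def simulate_mouse(config: SimConfig, group: str, week: float, mouse_id: str,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one mouse's population at chase time ``week`` and sample cells.

    Returns a ground-truth table (one row per sampled surviving cell).  The
    population is thinned uniformly whenever it exceeds
    ``config.max_population``; uniform thinning leaves the per-cell label
    distribution unbiased because cell fates are independent.
    """
    t_end = week * HOURS_PER_WEEK
    subs = config.subpopulations_for(group)
    n_sub = len(subs)
    mean_t = np.array([s.mean_division_time_h for s in subs] + [np.inf])
    cv = np.array([s.division_time_cv for s in subs] + [0.0])
    rates = np.array([s.resolved_exit_rate(config.death_rate_per_h) for s in subs]
                     + [config.death_rate_per_h])

    n0 = config.n_founders if config.n_founders is not None else config.n_cells_per_mouse
    probs = [s.fraction for s in subs] + [config.unlabeled_fraction_for(group)]
    counts = rng.multinomial(n0, np.asarray(probs) / np.sum(probs))
    sub = np.repeat(np.arange(n_sub + 1), counts)
    is_unl = sub == n_sub

    cycle = _draw_cycles(rng, sub, mean_t, cv)
    phase = rng.random(n0)
    t_last = np.full(n0, -config.label_duration_h)
    t_next = np.full(n0, np.inf)
    lab = ~is_unl
    t_last[lab] = -phase[lab] * cycle[lab]
    t_next[lab] = t_last[lab] + cycle[lab]
    gfp = np.where(is_unl, 0.0, config.initial_label)
    ndiv = np.zeros(n0, dtype=np.int64)
    t_exit = _exit_times(rng, np.zeros(n0), rates[sub])

    state = {"gfp": gfp, "sub": sub, "ndiv": ndiv, "t_last": t_last,
             "t_next": t_next, "t_exit": t_exit, "cycle": cycle}
    done = {k: np.empty(0, dtype=v.dtype) for k, v in state.items()}

    max_iter = 500_000
    for _ in range(max_iter):
        if state["gfp"].size == 0:
            break
        t_next = state["t_next"]
        t_exit = state["t_exit"]
        divides = (t_next <= t_end) & (t_next < t_exit)
        dies = ~divides & (t_exit <= t_end)
        survives = ~divides & ~dies

        if survives.any():
            done = {k: np.concatenate([done[k], state[k][survives]])
                    for k in state}

        m = int(divides.sum())
        if m:
            g = state["gfp"][divides]
            birth = t_next[divides]
            dsub = np.tile(state["sub"][divides], 2)
            dnd = np.tile(state["ndiv"][divides] + 1, 2)
            f = _split_fractions(rng, m, config.partition_cv)
            dg = np.concatenate([g * f, g * (1.0 - f)])
            dbirth = np.tile(birth, 2)
            dcycle = _draw_cycles(rng, dsub, mean_t, cv)
            state = {
                "gfp": dg, "sub": dsub, "ndiv": dnd, "t_last": dbirth,
                "t_next": dbirth + dcycle,
                "t_exit": _exit_times(rng, dbirth, rates[dsub]),
                "cycle": dcycle,
            }
        else:
            state = {k: v[:0] for k, v in state.items()}

        total = done["gfp"].size + state["gfp"].size
        if total > config.max_population:
            keep = np.zeros(total, dtype=bool)
            keep[rng.choice(total, config.max_population, replace=False)] = True
            nd = done["gfp"].size
            done = {k: v[keep[:nd]] for k, v in done.items()}
            state = {k: v[keep[nd:]] for k, v in state.items()}
    else:  # pragma: no cover - defensive
        raise RuntimeError("branching-process simulation failed to terminate")

    n_alive = done["gfp"].size
    if n_alive == 0:
        logger.warning("mouse %s: no surviving cells at week %g", mouse_id, week)
        return pd.DataFrame(columns=_TRUTH_COLUMNS)

    take = min(config.n_cells_per_mouse, n_alive)
    idx = np.sort(rng.choice(n_alive, take, replace=False))
    names = [s.name for s in subs] + [_UNLABELED]
    subnames = np.array(names, dtype=object)[done["sub"][idx]]
    return pd.DataFrame({
        "cell_id": [f"{mouse_id}-c{i}" for i in range(take)],
        "mouse_id": mouse_id,
        "group": group,
        "week": float(week),
        "subpopulation": subnames,
        "true_gfp": done["gfp"][idx],
        "n_divisions": done["ndiv"][idx],
        "alive": True,
        "t_since_last_division_h": t_end - done["t_last"][idx],
        "cycle_length_h": done["cycle"][idx],
    })


def simulate_pulse_chase(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort and return ``(events, truth)`` tables.

    One set of ``n_mice_per_group`` mice is generated per group and chase
    week (a cross-sectional design: each mouse is sampled once).  Per-mouse
    random streams are spawned deterministically from ``config.seed``, so
    identical configs yield bit-identical outputs.
    """
    config.validate()
    mice = [(group, week, f"{group}-w{week:g}-m{j + 1}")
            for group in config.groups
            for week in config.chase_weeks
            for j in range(config.n_mice_per_group)]
    children = np.random.SeedSequence(config.seed).spawn(len(mice) + 1)
    parts = []
    for (group, week, mouse_id), child in zip(mice, children):
        parts.append(simulate_mouse(config, group, week, mouse_id,
                                    np.random.default_rng(child)))
    truth = pd.concat(parts, ignore_index=True)
    if truth.empty:
        raise RuntimeError("simulation produced no surviving cells")
    events = measure_events(truth, config,
                            rng=np.random.default_rng(children[-1]))
    return events, truth


# ---------------------------------------------------------------------------
# Measurement model
# ---------------------------------------------------------------------------

def true_g0_mask(truth: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Ground-truth G0 classification: dwell since last division > threshold."""
    return truth["t_since_last_division_h"].to_numpy() > config.g0_dwell_h


def measure_events(truth: pd.DataFrame, config: SimConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Apply the measurement model to ground-truth cells.

    Measured GFP is ``(true GFP + autofluorescence)`` times a multiplicative
    log-normal factor with unit median and CV ``measurement_cv`` (so the
    geometric mean of replicate measurements equals the noise-free value).
    Ki67 and DNA-content channels are derived from the cell's cycling state:
    cells dwelling longer than ``g0_dwell_h`` since their last division read
    as Ki67-negative with 2N DNA; cycling cells read Ki67-positive, with DNA
    ramping from 2N to 4N through the post-G1 part of the cycle.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _MEASURE_STREAM]))
    n = len(truth)

    def lognoise(cv: float, size: int) -> np.ndarray:
        if cv <= 0:
            return np.ones(size)
        sigma = math.sqrt(math.log1p(cv**2))
        return np.exp(rng.normal(0.0, sigma, size))

    gfp = (truth["true_gfp"].to_numpy() + config.autofluorescence) * \
        lognoise(config.measurement_cv, n)

    dwell = truth["t_since_last_division_h"].to_numpy()
    cyc = truth["cycle_length_h"].to_numpy()
    in_g0 = dwell > config.g0_dwell_h
    u = np.zeros(n)
    fin = np.isfinite(cyc) & (cyc > 0)
    u[fin] = np.clip(dwell[fin] / cyc[fin], 0.0, 1.0)
    in_s = ~in_g0 & (u >= config.g1_fraction)

    ki67 = np.where(in_g0, config.ki67_neg_mean, config.ki67_pos_mean) * \
        lognoise(config.ki67_cv, n)
    ramp = np.clip((u - config.g1_fraction) / (1.0 - config.g1_fraction), 0.0, 1.0)
    dna = np.where(in_s, 2.0 + 2.0 * ramp, 2.0) * lognoise(config.dna_cv, n)

    return pd.DataFrame({
        "cell_id": truth["cell_id"].to_numpy(),
        "mouse_id": truth["mouse_id"].to_numpy(),
        "group": truth["group"].to_numpy(),
        "week": truth["week"].to_numpy(),
        "gfp": gfp,
        "ki67": ki67,
        "dna_content": dna,
    })


# ---------------------------------------------------------------------------
# Bookkeeping oracles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationCheck:
    """Result of a total-label conservation audit between two snapshots."""

    conserved: bool
    rel_deviation: float
    death_interference: bool

    def __bool__(self) -> bool:  # truthiness == conservation verdict
        return self.conserved


def total_label_conservation(before: pd.DataFrame, after: pd.DataFrame,
                             rel_tol: float = 1e-9) -> ConservationCheck:
    """Check that summed true GFP is unchanged between two snapshots.

    Division only redistributes label, so absent death the population total
    is invariant.  Death is flagged (and conservation denied) when either
    snapshot carries dead cells or the population shrank, which divisions
    alone cannot do.
    """
    tot_b = float(before["true_gfp"].sum())
    tot_a = float(after["true_gfp"].sum())
    rel = abs(tot_a - tot_b) / tot_b if tot_b > 0 else abs(tot_a)
    death = len(after) < len(before)
    for snap in (before, after):
        if "alive" in snap.columns and (~snap["alive"].astype(bool)).any():
            death = True
    return ConservationCheck(conserved=(rel <= rel_tol) and not death,
                             rel_deviation=rel, death_interference=death)


def divide_population(truth: pd.DataFrame, partition_cv: float,
                      rng: np.random.Generator, rounds: int = 1) -> pd.DataFrame:
    """Apply synchronous division rounds to a ground-truth table.

    Every cell splits into two daughters whose label shares follow the
    symmetric beta partition model.  This is the reference harness for the
    conservation oracle: no death, pure redistribution.
    """
    out = truth.copy()
    for _ in range(rounds):
        g = out["true_gfp"].to_numpy()
        f = _split_fractions(rng, g.size, partition_cv)
        halves = pd.concat([out, out], ignore_index=True)
        halves["true_gfp"] = np.concatenate([g * f, g * (1.0 - f)])
        halves["n_divisions"] = np.tile(out["n_divisions"].to_numpy() + 1, 2)
        out = halves
    return out


# ---------------------------------------------------------------------------
# Synthetic data for the statistical modules
# ---------------------------------------------------------------------------

#: Default exponential-decay parameters (A, B, R) per group for synthetic
#: log-ratio datasets: a fast-decaying control (label lost within ~2 weeks)
#: and a slow-decaying transgenic group that retains label through week 8.
DEFAULT_DECAY_PARAMS: dict[str, tuple[float, float, float]] = {
    "control": (-2.7, 2.7, 0.10),
    "lmo2": (-2.7, 2.55, 0.80),
}

#: Residual scatter of per-mouse log10 ratios around the group curve.
DEFAULT_LOGRATIO_SD = 0.3


def simulate_logratio_series(
        group_params: Mapping[str, tuple[float, float, float]] | None = None,
        weeks: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0),
        n_mice: int = 4,
        noise_sd: float = DEFAULT_LOGRATIO_SD,
        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a log-ratio dataset directly from ``Y = A + B * R**X`` plus noise.

    One observation per mouse and week, ``n_mice`` mice per group per week,
    i.i.d. Gaussian residuals on the log10 scale.
    """
    if group_params is None:
        group_params = DEFAULT_DECAY_PARAMS
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for group, (a, b, r) in group_params.items():
        for week in weeks:
            mu = a + b * r**week
            y = mu + rng.normal(0.0, noise_sd, n_mice)
            for j in range(n_mice):
                rows.append((group, f"{group}-w{week:g}-m{j + 1}",
                             float(week), float(y[j])))
    return pd.DataFrame(rows, columns=["group", "mouse_id", "x", "y"])


#: Genes per mouse chromosome for synthetic expression matrices; roughly
#: proportional to real gene density, downsampled to keep matrices small.
DEFAULT_CHROM_GENE_COUNTS: dict[str, int] = {
    "chr1": 130, "chr2": 150, "chr3": 90, "chr4": 120, "chr5": 110,
    "chr6": 100, "chr7": 140, "chr8": 90, "chr9": 110, "chr10": 90,
    "chr11": 150, "chr12": 70, "chr13": 80, "chr14": 70, "chr15": 100,
    "chr16": 60, "chr17": 90, "chr18": 60, "chr19": 60, "chrX": 80,
    "chrY": 12,
}


def simulate_expression(
        n_samples: int = 6,
        spikes: Sequence[tuple[str, Sequence[int], float]] = (),
        noise_sd: float = 0.5,
        gene_counts: Mapping[str, int] | None = None,
        baseline_mean: float = 6.0,
        baseline_sd: float = 2.0,
        rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log2 expression matrix with optional chromosome spike-ins.

    Each gene has a baseline drawn once and shared across samples; samples
    add i.i.d. Gaussian noise (SD ``noise_sd``).  A spike
    ``(chromosome, sample_indices, log2_shift)`` adds a constant dosage shift
    to every gene of that chromosome in the given samples — e.g.
    ``log2(3/2)`` for a fully dosage-expressed trisomy.

    Returns ``(expression, annotation)``: a genes x samples DataFrame and a
    two-column gene→chromosome table.
    """
    if gene_counts is None:
        gene_counts = DEFAULT_CHROM_GENE_COUNTS
    if rng is None:
        rng = np.random.default_rng()
    chroms = np.concatenate([np.repeat(c, n) for c, n in gene_counts.items()])
    n_genes = chroms.size
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    base = rng.normal(baseline_mean, baseline_sd, n_genes)
    mat = base[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples))
    for chrom, sample_idx, shift in spikes:
        gmask = chroms == chrom
        if not gmask.any():
            raise ValueError(f"unknown chromosome {chrom!r} in spike")
        for j in sample_idx:
            mat[gmask, j] += shift
    expr = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    annot = pd.DataFrame({"gene": genes, "chromosome": chroms})
    return expr, annot
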
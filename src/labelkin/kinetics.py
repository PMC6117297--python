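"""Exponential label-loss kinetics on log10 count ratios.

The measured quantity per mouse is the log10 ratio of label-retaining to
total cells, offset-stabilized as ``Y = log10((hi + c) / total)``.  Label
loss over chase time ``X`` (weeks) follows

    Y = A + B * R**X,      0 < R < 1,

so ``Y(0) = A + B`` and ``Y`` asymptotes at ``A``; ``R`` is the weekly
retention factor.  Fitting is nonlinear least squares via variable
projection: for fixed ``R`` the model is linear in ``A`` and ``B``, so the
sum of squares is profiled over ``R`` alone (grid scan plus bounded Brent
refinement), which is exact on noiseless data and fast enough for
thousands of bootstrap refits.

Group structure is selected over the nested sequence
shared(A,B,R) -> separate A -> separate A,B -> separate A,B,R with
extra-sum-of-squares F-tests; the final reported model keeps all three
parameters group-specific regardless of the last test's outcome.  Inference
on times to k-log reduction uses bootstrap of residuals.  A companion
estimator converts mean-fluorescence halving between two chase times into a
mean division time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from labelkin._units import HOURS_PER_WEEK
from labelkin.gating import GateSet, classify_gfp

logger = logging.getLogger(__name__)

STRUCTURE_ORDER = ("shared", "A", "AB", "ABR")

_R_GRID = np.linspace(1e-4, 1.0 - 1e-4, 241)
_R_EDGE = 1e-6          # proximity to 0/1 that flags non-identifiability
_B_TINY = 1e-8          # |B| below which R is unidentifiable


# ---------------------------------------------------------------------------
# Log-ratio transform
# ---------------------------------------------------------------------------

def log_ratio_transform(counts: pd.DataFrame, c: float = 100.0) -> pd.DataFrame:
    """Variance-stabilized log ratio ``Y = log10((gfphi_dn3 + c) / dn3)``.

    The offset ``c`` (default 100) keeps the log finite when the hi count is
    zero; it should stay below the smallest nonzero hi count in the data,
    and a warning is emitted otherwise.  Rows with ``dn3 == 0`` cannot form
    a ratio and are rejected with a logged warning.
    """
    if c <= 0:
        raise ValueError("offset c must be positive")
    bad = counts["dn3"] <= 0
    if bad.any():
        logger.warning("rejecting %d count row(s) with dn3 == 0", int(bad.sum()))
    cc = counts.loc[~bad]
    nonzero = cc.loc[cc["gfphi_dn3"] > 0, "gfphi_dn3"]
    if not nonzero.empty and c >= nonzero.min():
        logger.warning(
            "offset c=%g is not below the smallest nonzero gfphi_dn3 (%g); "
            "the transform will be dominated by the offset", c, nonzero.min())
    out = pd.DataFrame({
        "group": cc["group"].to_numpy(),
        "mouse_id": cc["mouse_id"].to_numpy(),
        "x": cc["week"].astype(float).to_numpy(),
        "y": np.log10((cc["gfphi_dn3"].to_numpy(float) + c)
                      / cc["dn3"].to_numpy(float)),
    })
    out.attrs["offset"] = float(c)
    return out


# ---------------------------------------------------------------------------
# Variable-projection least squares
# ---------------------------------------------------------------------------

def _two_col_sse(r: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Profiled SSE for the single-group design ``[1, r**x]``, vectorized in r.

    Returns (sse, a, b) arrays matching ``r``.  Uses closed-form 2x2 normal
    equations; a degenerate design (``r**x`` constant) falls back to the
    intercept-only fit with b = 0.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    v = r[:, None] ** x[None, :]
    n = x.size
    sy = y.sum()
    syy = float(y @ y)
    sv = v.sum(axis=1)
    svv = (v * v).sum(axis=1)
    svy = v @ y
    det = n * svv - sv * sv
    ok = det > 1e-12 * n * np.maximum(svv, 1e-300)
    b = np.where(ok, (n * svy - sv * sy) / np.where(ok, det, 1.0), 0.0)
    a = (sy - b * sv) / n
    sse = np.maximum(syy - a * sy - b * svy, 0.0)
    return sse, a, b


def _fit_single_group(x: np.ndarray, y: np.ndarray):
    """Fit one group's (A, B, R) by 1-D profile over R."""
    sse_grid, _, _ = _two_col_sse(_R_GRID, x, y)
    i = int(np.argmin(sse_grid))
    lo = _R_GRID[max(i - 1, 0)]
    hi = _R_GRID[min(i + 1, _R_GRID.size - 1)]
    res = optimize.minimize_scalar(
        lambda r: _two_col_sse(r, x, y)[0][0],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    r = float(res.x)
    sse, a, b = _two_col_sse(r, x, y)
    return float(a[0]), float(b[0]), r, float(sse[0])


def _shared_design(r: float, x: np.ndarray, gidx: np.ndarray, n_groups: int,
                   structure: str) -> np.ndarray:
    v = r ** x
    if structure == "shared":
        return np.column_stack([np.ones_like(x), v])
    onehot = np.zeros((x.size, n_groups))
    onehot[np.arange(x.size), gidx] = 1.0
    if structure == "A":
        return np.column_stack([onehot, v])
    if structure == "AB":
        return np.column_stack([onehot, onehot * v[:, None]])
    raise ValueError(f"unknown structure {structure!r}")


def _fit_shared_r(x, y, gidx, n_groups, structure):
    def sse_of(r: float):
        design = _shared_design(r, x, gidx, n_groups, structure)
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), coef

    grid_sse = np.array([sse_of(r)[0] for r in _R_GRID])
    i = int(np.argmin(grid_sse))
    lo = _R_GRID[max(i - 1, 0)]
    hi = _R_GRID[min(i + 1, _R_GRID.size - 1)]
    res = optimize.minimize_scalar(lambda r: sse_of(r)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    r = float(res.x)
    sse, coef = sse_of(r)
    return r, coef, sse


@dataclass
class _ArrayFit:
    params: dict[int, tuple[float, float, float]]  # group index -> (A, B, R)
    fitted: np.ndarray
    sse: float
    flags: tuple[str, ...]


def _fit_arrays(x: np.ndarray, y: np.ndarray, gidx: np.ndarray,
                n_groups: int, structure: str) -> _ArrayFit:
    flags: list[str] = []
    params: dict[int, tuple[float, float, float]] = {}
    fitted = np.empty_like(y)

    if structure == "ABR":
        sse = 0.0
        for g in range(n_groups):
            m = gidx == g
            a, b, r, s = _fit_single_group(x[m], y[m])
            params[g] = (a, b, r)
            fitted[m] = a + b * r ** x[m]
            sse += s
    else:
        r, coef, sse = _fit_shared_r(x, y, gidx, n_groups, structure)
        if structure == "shared":
            a_g = [float(coef[0])] * n_groups
            b_g = [float(coef[1])] * n_groups
        elif structure == "A":
            a_g = [float(c) for c in coef[:n_groups]]
            b_g = [float(coef[n_groups])] * n_groups
        else:  # AB
            a_g = [float(c) for c in coef[:n_groups]]
            b_g = [float(c) for c in coef[n_groups:]]
        for g in range(n_groups):
            params[g] = (a_g[g], b_g[g], r)
            m = gidx == g
            fitted[m] = a_g[g] + b_g[g] * r ** x[m]

    for g, (a, b, r) in params.items():
        if r <= _R_EDGE or r >= 1.0 - _R_EDGE:
            flags.append(f"R_at_boundary:{g}")
        if abs(b) < _B_TINY * max(1.0, abs(a)):
            flags.append(f"R_non_identifiable:{g}")
    return _ArrayFit(params=params, fitted=fitted, sse=float(sse),
                     flags=tuple(sorted(set(flags))))


def _n_params(structure: str, n_groups: int) -> int:
    return {"shared": 3, "A": n_groups + 2, "AB": 2 * n_groups + 1,
            "ABR": 3 * n_groups}[structure]


# ---------------------------------------------------------------------------
# Public fit API
# ---------------------------------------------------------------------------

@dataclass
class ExpDecayFit:
    """Fitted exponential label-loss model ``Y = A + B * R**X`` per group."""

    structure: str
    group_names: tuple[str, ...]
    params: dict[str, tuple[float, float, float]]  # group -> (A, B, R)
    sse: float
    n_obs: int
    n_params: int
    adjusted_r2: float
    residuals: pd.DataFrame          # group, mouse_id, x, y, fitted, resid
    flags: tuple[str, ...] = ()
    comparison: pd.DataFrame | None = None
    offset: float | None = None

    def predict(self, group: str, x) -> np.ndarray:
        a, b, r = self.params[group]
        return a + b * r ** np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        d = {
            "structure": self.structure,
            "group_names": list(self.group_names),
            "params": {g: list(p) for g, p in self.params.items()},
            "sse": self.sse,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "adjusted_r2": self.adjusted_r2,
            "flags": list(self.flags),
            "offset": self.offset,
            "residuals": self.residuals.to_dict(orient="list"),
        }
        if self.comparison is not None:
            d["comparison"] = self.comparison.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExpDecayFit":
        comp = d.get("comparison")
        return cls(
            structure=d["structure"],
            group_names=tuple(d["group_names"]),
            params={g: tuple(p) for g, p in d["params"].items()},
            sse=float(d["sse"]), n_obs=int(d["n_obs"]),
            n_params=int(d["n_params"]),
            adjusted_r2=float(d["adjusted_r2"]),
            residuals=pd.DataFrame(d["residuals"]),
            flags=tuple(d.get("flags", ())),
            comparison=pd.DataFrame(comp) if comp is not None else None,
            offset=d.get("offset"),
        )


def _series_arrays(series: pd.DataFrame):
    groups = tuple(pd.unique(series["group"]))
    gmap = {g: i for i, g in enumerate(groups)}
    x = series["x"].to_numpy(float)
    y = series["y"].to_numpy(float)
    gidx = series["group"].map(gmap).to_numpy()
    return x, y, gidx, groups


def fit_exp_decay(series: pd.DataFrame, structure: str = "ABR") -> ExpDecayFit:
    """Least-squares fit of ``Y = A + B * R**X`` with the given group structure.

    ``structure`` names which parameters are group-specific: ``"shared"``
    (all common), ``"A"``, ``"AB"`` or ``"ABR"`` (all separate).  ``R`` is
    constrained to (0, 1); a fit pinned near either edge, or with ``B``
    indistinguishable from zero, is returned with a non-identifiability
    flag rather than rejected.
    """
    if structure not in STRUCTURE_ORDER:
        raise ValueError(f"structure must be one of {STRUCTURE_ORDER}")
    if series.empty:
        raise ValueError("empty series")
    x, y, gidx, groups = _series_arrays(series)
    for g, name in enumerate(groups):
        if np.unique(x[gidx == g]).size < 2:
            raise ValueError(
                f"group {name!r} needs at least 2 distinct chase times")
    p = _n_params(structure, len(groups))
    if x.size < p + 1:
        raise ValueError(
            f"need at least {p + 1} rows to fit {p} parameters, got {x.size}")

    af = _fit_arrays(x, y, gidx, len(groups), structure)
    resid = y - af.fitted
    sst = float(((y - y.mean()) ** 2).sum())
    n = x.size
    if sst > 0:
        adj = 1.0 - (af.sse / (n - p)) / (sst / (n - 1))
    else:
        adj = 1.0 if af.sse == 0 else -math.inf
    residuals = pd.DataFrame({
        "group": series["group"].to_numpy(),
        "mouse_id": series.get("mouse_id", pd.Series([""] * n)).to_numpy(),
        "x": x, "y": y, "fitted": af.fitted, "resid": resid,
    })
    return ExpDecayFit(
        structure=structure, group_names=groups,
        params={name: af.params[i] for i, name in enumerate(groups)},
        sse=af.sse, n_obs=n, n_params=p, adjusted_r2=float(adj),
        residuals=residuals, flags=af.flags,
        offset=series.attrs.get("offset"),
    )


def select_group_structure(series: pd.DataFrame) -> ExpDecayFit:
    """Fit the nested structure sequence and attach an F-test comparison table.

    Each enlargement (shared -> separate A -> separate A,B -> separate
    A,B,R) is scored with an extra-sum-of-squares F-test.  The returned fit
    always carries fully group-specific parameters: retaining separate
    nonlinear parameters even when the last test is not significant keeps
    the per-group reduction times well-defined.
    """
    groups = pd.unique(series["group"])
    if len(groups) < 2:
        raise ValueError("structure selection requires at least 2 groups")
    fits = {s: fit_exp_decay(series, s) for s in STRUCTURE_ORDER}
    n = fits["ABR"].n_obs
    rows = [{"structure": "shared", "n_params": fits["shared"].n_params,
             "sse": fits["shared"].sse, "step": "",
             "f_stat": np.nan, "df_num": np.nan, "df_den": np.nan,
             "p_value": np.nan}]
    for small, big in zip(STRUCTURE_ORDER[:-1], STRUCTURE_ORDER[1:]):
        fs, fb = fits[small], fits[big]
        df_num = fb.n_params - fs.n_params
        df_den = n - fb.n_params
        denom = fb.sse / df_den if df_den > 0 else np.nan
        if denom and denom > 0:
            f = (fs.sse - fb.sse) / df_num / denom
            p = float(stats.f.sf(f, df_num, df_den))
        else:
            f, p = np.nan, np.nan
        rows.append({"structure": big, "n_params": fb.n_params, "sse": fb.sse,
                     "step": f"{small}->{big}", "f_stat": f,
                     "df_num": df_num, "df_den": df_den, "p_value": p})
    final = fits["ABR"]
    final.comparison = pd.DataFrame(rows)
    return final


# ---------------------------------------------------------------------------
# Log-reduction times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionTimes:
    """Time (weeks) for the fitted curve to fall k logs below Y(0) per group."""

    k: float
    t_weeks: dict[str, float]
    asymptote_limited: tuple[str, ...]


def _t_k(b: float, r: float, k: float) -> float:
    # Solve A + B*R**t = (A + B) - k  =>  R**t = (B - k)/B.
    if b <= k:
        return math.inf
    return math.log((b - k) / b) / math.log(r)


def time_to_log_reduction(fit: ExpDecayFit, k: float) -> ReductionTimes:
    """Closed-form k-log reduction time per group.

    ``t_k = log((B - k)/B) / log(R)``; when the decaying amplitude ``B`` is
    at most ``k`` the curve never falls k logs below its starting level and
    the group is flagged asymptote-limited with ``t_k = +inf``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    times = {}
    limited = []
    for g, (a, b, r) in fit.params.items():
        t = _t_k(b, r, k)
        times[g] = t
        if not math.isfinite(t):
            limited.append(g)
    return ReductionTimes(k=float(k), t_weeks=times,
                          asymptote_limited=tuple(limited))


# ---------------------------------------------------------------------------
# Bootstrap inference on reduction-time differences
# ---------------------------------------------------------------------------

@dataclass
class ReductionTimeResult:
    """Residual-bootstrap inference on between-group reduction-time gaps.

    ``delta[k]`` is ``t_k(contrast[1]) - t_k(contrast[0])`` from the point
    fit; ``draws[k]`` holds the bootstrap distribution (infinite entries
    mark replicates whose refit was asymptote-limited for one group and are
    kept on the appropriate tail).
    """

    contrast: tuple[str, str]
    k_values: tuple[float, ...]
    n_boot: int
    seed: int
    scheme: str
    point_times: dict[float, dict[str, float]]
    delta: dict[float, float]
    ci: dict[float, tuple[float, float]]
    p_value: dict[float, float]
    draws: dict[float, np.ndarray] = field(repr=False, default_factory=dict)
    n_failed: int = 0


def _delta(t1: float, t2: float) -> float:
    # Both infinite: a tie on the far tail; score as zero so the replicate
    # counts against rejection on both sides.
    if math.isinf(t1) and math.isinf(t2):
        return 0.0
    return t2 - t1


def bootstrap_reduction_test(series: pd.DataFrame, fit: ExpDecayFit,
                             ks: Sequence[float] = (1.0, 2.0),
                             n_boot: int = 5000, seed: int = 0,
                             scheme: str = "within",
                             contrast: tuple[str, str] | None = None,
                             ) -> ReductionTimeResult:
    """Bootstrap of residuals for differences in k-log reduction times.

    Residuals from the fitted model are resampled with replacement (within
    group by default, or pooled with ``scheme="pooled"``), added back to the
    fitted values, and the model is refit with the same group structure;
    ``t_k`` is recomputed for each replicate.  The two-sided p-value is
    ``2 * min(P(delta* <= 0), P(delta* >= 0))`` floored at
    ``1 / (n_boot + 1)``; the confidence interval is percentile-based.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if scheme not in ("within", "pooled"):
        raise ValueError("scheme must be 'within' or 'pooled'")
    for k in ks:
        if k <= 0:
            raise ValueError("all k must be positive")
    x, y, gidx, groups = _series_arrays(series)
    if contrast is None:
        if len(groups) != 2:
            raise ValueError("specify contrast explicitly for != 2 groups")
        contrast = (groups[0], groups[1])
    for g in contrast:
        if g not in groups:
            raise ValueError(f"unknown contrast group {g!r}")
    gnum = {g: i for i, g in enumerate(groups)}
    i1, i2 = gnum[contrast[0]], gnum[contrast[1]]

    base = _fit_arrays(x, y, gidx, len(groups), fit.structure)
    fitted = base.fitted
    resid = y - fitted
    pools = [np.flatnonzero(gidx == g) for g in range(len(groups))]

    rng = np.random.default_rng(seed)
    ks = tuple(float(k) for k in ks)
    draws = {k: np.full(n_boot, np.nan) for k in ks}
    n_failed = 0
    e = np.empty_like(resid)
    for b in range(n_boot):
        if scheme == "within":
            for pos in pools:
                e[pos] = resid[pos[rng.integers(0, pos.size, pos.size)]]
        else:
            e[:] = resid[rng.integers(0, resid.size, resid.size)]
        try:
            rep = _fit_arrays(x, fitted + e, gidx, len(groups), fit.structure)
        except Exception:  # pragma: no cover - fit is robust by construction
            n_failed += 1
            continue
        for k in ks:
            t1 = _t_k(rep.params[i1][1], rep.params[i1][2], k)
            t2 = _t_k(rep.params[i2][1], rep.params[i2][2], k)
            draws[k][b] = _delta(t1, t2)
    if n_failed > n_boot // 2:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed; data too degenerate")

    point_times, delta, ci, pval = {}, {}, {}, {}
    for k in ks:
        tk = time_to_log_reduction(fit, k).t_weeks
        point_times[k] = tk
        delta[k] = _delta(tk[contrast[0]], tk[contrast[1]])
        d = draws[k][~np.isnan(draws[k])]
        le = float(np.mean(d <= 0))
        ge = float(np.mean(d >= 0))
        p = 2.0 * min(le, ge)
        pval[k] = min(1.0, max(p, 1.0 / (n_boot + 1)))
        # Nearest-rank percentiles: robust when draws include +/-inf
        # (asymptote-limited replicates).
        ci[k] = (float(np.percentile(d, 2.5, method="nearest")),
                 float(np.percentile(d, 97.5, method="nearest")))
        draws[k] = d
    return ReductionTimeResult(
        contrast=contrast, k_values=ks, n_boot=n_boot, seed=seed,
        scheme=scheme, point_times=point_times, delta=delta, ci=ci,
        p_value=pval, draws=draws, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Division-time estimation from fluorescence halving
# ---------------------------------------------------------------------------

@dataclass
class DivisionTimeEstimate:
    """Mean division time from label-fluorescence halving.

    ``per_mouse`` holds one row per mouse with the implied division count
    ``d = log2(mfi0 / mfi1)`` and ``T = (t1 - t0) / d`` hours; mice without
    a fluorescence decline are flagged and excluded from the group summary
    (mean ± SD across mice).
    """

    per_mouse: pd.DataFrame
    per_group: pd.DataFrame


def estimate_division_time(pairs: pd.DataFrame) -> DivisionTimeEstimate:
    """Estimate mean division times from per-mouse MFI at two chase times.

    ``pairs`` requires columns ``mouse_id, group, t0_h, mfi0, t1_h, mfi1``.
    Assumes mean fluorescence halves with each division, so the number of
    divisions over the interval is ``log2(mfi0 / mfi1)``.
    """
    req = {"mouse_id", "group", "t0_h", "mfi0", "t1_h", "mfi1"}
    missing = req - set(pairs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (pairs["t1_h"] <= pairs["t0_h"]).any():
        raise ValueError("t1_h must exceed t0_h for every mouse")
    if (pairs[["mfi0", "mfi1"]] <= 0).any().any():
        raise ValueError("MFI values must be positive")

    pm = pairs.copy()
    declining = pm["mfi1"] < pm["mfi0"]
    pm["divisions"] = np.where(
        declining, np.log2(pm["mfi0"] / pm["mfi1"]), np.nan)
    pm["division_time_h"] = np.where(
        declining, (pm["t1_h"] - pm["t0_h"]) / pm["divisions"], np.nan)
    pm["flagged_no_decline"] = ~declining
    n_flag = int((~declining).sum())
    if n_flag:
        logger.warning("%d mouse/mice without MFI decline excluded from the "
                       "division-time summary", n_flag)

    ok = pm[declining]
    per_group = (ok.groupby("group", observed=True)["division_time_h"]
                   .agg(mean_division_time_h="mean",
                        sd_division_time_h=lambda s: s.std(ddof=1),
                        n_mice="count")
                   .reset_index())
    return DivisionTimeEstimate(per_mouse=pm, per_group=per_group)


def mfi_pairs_from_events(events: pd.DataFrame, gates: GateSet,
                          t0_week: float, t1_week: float,
                          autofluorescence: float = 0.0) -> pd.DataFrame:
    """Build the MFI pair table for :func:`estimate_division_time`.

    For each group the reference ``mfi0`` is the pooled arithmetic mean GFP
    of non-neg events from all week-``t0_week`` mice (the design is
    cross-sectional, so no mouse is measured twice); each week-``t1_week``
    mouse contributes its own ``mfi1``.  A known autofluorescence floor can
    be subtracted from both means.
    """
    labeled, _ = classify_gfp(events, gates)
    labeled = labeled[labeled["gfp_class"] != "neg"]
    rows = []
    for group, gev in labeled.groupby("group", observed=True):
        ref = gev[gev["week"] == t0_week]
        tgt = gev[gev["week"] == t1_week]
        if ref.empty or tgt.empty:
            logger.warning("group %s lacks events at week %g or %g; skipped",
                           group, t0_week, t1_week)
            continue
        mfi0 = float(ref["gfp"].mean()) - autofluorescence
        for mouse_id, mev in tgt.groupby("mouse_id", observed=True):
            rows.append({
                "mouse_id": mouse_id, "group": group,
                "t0_h": t0_week * HOURS_PER_WEEK, "mfi0": mfi0,
                "t1_h": t1_week * HOURS_PER_WEEK,
                "mfi1": float(mev["gfp"].mean()) - autofluorescence,
            })
    out = pd.DataFrame(rows,
                       columns=["mouse_id", "group", "t0_h", "mfi0",
                                "t1_h", "mfi1"])
    if not out.empty and (out[["mfi0", "mfi1"]] <= 0).any().any():
        raise ValueError(
            "background subtraction produced non-positive MFI; lower "
            "autofluorescence or use a shorter chase interval")
    return out
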
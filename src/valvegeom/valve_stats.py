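"""Per-pressure statistics of the gQOIs.

Replicates the study-level statistical layer for valves each fixed at a
single transvalvular pressure (TVP): mean ± s.e.m per TVP (design
n = 3, 5, 3 at 10/20/30 mmHg), ordinary least-squares regression of each
normalized gQOI against TVP with a two-sided t-test on the slope, a
degenerate constant model (slope ≡ 0) for quantities whose pressure trend is
below measurement error (normalized thickness w̄ and tilt angle β), pooling
of the left and right leaflets (each valve contributes both values), and the
derived quantities: anterior / left&right size ratios and the relative
perimeter change between pressures.

``MURINE_PV_REFERENCE`` carries published summary morphometry of 1-year-old
C57BL/6J murine pulmonary valves (per-TVP means ± s.e.m of the normalized
gQOIs and of the valve perimeter), used as reference input for the derived
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "GQOITable",
    "MURINE_PV_REFERENCE",
    "REFERENCE_N_PER_TVP",
    "group_mean_sem",
    "fit_linear_vs_tvp",
    "fit_constant",
    "build_table1",
    "reference_table",
    "anterior_ratio",
    "perimeter_change",
    "valve_thickness_um",
]

TVPS = (10.0, 20.0, 30.0)
REFERENCE_N_PER_TVP = {10.0: 3, 20.0: 5, 30.0: 3}

#: Published per-TVP reference means ± s.e.m (normalized gQOIs; perimeter in
#: µm; w̄ tabulated ×10²).  Keys: row id -> {tvp: (mean, sem)}.
MURINE_PV_REFERENCE = {
    "fe_anterior":   {10.0: (0.29, 0.02), 20.0: (0.31, 0.01), 30.0: (0.30, 0.01)},
    "fe_left_right": {10.0: (0.36, 0.01), 20.0: (0.35, 0.01), 30.0: (0.32, 0.01)},
    "ba_anterior":   {10.0: (0.41, 0.01), 20.0: (0.41, 0.01), 30.0: (0.41, 0.01)},
    "ba_left_right": {10.0: (0.49, 0.01), 20.0: (0.47, 0.01), 30.0: (0.46, 0.01)},
    "height":        {10.0: (0.14, 0.00), 20.0: (0.13, 0.00), 30.0: (0.13, 0.00)},
    "thickness_x100": {10.0: (0.42, 0.04), 20.0: (0.36, 0.02), 30.0: (0.42, 0.04)},
    "beta_deg":      {10.0: (11.0, 2.0), 20.0: (10.0, 2.0), 30.0: (11.0, 1.0)},
    "l_gamma_um":    {10.0: (4646.0, 20.0), 20.0: (5206.0, 67.0), 30.0: (5219.0, 206.0)},
}

#: default regression model per table row
DEFAULT_MODEL_MAP = {
    "fe_anterior": "linear", "fe_left_right": "linear",
    "ba_anterior": "linear", "ba_left_right": "linear",
    "height": "linear", "l_gamma_um": "linear",
    "thickness_x100": "constant", "beta_deg": "constant",
}


@dataclass
class RegressionResult:
    """OLS (or degenerate constant) fit of one gQOI against TVP."""

    model: str                      # "linear" | "constant"
    intercept: float
    intercept_sem: float
    slope: float | None = None      # per mmHg; None for the constant model
    slope_sem: float | None = None
    p_value: float | None = None    # H0: slope = 0; None when not applicable
    n_points: int = 0


@dataclass
class GQOITable:
    """Summary table: per-TVP mean ± s.e.m and a regression fit per row.

    ``rows`` maps row id -> {"per_tvp": {tvp: (mean, sem, n)},
    "regression": RegressionResult}.  Left and right leaflets are pooled
    into a single group.
    """

    rows: dict = field(default_factory=dict)
    n_per_tvp: dict = field(default_factory=dict)

    def mean(self, row: str, tvp: float) -> float:
        return self.rows[row]["per_tvp"][float(tvp)][0]

    def to_frame(self, report_precision: bool = False) -> pd.DataFrame:
        """Machine-precision (default) or report-rounded tabular view.

        Report rounding follows the printed convention: 2 d.p. for
        normalized quantities and p-values, integers for µm and degrees;
        slopes are tabulated ×10² except for the perimeter row.
        """
        recs = []
        for row, data in self.rows.items():
            reg = data["regression"]
            dimensional = row in ("l_gamma_um", "beta_deg")
            slope_factor = 1.0 if row == "l_gamma_um" else 100.0
            rec = {"gqoi": row, "model": reg.model,
                   "intercept": reg.intercept, "intercept_sem": reg.intercept_sem,
                   "slope_x100" if slope_factor == 100.0 else "slope":
                       (np.nan if reg.slope is None else reg.slope * slope_factor),
                   "p_value": np.nan if reg.p_value is None else reg.p_value,
                   "n_points": reg.n_points}
            for tvp, (m, s, n) in data["per_tvp"].items():
                rec[f"mean_{int(tvp)}mmHg"] = m
                rec[f"sem_{int(tvp)}mmHg"] = s
            if report_precision:
                nd = 0 if dimensional else 2
                for k, v in rec.items():
                    if isinstance(v, float) and not np.isnan(v):
                        rec[k] = round(v, nd) if k.startswith(("mean", "sem", "inter")) \
                            else round(v, 2)
            recs.append(rec)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def group_mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd / √n, n−1 denominator)."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least two values for mean ± s.e.m")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def fit_linear_vs_tvp(points, weights=None) -> RegressionResult:
    """OLS fit value = a + b·TVP over individual (tvp, value) points.

    Standard errors come from the usual OLS variance estimator; the p-value
    is the two-sided t-test of H0: b = 0 with n−2 degrees of freedom.
    Optional ``weights`` give a weighted fit (used when regressing on
    per-TVP means with group sizes as weights; the slope then equals the
    all-points OLS slope exactly).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (tvp, value) points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 2:
        raise ValueError("all TVPs identical: regression design is degenerate")
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    dof = len(x) - 2
    s2 = (w * resid ** 2).sum() / dof
    slope_sem = float(np.sqrt(s2 / sxx))
    intercept_sem = float(np.sqrt(s2 * (1.0 / sw + xbar ** 2 / sxx)))
    if slope_sem > 0:
        tstat = slope / slope_sem
        p = float(2 * sps.t.sf(abs(tstat), dof))
    else:
        p = 0.0 if slope != 0 else 1.0
    return RegressionResult(model="linear", intercept=float(intercept),
                            intercept_sem=intercept_sem, slope=float(slope),
                            slope_sem=slope_sem, p_value=p, n_points=len(x))


def fit_constant(points, weights=None) -> RegressionResult:
    """Degenerate regression with zero slope: the intercept is the grand
    mean over all individual points; no slope test applies."""
    pts = np.asarray(points, float)
    if pts.ndim == 2:
        y = pts[:, 1]
    else:
        y = pts
    if len(y) < 2:
        raise ValueError("need at least two points")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    mean = float((w * y).sum() / w.sum())
    resid = y - mean
    sem = float(np.sqrt((w * resid ** 2).sum() / (len(y) - 1) / w.sum()))
    return RegressionResult(model="constant", intercept=mean,
                            intercept_sem=sem, n_points=len(y))


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def _row_values(records, row: str):
    """(tvp, value) pairs for one table row; pooled rows yield two entries
    per valve (left and right are separate points, not averaged)."""
    out = []
    for r in records:
        if row == "fe_anterior":
            vals = [r.l_fe_norm["anterior"]]
        elif row == "fe_left_right":
            vals = [r.l_fe_norm["left"], r.l_fe_norm["right"]]
        elif row == "ba_anterior":
            vals = [r.l_ba_norm["anterior"]]
        elif row == "ba_left_right":
            vals = [r.l_ba_norm["left"], r.l_ba_norm["right"]]
        elif row == "height":
            vals = [r.height_norm]
        elif row == "thickness_x100":
            vals = [100.0 * r.thickness_norm]
        elif row == "beta_deg":
            vals = [r.beta]
        elif row == "l_gamma_um":
            vals = [r.l_gamma]
        else:
            raise KeyError(row)
        out.extend((float(r.tvp), v) for v in vals)
    return np.array(sorted(out))


def build_table1(records, model_map: dict | None = None) -> GQOITable:
    """Assemble the summary table from per-valve gQOI records.

    Left and right leaflets are pooled; the linear model is applied to the
    normalized lengths, height and the perimeter, the constant model to the
    normalized thickness and the tilt angle (overridable via ``model_map``).
    The output is permutation-invariant in the record order.
    """
    model_map = dict(DEFAULT_MODEL_MAP, **(model_map or {}))
    tvps = sorted({float(r.tvp) for r in records})
    if len(tvps) < 2:
        raise ValueError("records must cover at least two TVPs")
    table = GQOITable(n_per_tvp={t: sum(1 for r in records if float(r.tvp) == t)
                                 for t in tvps})
    for row, model in model_map.items():
        pts = _row_values(records, row)
        per_tvp = {}
        for t in tvps:
            vals = pts[pts[:, 0] == t][:, 1]
            if len(vals) < 2:
                raise ValueError(f"row '{row}' needs >= 2 values at {t} mmHg")
            m, s = group_mean_sem(vals)
            per_tvp[t] = (m, s, len(vals))
        reg = fit_linear_vs_tvp(pts) if model == "linear" else fit_constant(pts)
        table.rows[row] = {"per_tvp": per_tvp, "regression": reg}
    return table


def reference_table() -> GQOITable:
    """Summary table built from the published per-TVP reference means,
    regressing on the means weighted by the published group sizes."""
    table = GQOITable(n_per_tvp=dict(REFERENCE_N_PER_TVP))
    for row, model in DEFAULT_MODEL_MAP.items():
        per = MURINE_PV_REFERENCE[row]
        per_tvp = {t: (m, s, REFERENCE_N_PER_TVP[t]) for t, (m, s) in per.items()}
        pts = np.array([(t, per[t][0]) for t in sorted(per)])
        w = np.array([REFERENCE_N_PER_TVP[t] for t in sorted(per)], float)
        reg = fit_linear_vs_tvp(pts, weights=w) if model == "linear" \
            else fit_constant(pts, weights=w)
        table.rows[row] = {"per_tvp": per_tvp, "regression": reg}
    return table


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def anterior_ratio(table: GQOITable, quantity: str, tvp: float,
                   ndigits: int = 2) -> float:
    """Anterior / pooled left&right mean ratio of the free-edge or basal
    length at one TVP, rounded for report output."""
    row_a = {"free_edge": "fe_anterior", "basal": "ba_anterior"}[quantity]
    row_lr = {"free_edge": "fe_left_right", "basal": "ba_left_right"}[quantity]
    denom = table.mean(row_lr, tvp)
    if denom == 0:
        raise ZeroDivisionError("left&right mean is zero")
    return round(table.mean(row_a, tvp) / denom, ndigits)


def valve_thickness_um(table: GQOITable) -> float:
    """Dimensional valve-average leaflet thickness: the constant-model
    normalized thickness (tabulated ×10²) times the group-size-weighted mean
    perimeter length."""
    wbar = table.rows["thickness_x100"]["regression"].intercept / 100.0
    per = table.rows["l_gamma_um"]["per_tvp"]
    n = np.array([v[2] for v in per.values()], float)
    means = np.array([v[0] for v in per.values()])
    return float(wbar * (n @ means) / n.sum())


def perimeter_change(table: GQOITable, tvp_from: float, tvp_to: float) -> float:
    """Relative change of the valve perimeter mean between two TVPs, in %."""
    base = table.mean("l_gamma_um", tvp_from)
    if base == 0:
        raise ZeroDivisionError("baseline perimeter is zero")
    return 100.0 * (table.mean("l_gamma_um", tvp_to) - base) / base
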
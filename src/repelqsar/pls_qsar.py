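"""PLS regression of log-activity on the atom-descriptor matrix.

The activity is modeled as ``log10(MED)`` (lower = more repellent).
Descriptor columns are autoscaled (zero-variance columns dropped) and a
NIPALS PLS1 model with *k* latent factors is fitted.  Model selection uses
the factor-dynamics table: training R² and repeated leave-many-out Q² for
``k = 1..k_max``, with the selected *k* the smallest one whose Q² is within
tolerance of the maximum.  Interpretation uses the field-contribution map:
per (supergraph position, field) the standardized coefficient, sign-flipped
into "activity" orientation (positive = increases repellency) and
normalized to unit total absolute impact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .atomic_fields import FIELD_NAMES, VACANCY_VALUES, AtomicFieldVector
from .dataset_io import ActivityVector
from .molgraph import MolecularGraph
from .supergraph import Supergraph, AtomMapping, descriptor_matrix, embed

__all__ = [
    "PLSModel",
    "FactorDynamics",
    "ContributionMap",
    "PredictionResult",
    "fit_pls",
    "crossval_q2",
    "factor_dynamics",
    "predict",
    "field_contributions",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


def _nipals_coefficients(Xs: np.ndarray, yc: np.ndarray, k: int) -> np.ndarray:
    """NIPALS PLS1 on autoscaled X / centered y.

    Returns an array ``B`` of shape (k, p): ``B[a-1]`` are the regression
    coefficients (in the scaled column space) of the *a*-factor model, so
    one deflation pass yields the whole nested family.
    """
    n, p = Xs.shape
    Xr = Xs.copy()
    yr = yc.copy()
    W, P, Q = [], [], []
    for _ in range(k):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w = w / nw
        t = Xr @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p_load = Xr.T @ t / tt
        q = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p_load)
        yr = yr - q * t
        W.append(w)
        P.append(p_load)
        Q.append(q)
    a_eff = len(W)
    Wm = np.array(W).T  # p x a
    Pm = np.array(P).T
    Qv = np.array(Q)
    B = np.zeros((k, p))
    for a in range(1, a_eff + 1):
        Ba = Wm[:, :a] @ np.linalg.solve(Pm[:, :a].T @ Wm[:, :a], Qv[:a])
        B[a - 1] = Ba
    for a in range(a_eff, k):
        B[a] = B[a_eff - 1] if a_eff else 0.0
    return B


@dataclass
class PLSModel:
    """Fitted latent-factor regression of log-activity."""

    n_factors: int
    column_names: Tuple[str, ...]  # kept (non-constant) columns
    means: np.ndarray
    scales: np.ndarray
    coef_scaled: np.ndarray  # coefficients in autoscaled column space
    y_mean: float
    fitted: pd.Series = field(repr=False, default=None)
    r2: float = float("nan")
    fields: Tuple[str, ...] = FIELD_NAMES
    all_columns: Tuple[str, ...] = ()

    def predict_rows(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted log-activity for rows of a full descriptor matrix."""
        Xk = X[list(self.column_names)].to_numpy(dtype=float)
        Xs = (Xk - self.means) / self.scales
        return Xs @ self.coef_scaled + self.y_mean

    @property
    def coef_original(self) -> np.ndarray:
        """Coefficients on the original (unscaled) descriptor columns."""
        return self.coef_scaled / self.scales

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_factors": self.n_factors,
                "column_names": list(self.column_names),
                "means": self.means.tolist(),
                "scales": self.scales.tolist(),
                "coef_scaled": self.coef_scaled.tolist(),
                "y_mean": self.y_mean,
                "r2": self.r2,
                "fields": list(self.fields),
                "all_columns": list(self.all_columns),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        return cls(
            n_factors=d["n_factors"],
            column_names=tuple(d["column_names"]),
            means=np.array(d["means"]),
            scales=np.array(d["scales"]),
            coef_scaled=np.array(d["coef_scaled"]),
            y_mean=d["y_mean"],
            r2=d["r2"],
            fields=tuple(d["fields"]),
            all_columns=tuple(d["all_columns"]),
        )


def _align(X: pd.DataFrame, y: ActivityVector) -> Tuple[pd.DataFrame, np.ndarray]:
    if set(y.ids) - set(X.index):
        missing = sorted(set(y.ids) - set(X.index))
        raise ValueError(f"activity ids missing from descriptor matrix: {missing}")
    return X.loc[list(y.ids)], np.asarray(y.values, dtype=float)


def _autoscale(Xk: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = Xk.mean(axis=0)
    scales = Xk.std(axis=0, ddof=1)
    return (Xk - means) / scales, means, scales


def fit_pls(X: pd.DataFrame, y: ActivityVector, k: int) -> PLSModel:
    """Fit a *k*-factor NIPALS PLS1 model of log-activity.

    Columns are autoscaled to zero mean / unit variance; constant columns
    are dropped (logged).  ``k`` is capped at ``min(n_samples - 1,
    n_kept_columns)`` with a warning.  The fit is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Xa, yv = _align(X, y)
    arr = Xa.to_numpy(dtype=float)
    keep = arr.std(axis=0, ddof=1) > _EPS
    if (~keep).any():
        log.debug("dropping %d constant descriptor columns", int((~keep).sum()))
    cols = tuple(np.asarray(Xa.columns)[keep])
    Xk = arr[:, keep]
    k_max = min(len(yv) - 1, Xk.shape[1])
    if k > k_max:
        log.warning("k=%d exceeds usable rank; capped to %d", k, k_max)
        k = k_max
    Xs, means, scales = _autoscale(Xk)
    yc = yv - yv.mean()
    B = _nipals_coefficients(Xs, yc, k)
    model = PLSModel(
        n_factors=k,
        column_names=cols,
        means=means,
        scales=scales,
        coef_scaled=B[k - 1],
        y_mean=float(yv.mean()),
        all_columns=tuple(X.columns),
    )
    fitted = model.predict_rows(Xa)
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    model.r2 = 1.0 - ss_res / ss_tot
    model.fitted = pd.Series(fitted, index=Xa.index)
    return model


def _cv_press_per_k(
    Xa: pd.DataFrame,
    yv: np.ndarray,
    k: int,
    leave_fraction: float,
    n_repeats: int,
    seed: int,
) -> np.ndarray:
    """Mean Q² per factor count (1..k) over repeated random partitions."""
    n = len(yv)
    m = max(1, int(round(leave_fraction * n)))
    arr = Xa.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    q2 = np.zeros((n_repeats, k))
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        press = np.zeros(k)
        for start in range(0, n, m):
            test = perm[start:start + m]
            train = np.setdiff1d(perm, test)
            if len(train) < 2:
                raise ValueError("cross-validation fold has < 2 training samples")
            Xt = arr[train]
            keep = Xt.std(axis=0, ddof=1) > _EPS
            Xs, means, scales = _autoscale(Xt[:, keep])
            yt = yv[train]
            yc = yt - yt.mean()
            kk = min(k, len(train) - 1, int(keep.sum()))
            B = _nipals_coefficients(Xs, yc, kk)
            Xv = (arr[np.ix_(test, np.flatnonzero(keep))] - means) / scales
            for a in range(k):
                pred = Xv @ B[min(a, kk - 1)] + yt.mean()
                press[a] += float(((yv[test] - pred) ** 2).sum())
        q2[rep] = 1.0 - press / ss_tot
    return q2.mean(axis=0)


def crossval_q2(
    X: pd.DataFrame,
    y: ActivityVector,
    k: int,
    leave_fraction: float = 0.1,
    n_repeats: int = 25,
    seed: int = 7,
) -> float:
    """Leave-many-out Q² = 1 − PRESS/TSS, averaged over random partitions.

    Each repeat partitions the samples into disjoint folds of
    ``round(leave_fraction * n)`` so every sample is predicted
    out-of-fold exactly once per repeat.  Reproducible given ``seed``.
    """
    if not 0 < leave_fraction < 0.5:
        raise ValueError("leave_fraction must be in (0, 0.5)")
    Xa, yv = _align(X, y)
    return float(
        _cv_press_per_k(Xa, yv, k, leave_fraction, n_repeats, seed)[k - 1]
    )


@dataclass
class FactorDynamics:
    """R²/Q² as a function of the number of latent factors."""

    table: pd.DataFrame  # columns: k, r, R2, Q2
    selected_k: int
    q2_tolerance: float


def factor_dynamics(
    X: pd.DataFrame,
    y: ActivityVector,
    k_max: int = 10,
    leave_fraction: float = 0.1,
    n_repeats: int = 25,
    seed: int = 7,
    q2_tolerance: float = 0.01,
) -> FactorDynamics:
    """Factor-dynamics table and minimum-k-at-max-Q² model selection.

    The selected factor count is the smallest *k* whose Q² is within
    ``q2_tolerance`` of the maximum over ``1..k_max`` — the smallest
    model statistically indistinguishable from the best one.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    Xa, yv = _align(X, y)
    arr = Xa.to_numpy(dtype=float)
    keep = arr.std(axis=0, ddof=1) > _EPS
    k_max_eff = min(k_max, len(yv) - 1, int(keep.sum()))
    Xs, _, _ = _autoscale(arr[:, keep])
    yc = yv - yv.mean()
    B = _nipals_coefficients(Xs, yc, k_max_eff)
    ss_tot = float((yc**2).sum())
    rows = []
    q2s = _cv_press_per_k(Xa, yv, k_max_eff, leave_fraction, n_repeats, seed)
    for a in range(1, k_max_eff + 1):
        fitted = Xs @ B[a - 1]
        r2 = 1.0 - float(((yc - fitted) ** 2).sum()) / ss_tot
        r = float(np.corrcoef(fitted, yc)[0, 1]) if fitted.std() > 0 else 0.0
        rows.append({"k": a, "r": r, "R2": r2, "Q2": q2s[a - 1]})
    tab = pd.DataFrame(rows)
    best = tab["Q2"].max()
    selected = int(tab.loc[tab["Q2"] >= best - q2_tolerance, "k"].iloc[0])
    return FactorDynamics(table=tab, selected_k=selected, q2_tolerance=q2_tolerance)


@dataclass
class PredictionResult:
    compound_id: str
    med: float  # original dosage scale
    log10_med: float
    out_of_msg_fraction: float
    in_domain: bool


def predict(
    model: PLSModel,
    sg: Supergraph,
    graph: MolecularGraph,
    field_vector: AtomicFieldVector,
    domain_floor: float = 0.5,
    fields: Optional[Tuple[str, ...]] = None,
) -> PredictionResult:
    """Predict the MED of a new molecule via frozen-MSG superposition.

    The molecule is embedded into the MSG without extending it; atoms
    that find no position are counted into the out-of-MSG fraction (an
    applicability diagnostic) and contribute nothing to the descriptor
    row.  A fraction above ``1 - domain_floor`` triggers an
    outside-model-domain warning, but the prediction is still returned.
    """
    fields = fields or model.fields
    mapping = embed(sg, graph)
    row, _ = descriptor_matrix(
        sg,
        [AtomMapping(compound_id=graph.id, atom_to_vertex=mapping.atom_to_vertex)],
        {graph.id: field_vector},
        fields=fields,
    )
    out_frac = 1.0 - len(mapping.atom_to_vertex) / graph.n_atoms
    in_domain = (1.0 - out_frac) >= domain_floor
    if not in_domain:
        log.warning(
            "%s: %.0f%% of atoms outside the supergraph; prediction is outside "
            "the model domain", graph.id, 100 * out_frac,
        )
    log_med = float(model.predict_rows(row)[0])
    return PredictionResult(
        compound_id=graph.id,
        med=float(10.0 ** min(log_med, 300.0)),  # antilog, overflow-safe
        log10_med=log_med,
        out_of_msg_fraction=out_frac,
        in_domain=in_domain,
    )


@dataclass
class ContributionMap:
    """Signed normalized impacts per (MSG position, field).

    Positive impact means increasing the descriptor value increases the
    *activity* (i.e. lowers the MED); the published color convention
    paints those positions red and negative ones blue.
    """

    table: pd.DataFrame  # columns: vertex, field, impact

    def total_abs(self) -> float:
        return float(self.table["impact"].abs().sum())

    def impact(self, vertex: int, field_name: str) -> float:
        sel = self.table[
            (self.table["vertex"] == vertex) & (self.table["field"] == field_name)
        ]
        return float(sel["impact"].iloc[0]) if len(sel) else 0.0

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def field_contributions(model: PLSModel, sg: Supergraph) -> ContributionMap:
    """Field-contribution map of a fitted model.

    The raw impact of a column is its regression coefficient times the
    column standard deviation (= the coefficient on the autoscaled
    column).  Because the model regresses log10 MED while the map is
    read in activity orientation, the sign is flipped; impacts are then
    normalized to unit total absolute impact (an all-zero coefficient
    vector yields an all-zero map).
    """
    raw = {c: -b for c, b in zip(model.column_names, model.coef_scaled)}
    rows = []
    for col in model.all_columns or model.column_names:
        v_str, fld = col.split("|")
        rows.append(
            {"vertex": int(v_str[1:]), "field": fld, "impact": raw.get(col, 0.0)}
        )
    tab = pd.DataFrame(rows)
    total = tab["impact"].abs().sum()
    if total > _EPS:
        tab["impact"] = tab["impact"] / total
    else:
        tab["impact"] = 0.0
    return ContributionMap(table=tab)
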
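"""Penalized-regression sensitivity analysis over the candidate space.

Complementing the stepwise engine, an adaptive lasso (weighted L1
penalty, weights from a pilot ridge estimator) selects the second-order
terms, and a debiased least-squares refit on the selected support
supplies the working coefficients.  Every four-drug candidate is then
scored by predicted viability; selection proceeds through a one-sided
95% computed confidence interval (CCI) anchored at the best candidate:
all candidates whose criterion (predicted therapeutic window, or
predicted cancer viability when no non-cancer screen exists) falls on
the favorable side of the bound are declared statistically
undistinguishable from the best.  The selected set is summarized as a
drug network (node weight = presence fraction, edge weight = pair
presence fraction) and a per-drug dose-level split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, RidgeCV
from sklearn.model_selection import KFold

from .design import CandidateCombination
from .screen_regression import (
    ScreenDataset,
    SecondOrderModel,
    fit_second_order,
    model_matrix,
    second_order_terms,
)

__all__ = [
    "AdaptiveLassoModel",
    "CCISelection",
    "NetworkSummary",
    "UnknownDrugError",
    "fit_adaptive_lasso",
    "predict_candidates",
    "cci_select",
    "summarize_network",
    "ranking_frame",
]

log = logging.getLogger(__name__)

_WEIGHT_CAP = 1e8  # adaptive weight for a pilot coefficient of ~0
_SUPPORT_TOL = 1e-8


class UnknownDrugError(KeyError):
    """A candidate names a drug absent from the fitted model's panel."""


@dataclass
class AdaptiveLassoModel:
    """Adaptive-lasso support with a debiased OLS refit on that support.

    ``weights`` are the per-term penalty weights 1/|pilot|^gamma, ``lambda_``
    the cross-validated penalty, and ``refit`` the least-squares model on
    the selected terms (which supplies predictions, SEs and sigma2).
    """

    support: tuple[str, ...]
    weights: dict[str, float]
    lambda_: float
    gamma: float
    pilot: str
    refit: SecondOrderModel
    seed: int

    @property
    def model_id(self) -> str:
        return self.refit.model_id

    @property
    def drug_names(self) -> tuple[str, ...]:
        return self.refit.drug_names

    @property
    def sigma2(self) -> float:
        return self.refit.sigma2

    @property
    def coef(self) -> dict[str, float]:
        return self.refit.coef

    @property
    def beta0(self) -> float:
        return self.refit.beta0

    def predict_candidate(self, cand: CandidateCombination) -> float:
        try:
            return self.refit.predict_candidate(cand)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise UnknownDrugError(str(exc)) from exc


def fit_adaptive_lasso(
    data: ScreenDataset, gamma: float = 1.0, seed: int = 0, n_folds: int = 10
) -> AdaptiveLassoModel:
    """Adaptive lasso on the full second-order basis of the screen design.

    Pilot ridge (leave-one-out generalized cross-validation) gives weights
    w_j = 1/|β̂_pilot,j|^gamma; the weighted lasso is solved by feature
    rescaling with the penalty chosen by ``n_folds``-fold cross-validation
    on a seeded fold split; the selected support is refit by OLS.
    """
    names = data.design.panel.names
    terms = second_order_terms(names)
    coded, y = data.observations()
    X = model_matrix(coded, names, terms)

    if float(np.var(y)) < 1e-12:
        log.info("fit_adaptive_lasso: constant response; intercept-only model")
        refit = fit_second_order(data, ())
        return AdaptiveLassoModel(
            support=(),
            weights={t: _WEIGHT_CAP for t in terms},
            lambda_=np.inf,
            gamma=gamma,
            pilot="ridge (LOO-GCV)",
            refit=refit,
            seed=seed,
        )

    pilot = RidgeCV(alphas=np.logspace(-4, 4, 41), fit_intercept=True)
    pilot.fit(X, y)
    w = 1.0 / np.maximum(np.abs(pilot.coef_), 1.0 / _WEIGHT_CAP) ** gamma
    w = np.minimum(w, _WEIGHT_CAP)

    Z = X / w  # lasso coef b_j on Z maps back as beta_j = b_j / w_j
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv = LassoCV(
            alphas=100, cv=folds, fit_intercept=True, max_iter=50000, tol=1e-6
        )
        cv.fit(Z, y)
    beta = cv.coef_ / w
    support = tuple(t for t, b in zip(terms, beta) if abs(b) > _SUPPORT_TOL)
    refit = fit_second_order(data, support)
    return AdaptiveLassoModel(
        support=support,
        weights=dict(zip(terms, w.tolist())),
        lambda_=float(cv.alpha_),
        gamma=gamma,
        pilot="ridge (LOO-GCV)",
        refit=refit,
        seed=seed,
    )


def predict_candidates(
    model_cancer: AdaptiveLassoModel | SecondOrderModel,
    model_noncancer: AdaptiveLassoModel | SecondOrderModel | None,
    candidates: Sequence[CandidateCombination],
) -> list[CandidateCombination]:
    """Fill predicted viabilities (and PTW when a non-cancer model exists)."""
    known = set(model_cancer.drug_names)
    for cand in candidates:
        unknown = set(cand.members) - known
        if unknown:
            raise UnknownDrugError(
                f"candidate drugs {sorted(unknown)} absent from the fitted model"
            )
        cand.pred_cancer_viability = model_cancer.predict_candidate(cand)
        if model_noncancer is not None:
            cand.pred_healthy_viability = model_noncancer.predict_candidate(cand)
            cand.ptw = cand.pred_healthy_viability - cand.pred_cancer_viability
    return list(candidates)


Mode = Literal["max_ptw", "min_cancer_viability"]


@dataclass
class CCISelection:
    """One-sided 95% selection of candidates undistinguishable from the best."""

    mode: Mode
    best: CandidateCombination
    best_value: float
    se_best: float
    bound: float
    selected: list[CandidateCombination]
    alpha: float
    n_boot: int
    seed: int


def _criterion(cand: CandidateCombination, mode: Mode) -> float:
    if mode == "max_ptw":
        if cand.ptw is None:
            raise ValueError("candidates carry no PTW; was a non-cancer model given?")
        return cand.ptw
    if cand.pred_cancer_viability is None:
        raise ValueError("candidates carry no predicted cancer viability")
    return cand.pred_cancer_viability


def _bootstrap_se(
    model: AdaptiveLassoModel | SecondOrderModel,
    cand: CandidateCombination,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Residual-bootstrap draws of the candidate's predicted viability.

    The selected support is held fixed: each resample refits the OLS on
    the support with y* = fitted + resampled residuals and re-predicts.
    """
    refit = model.refit if isinstance(model, AdaptiveLassoModel) else model
    if refit.data is None:
        raise ValueError("model carries no dataset for bootstrapping")
    names = refit.drug_names
    coded, y = refit.data.observations()
    X = np.column_stack([np.ones(len(y)), model_matrix(coded, names, refit.terms)])
    beta = np.concatenate([[refit.beta0], [refit.coef[t] for t in refit.terms]])
    fitted = X @ beta
    resid = y - fitted
    x0 = np.concatenate(
        [[1.0], model_matrix((cand.coded_row(names) - 1.0)[None, :], names, refit.terms)[0]]
    )
    h = x0 @ np.linalg.pinv(X)  # prediction functional of y
    idx = rng.integers(0, len(y), size=(n_boot, len(y)))
    return float(h @ fitted) + resid[idx] @ h


def cci_select(
    filled: Sequence[CandidateCombination],
    mode: Mode,
    model_cancer: AdaptiveLassoModel | SecondOrderModel,
    model_noncancer: AdaptiveLassoModel | SecondOrderModel | None = None,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    use_t: bool = False,
) -> CCISelection:
    """Select all candidates on the favorable side of the one-sided bound.

    The best candidate's criterion (highest PTW, or lowest predicted
    cancer viability) gets a residual-bootstrap SE; the bound is
    best ∓ z_{1−alpha}·se.  With se = 0 the interval degenerates to exact
    ties with the best.
    """
    if not filled:
        raise ValueError("empty candidate list")
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} < 100: bootstrap SE will be unstable")
    crit = np.array([_criterion(c, mode) for c in filled])
    if mode == "max_ptw":
        i_best = int(np.argmax(crit))
    else:
        i_best = int(np.argmin(crit))
    best = filled[i_best]
    best_value = float(crit[i_best])

    rng = np.random.default_rng(seed)
    draws_c = _bootstrap_se(model_cancer, best, n_boot, rng)
    if mode == "max_ptw":
        if model_noncancer is None:
            raise ValueError("max_ptw mode needs a non-cancer model")
        draws_n = _bootstrap_se(model_noncancer, best, n_boot, rng)
        draws = draws_n - draws_c
    else:
        draws = draws_c
    se_best = float(np.std(draws, ddof=1))
    if se_best <= 1e-10 * max(1.0, abs(best_value)):  # numerically exact fit
        se_best = 0.0

    if use_t:
        refit = model_cancer.refit if isinstance(model_cancer, AdaptiveLassoModel) else model_cancer
        q = float(stats.t.ppf(1.0 - alpha, refit.df_resid))
    else:
        q = float(stats.norm.ppf(1.0 - alpha))

    if se_best == 0.0:
        selected = [c for c, v in zip(filled, crit) if v == best_value]
        bound = best_value
    elif mode == "max_ptw":
        bound = best_value - q * se_best
        selected = [c for c, v in zip(filled, crit) if v >= bound]
    else:
        bound = best_value + q * se_best
        selected = [c for c, v in zip(filled, crit) if v <= bound]
    return CCISelection(
        mode=mode,
        best=best,
        best_value=best_value,
        se_best=se_best,
        bound=float(bound),
        selected=selected,
        alpha=alpha,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass
class NetworkSummary:
    """Drug-presence summary of the selected (in-CCI) combinations."""

    node_weight: dict[str, float]
    edge_weight: dict[tuple[str, str], float]
    level_split: dict[str, tuple[float, float]]  # (fraction at level 1, at level 2)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for drug, w in self.node_weight.items():
            g.add_node(drug, weight=float(w))
        for (a, b), w in self.edge_weight.items():
            if w > 0:
                g.add_edge(a, b, weight=float(w))
        nx.write_graphml(g, str(path))

    def to_stacked_bar_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": d,
                "fraction_level1": self.level_split[d][0],
                "fraction_level2": self.level_split[d][1],
                "node_weight": self.node_weight[d],
            }
            for d in self.node_weight
        ]
        return pd.DataFrame(rows)


def summarize_network(
    selection: CCISelection, drugs: Sequence[str] | None = None
) -> NetworkSummary:
    """Node/edge/level-split weights over the selected combinations."""
    combos = selection.selected
    if not combos:
        raise ValueError("empty selection")
    if drugs is None:
        drugs = sorted({d for c in combos for d in c.members})
    n = len(combos)
    node = {d: sum(1 for c in combos if d in c.members) / n for d in drugs}
    edge = {}
    ds = list(drugs)
    for i in range(len(ds)):
        for j in range(i + 1, len(ds)):
            a, b = ds[i], ds[j]
            edge[(a, b)] = sum(1 for c in combos if a in c.members and b in c.members) / n
    split = {}
    for d in drugs:
        lo = sum(1 for c in combos if c.levels.get(d) == 1) / n
        hi = sum(1 for c in combos if c.levels.get(d) == 2) / n
        split[d] = (lo, hi)
    return NetworkSummary(node_weight=node, edge_weight=edge, level_split=split)


def ranking_frame(
    filled: Sequence[CandidateCombination], selection: CCISelection | None = None
) -> pd.DataFrame:
    """One row per candidate, ranked by the selection criterion."""
    in_cci = {id(c) for c in selection.selected} if selection is not None else set()
    rows = []
    for c in filled:
        rows.append(
            {
                "members": "+".join(c.members),
                "levels": "+".join(str(c.levels[m]) for m in c.members),
                "pred_cancer": c.pred_cancer_viability,
                "pred_healthy": c.pred_healthy_viability,
                "ptw": c.ptw,
                "in_cci": id(c) in in_cci,
            }
        )
    df = pd.DataFrame(rows)
    if selection is not None and selection.mode == "max_ptw":
        df = df.sort_values("ptw", ascending=False, kind="mergesort")
    else:
        df = df.sort_values("pred_cancer", kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)
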
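"""Second-order regression engine of the multidrug-optimization screen.

Viability (% of control) is modelled as a full quadratic polynomial in the
orthogonally coded dose scores x_i ∈ {−1, 0, +1} (levels 0/1/2 shifted by
one):

    V = β0 + Σ_i β_i x_i + Σ_{i<j} β_ij x_i x_j + Σ_i β_ii x_i²

Because the response is viability, negative pairwise coefficients are
synergistic (the pair lowers viability beyond additivity) and positive ones
antagonistic.  The engine fits the full model by least squares, prunes it
by backward stepwise elimination under weak heredity, classifies the
surviving interactions, scores drugs for elimination between search
rounds, and selects the optimized combination by predicted viability or
therapeutic window (non-cancer minus cancer viability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import CandidateCombination, DesignMatrix, DrugPanel

__all__ = [
    "ScreenDataset",
    "SecondOrderModel",
    "InteractionCall",
    "EliminationResult",
    "AliasingError",
    "second_order_terms",
    "model_matrix",
    "fit_second_order",
    "stepwise_reduce",
    "classify_interactions",
    "eliminate_drugs",
    "therapeutic_window",
    "select_odc",
]

log = logging.getLogger(__name__)

_NOISELESS_SIGMA2 = 1e-18  # below this, residual variance is treated as zero
_NOISELESS_COEF = 1e-8


class AliasingError(ValueError):
    """Design cannot separate the requested terms (rank-deficient basis)."""

    def __init__(self, confounded: Sequence[str]):
        self.confounded = tuple(confounded)
        super().__init__(
            "design is rank-deficient for the requested model; terms involved "
            f"in aliasing: {', '.join(self.confounded)}"
        )


# ---------------------------------------------------------------------------
# feature basis
# ---------------------------------------------------------------------------


def second_order_terms(names: Sequence[str]) -> tuple[str, ...]:
    """Canonical term order: mains, pairwise ``a:b`` (i<j), quadratics ``a^2``."""
    names = list(names)
    terms = list(names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            terms.append(f"{names[i]}:{names[j]}")
    terms += [f"{n}^2" for n in names]
    return tuple(terms)


def model_matrix(
    coded: np.ndarray, names: Sequence[str], terms: Sequence[str]
) -> np.ndarray:
    """Columns for ``terms`` (no intercept) from coded scores, one row per obs."""
    coded = np.asarray(coded, dtype=float)
    idx = {n: k for k, n in enumerate(names)}
    cols = []
    for t in terms:
        if t.endswith("^2"):
            cols.append(coded[:, idx[t[:-2]]] ** 2)
        elif ":" in t:
            a, b = t.split(":")
            cols.append(coded[:, idx[a]] * coded[:, idx[b]])
        else:
            cols.append(coded[:, idx[t]])
    return np.column_stack(cols) if cols else np.empty((len(coded), 0))


def pair_key(term: str) -> tuple[str, str] | None:
    if ":" in term:
        a, b = term.split(":")
        return tuple(sorted((a, b)))  # type: ignore[return-value]
    return None


def terms_involving(drug: str, terms: Iterable[str]) -> list[str]:
    out = []
    for t in terms:
        if t == drug or t == f"{drug}^2" or (":" in t and drug in t.split(":")):
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenDataset:
    """Replicate viability readouts (% of control) for one biological model.

    ``readouts`` has columns ``condition_id, replicate, viability_pct``;
    each design condition must have at least one readout.
    """

    design: DesignMatrix
    model_id: str
    readouts: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"condition_id", "replicate", "viability_pct"}
        if not req <= set(self.readouts.columns):
            raise ValueError(f"readouts must have columns {sorted(req)}")
        have = set(self.readouts["condition_id"].astype(str))
        missing = set(self.design.row_ids) - have
        if missing:
            raise ValueError(
                f"design conditions without readouts: {sorted(missing)[:5]}..."
            )

    @property
    def n_replicates(self) -> int:
        return int(self.readouts.groupby("condition_id").size().max())

    @classmethod
    def from_signals(
        cls, design: DesignMatrix, model_id: str, signals: pd.DataFrame
    ) -> "ScreenDataset":
        """Normalize raw plate signals to % of the mean control signal."""
        ctrl_ids = set(design.control_ids())
        if not ctrl_ids:
            raise ValueError("design has no all-zero control row to normalize against")
        ctrl = signals.loc[signals["condition_id"].astype(str).isin(ctrl_ids), "signal"]
        if ctrl.empty or ctrl.mean() <= 0:
            raise ValueError("no positive control signals for normalization")
        out = signals.copy()
        out["viability_pct"] = 100.0 * out["signal"] / ctrl.mean()
        return cls(design, model_id, out[["condition_id", "replicate", "viability_pct"]])

    def observations(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-expanded (coded scores, viability) arrays for fitting."""
        pos = {rid: k for k, rid in enumerate(self.design.row_ids)}
        rows = self.readouts["condition_id"].astype(str).map(pos).to_numpy()
        coded = self.design.coded_scores()[rows]
        y = self.readouts["viability_pct"].to_numpy(dtype=float)
        return coded, y

    def to_csv(self, path: str | Path) -> None:
        df = self.readouts.copy()
        df.insert(1, "model_id", self.model_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, design: DesignMatrix, model_id: str | None = None
    ) -> "ScreenDataset":
        df = pd.read_csv(path)
        if model_id is not None and "model_id" in df.columns:
            df = df[df["model_id"] == model_id]
        mid = model_id or (str(df["model_id"].iloc[0]) if "model_id" in df.columns else "model")
        if "viability_pct" not in df.columns and "signal" in df.columns:
            return cls.from_signals(design, mid, df)
        return cls(design, mid, df[["condition_id", "replicate", "viability_pct"]])


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------


@dataclass
class SecondOrderModel:
    """Least-squares quadratic response-surface fit for one biological model."""

    model_id: str
    drug_names: tuple[str, ...]
    terms: tuple[str, ...]  # retained terms, intercept implicit
    beta0: float
    coef: dict[str, float]
    se: dict[str, float]  # includes "Intercept"
    pvalue: dict[str, float]
    sigma2: float
    df_resid: int
    data: ScreenDataset | None = field(default=None, repr=False, compare=False)

    @property
    def term_support(self) -> frozenset[str]:
        return frozenset(self.terms)

    @property
    def beta1(self) -> dict[str, float]:
        return {t: c for t, c in self.coef.items() if ":" not in t and not t.endswith("^2")}

    @property
    def beta2(self) -> dict[tuple[str, str], float]:
        return {pair_key(t): c for t, c in self.coef.items() if ":" in t}

    @property
    def beta_q(self) -> dict[str, float]:
        return {t[:-2]: c for t, c in self.coef.items() if t.endswith("^2")}

    def predict(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        X = model_matrix(coded, self.drug_names, self.terms)
        beta = np.array([self.coef[t] for t in self.terms])
        return self.beta0 + X @ beta

    def predict_candidate(self, cand: CandidateCombination) -> float:
        row = cand.coded_row(self.drug_names).astype(float) - 1.0
        return float(self.predict(row[None, :])[0])

    def confint(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Two-sided t confidence intervals for every coefficient."""
        q = stats.t.ppf(0.5 + level / 2.0, self.df_resid) if self.df_resid > 0 else np.inf
        out = {"Intercept": (self.beta0 - q * self.se["Intercept"], self.beta0 + q * self.se["Intercept"])}
        for t in self.terms:
            out[t] = (self.coef[t] - q * self.se[t], self.coef[t] + q * self.se[t])
        return out

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "drug_names": list(self.drug_names),
            "terms": list(self.terms),
            "beta0": self.beta0,
            "coef": self.coef,
            "se": self.se,
            "pvalue": self.pvalue,
            "sigma2": self.sigma2,
            "df_resid": self.df_resid,
        }


def _lstsq_fit(
    X: np.ndarray, y: np.ndarray, terms: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int]:
    """QR least squares with coefficient SEs and two-sided t p-values.

    ``X`` includes the intercept column first; term labels exclude it.
    """
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the terms loading on the null space of X
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[s < s[0] * 1e-10 * max(X.shape)] if len(s) else vt[:0]
        if null.size == 0:
            null = vt[rank:]
        labels = ("Intercept",) + tuple(terms)
        involved = sorted(
            {labels[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise AliasingError(involved)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid / df_resid) if df_resid > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
    if sigma2 > _NOISELESS_SIGMA2:
        tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    else:
        # a perfect fit: any numerically nonzero coefficient is real
        pvals = np.where(np.abs(beta) > _NOISELESS_COEF, 0.0, 1.0)
    return beta, se, pvals, sigma2, df_resid


def fit_second_order(
    data: ScreenDataset, terms: Sequence[str] | None = None
) -> SecondOrderModel:
    """Fit the (full, by default) second-order model by ordinary least squares.

    Replicate readouts enter as independent observations.  A rank-deficient
    basis raises :class:`AliasingError` naming the confounded terms.
    """
    names = data.design.panel.names
    terms = tuple(terms) if terms is not None else second_order_terms(names)
    coded, y = data.observations()
    X = np.column_stack([np.ones(len(y)), model_matrix(coded, names, terms)])
    beta, se, pvals, sigma2, df_resid = _lstsq_fit(X, y, terms)
    return SecondOrderModel(
        model_id=data.model_id,
        drug_names=names,
        terms=terms,
        beta0=float(beta[0]),
        coef=dict(zip(terms, beta[1:].tolist())),
        se={"Intercept": float(se[0]), **dict(zip(terms, se[1:].tolist()))},
        pvalue={"Intercept": float(pvals[0]), **dict(zip(terms, pvals[1:].tolist()))},
        sigma2=sigma2,
        df_resid=df_resid,
        data=data,
    )


def stepwise_reduce(model: SecondOrderModel, alpha: float = 0.05) -> SecondOrderModel:
    """Backward stepwise elimination at significance ``alpha`` with weak heredity.

    Repeatedly drops the least-significant droppable term with p > alpha and
    refits.  A first-order term is protected while any retained interaction
    or quadratic involves its drug.  An intercept-only result is valid.
    """
    if model.data is None:
        raise ValueError("model carries no dataset; fit it with fit_second_order first")
    current = model
    while current.terms:
        protected = set()
        for t in current.terms:
            if ":" in t:
                protected.update(t.split(":"))
            elif t.endswith("^2"):
                protected.add(t[:-2])
        droppable = [
            t
            for t in current.terms
            if not (":" not in t and not t.endswith("^2") and t in protected)
            and current.pvalue[t] > alpha
        ]
        if not droppable:
            break
        worst = max(droppable, key=lambda t: current.pvalue[t])
        remaining = tuple(t for t in current.terms if t != worst)
        current = fit_second_order(current.data, remaining)
    return current


# ---------------------------------------------------------------------------
# interaction classification & drug elimination
# ---------------------------------------------------------------------------

Label = Literal["synergistic", "antagonistic", "additive/neutral"]


@dataclass(frozen=True)
class InteractionCall:
    """Sign/significance call for one pairwise or single-drug term.

    On the viability scale a significant negative coefficient kills beyond
    additivity (synergistic); a significant positive one protects
    (antagonistic); everything else is additive/neutral.
    """

    term: str  # "a:b" for pairs, the drug name for first-order calls
    label: Label
    coefficient: float
    pvalue: float

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.term.split(":"))


def classify_interactions(
    model: SecondOrderModel, alpha: float = 0.05
) -> list[InteractionCall]:
    """Label every retained first-order and pairwise term of the model."""
    calls = []
    for t in model.terms:
        if t.endswith("^2"):
            continue
        c, p = model.coef[t], model.pvalue[t]
        if p < alpha and c < 0:
            label: Label = "synergistic"
        elif p < alpha and c > 0:
            label = "antagonistic"
        else:
            label = "additive/neutral"
        calls.append(InteractionCall(t, label, c, p))
    return calls


@dataclass
class EliminationResult:
    """Surviving panel plus the per-drug net-antagonism score table."""

    panel: DrugPanel
    scores: pd.DataFrame  # columns: drug, n_synergistic, n_antagonistic, score, eliminated
    forced_retained: tuple[str, ...] = ()

    @property
    def eliminated(self) -> tuple[str, ...]:
        return tuple(self.scores.loc[self.scores["eliminated"], "drug"])


def eliminate_drugs(
    model: SecondOrderModel,
    calls: Sequence[InteractionCall],
    min_drugs: int = 4,
    fdr: float | None = 0.05,
) -> EliminationResult:
    """Drop antagonism-dominated and inert drugs between search rounds.

    A drug's score is the sum of the significant pairwise interaction
    coefficients involving it (synergies are negative, antagonisms
    positive, so the score is its net antagonistic burden in viability
    points); a positive score ⇒ eliminated, as is a drug with no
    significant call of any kind (pairwise or single-drug).  Weighting by
    coefficient size rather than counting calls keeps one decisive
    synergy from being outvoted by marginal false-positive antagonisms,
    and because elimination is irreversible while the pairwise calls are
    a family of C(n,2) simultaneous tests, significance of the pairwise
    calls is re-assessed under Benjamini–Hochberg control at ``fdr``
    (pass ``fdr=None`` to take the calls' labels at face value).
    If fewer than ``min_drugs`` would survive, the lowest-scoring
    eliminated drugs are retained with a warning.
    """
    panel = model.data.design.panel if model.data is not None else None
    names = model.drug_names
    pair_all = [c for c in calls if ":" in c.term]
    bh_keep: set[str] = {c.term for c in pair_all}
    if fdr is not None and pair_all:
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests([c.pvalue for c in pair_all], alpha=fdr, method="fdr_bh")
        bh_keep = {c.term for c, r in zip(pair_all, reject) if r}
    rows = []
    for drug in names:
        pair_calls = [
            c
            for c in calls
            if ":" in c.term
            and drug in c.drugs
            and c.label != "additive/neutral"
            and c.term in bh_keep
        ]
        syn = sum(1 for c in pair_calls if c.label == "synergistic")
        ant = sum(1 for c in pair_calls if c.label == "antagonistic")
        score = float(sum(c.coefficient for c in pair_calls))
        inert = not any(
            drug in c.drugs and c.label != "additive/neutral" for c in calls
        )
        rows.append(
            {
                "drug": drug,
                "n_synergistic": syn,
                "n_antagonistic": ant,
                "score": score,
                "eliminated": score > 0 or inert,
            }
        )
    scores = pd.DataFrame(rows)
    survivors = [r["drug"] for r in rows if not r["eliminated"]]
    forced: list[str] = []
    if len(survivors) < min_drugs:
        pool = sorted(
            (r for r in rows if r["eliminated"]),
            key=lambda r: (r["score"], names.index(r["drug"])),
        )
        for r in pool[: min_drugs - len(survivors)]:
            forced.append(r["drug"])
            scores.loc[scores["drug"] == r["drug"], "eliminated"] = False
        survivors = [d for d in names if d in set(survivors) | set(forced)]
        log.warning(
            "eliminate_drugs: retained %s to keep a %d-drug panel", forced, min_drugs
        )
    if panel is None:
        raise ValueError("model carries no dataset/panel")
    return EliminationResult(
        panel=panel.subset(survivors),
        scores=scores,
        forced_retained=tuple(forced),
    )


# ---------------------------------------------------------------------------
# therapeutic window & final selection
# ---------------------------------------------------------------------------


def therapeutic_window(viab_noncancer: float, viab_cancer: float) -> float:
    """TW = non-cancer viability − cancer viability (percentage points).

    Positive TW means the combination spares the non-cancer model.
    """
    return viab_noncancer - viab_cancer


def select_odc(
    model_cancer: SecondOrderModel,
    model_noncancer: SecondOrderModel | None,
    candidates: Sequence[CandidateCombination],
) -> CandidateCombination:
    """Pick the optimized combination from the candidate space.

    Every candidate is filled in place with its predicted viabilities.
    With a non-cancer model the objective is maximal predicted therapeutic
    window, ties broken by lower predicted cancer viability; without one,
    minimal predicted cancer viability.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    for cand in candidates:
        cand.pred_cancer_viability = model_cancer.predict_candidate(cand)
        if model_noncancer is not None:
            cand.pred_healthy_viability = model_noncancer.predict_candidate(cand)
            cand.ptw = therapeutic_window(
                cand.pred_healthy_viability, cand.pred_cancer_viability
            )
    if model_noncancer is not None:
        best = min(candidates, key=lambda c: (-c.ptw, c.pred_cancer_viability, c.key()))
    else:
        best = min(candidates, key=lambda c: (c.pred_cancer_viability, c.key()))
    return best
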
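"""End-user surface: configuration, file round-trips, reports and the
multi-round screen driver.

A full campaign runs up to three search rounds: fit the second-order
model, classify interactions, eliminate antagonism-dominated drugs,
re-screen the survivors, and in the final round optimize doses by
selecting the best four-drug candidate (maximal predicted therapeutic
window when a non-cancer screen exists, minimal predicted cancer
viability otherwise).  A single-round mode reproduces the
patient-derived-organoid workflow, where only the first 50-condition
screen is feasible within the clinical timeframe.

:func:`run_tgmo` drives the campaign from files via :class:`RunConfig`;
:func:`run_tgmo_simulated` drives the identical logic from a synthetic
ground truth, generating each round's screen on the fly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .design import (
    CandidateCombination,
    DesignMatrix,
    DrugPanel,
    build_generic_design,
    build_search1_design,
    enumerate_candidates,
)
from .screen_regression import (
    ScreenDataset,
    SecondOrderModel,
    classify_interactions,
    eliminate_drugs,
    fit_second_order,
    select_odc,
    stepwise_reduce,
    therapeutic_window,
)

__all__ = ["RunConfig", "RoundFiles", "run_tgmo", "run_tgmo_simulated", "plot_model_coefficients"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoundFiles:
    """File inputs of one search round."""

    design: str
    screen_cancer: str
    screen_noncancer: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a multi-round campaign driven from files."""

    panel: str
    rounds: tuple[RoundFiles, ...]
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    min_drugs: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not self.rounds:
            raise ValueError("at least one search round is required")
        for p in [self.panel] + [
            q for r in self.rounds for q in (r.design, r.screen_cancer, r.screen_noncancer) if q
        ]:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        rounds = tuple(RoundFiles(**r) for r in raw.pop("rounds"))
        return cls(rounds=rounds, **raw)


def _candidate_record(cand: CandidateCombination) -> dict:
    return {
        "members": list(cand.members),
        "levels": {m: cand.levels[m] for m in cand.members},
        "pred_cancer_viability": cand.pred_cancer_viability,
        "pred_healthy_viability": cand.pred_healthy_viability,
        "ptw": cand.ptw,
    }


def _measured_tw(
    cancer: ScreenDataset, noncancer: ScreenDataset
) -> dict[str, float]:
    """Measured TW per condition: mean non-cancer minus mean cancer viability."""
    mc = cancer.readouts.groupby("condition_id")["viability_pct"].mean()
    mn = noncancer.readouts.groupby("condition_id")["viability_pct"].mean()
    shared = sorted(set(mc.index) & set(mn.index))
    return {cid: therapeutic_window(float(mn[cid]), float(mc[cid])) for cid in shared}


def _pool_screens(parts: Sequence[ScreenDataset]) -> ScreenDataset:
    """Concatenate replicate readouts of identical designs (replicates renumbered)."""
    import pandas as pd

    frames = []
    offset = 0
    for ds in parts:
        df = ds.readouts.copy()
        df["replicate"] = df["replicate"] + offset
        offset += int(df["replicate"].max())
        frames.append(df)
    return ScreenDataset(parts[-1].design, parts[-1].model_id, pd.concat(frames, ignore_index=True))


def _run_rounds(
    panel: DrugPanel,
    round_data: Sequence[tuple[DesignMatrix, ScreenDataset, ScreenDataset | None]],
    alpha: float,
    min_drugs: int,
) -> dict:
    """Shared fit → classify → eliminate → select logic over loaded rounds."""
    report: dict = {"rounds": [], "n_rounds": len(round_data)}
    current = panel
    model_c = model_n = None
    data_c = data_n = None
    for k, (design, data_c, data_n) in enumerate(round_data, start=1):
        last = k == len(round_data)
        full_c = fit_second_order(data_c)
        model_c = stepwise_reduce(full_c, alpha)
        # elimination decisions read the full fit: backward elimination on a
        # correlated design redistributes dropped effects into retained
        # columns, inflating phantom interaction calls
        calls = classify_interactions(full_c, alpha)
        model_n = None
        if data_n is not None:
            model_n = stepwise_reduce(fit_second_order(data_n), alpha)
        entry = {
            "round": k,
            "n_conditions": design.n_conditions,
            "panel": list(current.names),
            "model_cancer": model_c.to_dict(),
            "model_noncancer": model_n.to_dict() if model_n is not None else None,
            "interaction_calls": [
                {"term": c.term, "label": c.label, "coefficient": c.coefficient, "pvalue": c.pvalue}
                for c in calls
            ],
            "measured_tw": _measured_tw(data_c, data_n) if data_n is not None else None,
        }
        if not last:
            elim = eliminate_drugs(full_c, calls, min_drugs=min_drugs)
            entry["elimination"] = {
                "scores": elim.scores.to_dict(orient="records"),
                "eliminated": list(elim.eliminated),
                "forced_retained": list(elim.forced_retained),
            }
            current = elim.panel
            log.info("round %d: eliminated %s, %d drugs survive", k, elim.eliminated, len(current))
        report["rounds"].append(entry)
    # Dose optimization: the final model pools every round screened on the
    # identical design over the final panel (typically the last two rounds
    # when no drug fell in between), halving the prediction variance that
    # drives the choice between candidate dose levels.
    final_design = round_data[-1][0]
    same = [
        (dc, dn)
        for d, dc, dn in round_data
        if d.panel.names == final_design.panel.names and np.array_equal(d.rows, final_design.rows)
    ]
    if len(same) > 1:
        pooled_c = _pool_screens([dc for dc, _ in same])
        model_c = stepwise_reduce(fit_second_order(pooled_c), alpha)
        if all(dn is not None for _, dn in same):
            model_n = stepwise_reduce(fit_second_order(_pool_screens([dn for _, dn in same])), alpha)
        report["final_model_pooled_rounds"] = len(same)
    candidates = enumerate_candidates(current, 4, 2)
    best = select_odc(model_c, model_n, candidates)
    report["final_panel"] = list(current.names)
    report["odc"] = _candidate_record(best)
    report["odc"]["doses_uM"] = {
        m: current[m].dose_at_level(best.levels[m]) for m in best.members
    }
    return report, best


def run_tgmo(config: RunConfig) -> dict:
    """Run a campaign from files and return (and optionally write) the report.

    The panel file fixes round 1; each later round's design file must cover
    the drugs surviving the previous round's elimination.
    """
    panel = (
        DrugPanel.from_json(config.panel)
        if config.panel.endswith(".json")
        else DrugPanel.from_csv(config.panel)
    )
    current = panel
    loaded = []
    for k, rf in enumerate(config.rounds, start=1):
        try:
            design = DesignMatrix.from_csv(rf.design, current)
        except Exception as exc:
            raise ValueError(f"search round {k}: cannot load design ({exc})") from exc
        data_c = ScreenDataset.from_csv(rf.screen_cancer, design, model_id="cancer")
        data_n = (
            ScreenDataset.from_csv(rf.screen_noncancer, design, model_id="noncancer")
            if rf.screen_noncancer
            else None
        )
        loaded.append((design, data_c, data_n))
        if k < len(config.rounds):
            # dry-run elimination to know the next round's expected panel
            m = fit_second_order(data_c)
            current = eliminate_drugs(
                m, classify_interactions(m, config.alpha), min_drugs=config.min_drugs
            ).panel
    report, _ = _run_rounds(panel, loaded, config.alpha, config.min_drugs)
    report["config"] = {
        "panel": config.panel,
        "rounds": [
            {"design": r.design, "screen_cancer": r.screen_cancer, "screen_noncancer": r.screen_noncancer}
            for r in config.rounds
        ],
        "alpha": config.alpha,
        "seed": config.seed,
        "min_drugs": config.min_drugs,
        "out_dir": config.out_dir,
    }
    report["version"] = __version__
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def run_tgmo_simulated(
    truth,
    n_replicates: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    n_rounds: int = 3,
    with_noncancer: bool = True,
    min_drugs: int = 4,
) -> tuple[dict, CandidateCombination]:
    """Drive the identical multi-round logic from a synthetic ground truth.

    Round 1 uses the 50-condition composite design (7-drug panels) or the
    generic constructor; later rounds redesign over the survivors.  Per-round
    noise seeds are spawned deterministically from ``seed``.
    """
    from .synthetic_data import simulate_screen

    rng = np.random.default_rng(seed)
    round_seeds = rng.integers(0, 2**31 - 1, size=(n_rounds, 2))
    panel = truth.panel
    current = panel
    loaded = []
    for k in range(1, n_rounds + 1):
        if k == 1 and len(current) == 7:
            design = build_search1_design(current)
        else:
            design = build_generic_design(current)
        data_c = simulate_screen(
            truth, design, n_replicates, seed=int(round_seeds[k - 1, 0]), model="cancer"
        )
        data_n = (
            simulate_screen(
                truth, design, n_replicates, seed=int(round_seeds[k - 1, 1]), model="noncancer"
            )
            if with_noncancer
            else None
        )
        loaded.append((design, data_c, data_n))
        if k < n_rounds:
            m = fit_second_order(data_c)
            current = eliminate_drugs(
                m, classify_interactions(m, alpha), min_drugs=min_drugs
            ).panel
    report, best = _run_rounds(panel, loaded, alpha, min_drugs)
    report["config"] = {
        "simulated": True,
        "seed": seed,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "n_rounds": n_rounds,
        "with_noncancer": with_noncancer,
    }
    report["version"] = __version__
    return report, best


def plot_model_coefficients(model: SecondOrderModel, path: str | Path) -> None:
    """Coefficient forest plot: first-order, pairwise and quadratic terms."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    terms = list(model.terms)
    vals = [model.coef[t] for t in terms]
    errs = [model.se[t] for t in terms]
    colors = [
        "#b2182b" if (":" not in t and not t.endswith("^2")) else "#762a83" if ":" in t else "#f4a582"
        for t in terms
    ]
    fig, ax = plt.subplots(figsize=(6, max(2.5, 0.28 * len(terms))))
    ypos = np.arange(len(terms))[::-1]
    ax.barh(ypos, vals, xerr=errs, color=colors, edgecolor="none", height=0.7)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_yticks(ypos, terms, fontsize=7)
    ax.set_xlabel("coefficient (viability points)")
    ax.set_title(f"{model.model_id}: second-order model")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
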
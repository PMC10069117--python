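"""Synthetic two-model screens with known ground truth.

The generator emulates the structure of a phenotypic combination screen:
a cancer model and a non-cancer model whose viability responses follow a
second-order polynomial in the presence-scaled coded doses
u_i = level_i / 2 ∈ {0, ½, 1}, with planted synergistic (negative) and
antagonistic (positive) pairwise terms and i.i.d. Gaussian plate noise on
the replicates.  On this scale an interaction contributes only when both
drugs are actually dosed — absent drugs (u = 0) drop out of every term —
which gives the planted pairs their intended pharmacological meaning; the
same surface is still an exact member of the quadratic model family the
regression engine fits on the orthogonal ±1 scores.  The non-cancer surface
scales the cancer effect part down (default 0.3), so active combinations
open a positive therapeutic window.  Both surfaces are anchored so the
untreated control reads exactly 100% viability, and evaluations are
clipped into [0, 130] % with a log entry.

Because the coefficients are known, every pipeline stage is testable:
the optimal four-drug candidate (``planted_odc``) is recorded by
exhaustive evaluation of the noiseless cancer surface over the full
candidate space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    CandidateCombination,
    DesignMatrix,
    DrugPanel,
    DrugSpec,
    enumerate_candidates,
)
from .screen_regression import ScreenDataset, model_matrix, second_order_terms

__all__ = ["GroundTruth", "make_ground_truth", "simulate_screen"]

log = logging.getLogger(__name__)

VIABILITY_RANGE = (0.0, 130.0)


@dataclass(frozen=True)
class GroundTruth:
    """Known second-order surfaces for a simulated two-model screen."""

    panel: DrugPanel
    beta_cancer: dict[str, float]  # term → coefficient; "Intercept" included
    beta_noncancer: dict[str, float]
    planted_odc: CandidateCombination
    noise_sd: float
    seed: int

    def _surface(self, levels: np.ndarray, beta: dict[str, float]) -> np.ndarray:
        levels = np.atleast_2d(np.asarray(levels, dtype=int))
        coded = levels.astype(float) / 2.0  # presence scale: absent drugs vanish
        terms = [t for t in beta if t != "Intercept"]
        X = model_matrix(coded, self.panel.names, terms)
        raw = beta["Intercept"] + X @ np.array([beta[t] for t in terms])
        lo, hi = VIABILITY_RANGE
        n_clip = int(np.sum((raw < lo) | (raw > hi)))
        if n_clip:
            log.info("ground-truth surface: clipped %d evaluation(s) into [%g, %g]", n_clip, lo, hi)
        return np.clip(raw, lo, hi)

    def cancer_surface(self, levels: np.ndarray) -> np.ndarray:
        """Noiseless cancer viability (%) at coded level rows (0/1/2)."""
        return self._surface(levels, self.beta_cancer)

    def noncancer_surface(self, levels: np.ndarray) -> np.ndarray:
        return self._surface(levels, self.beta_noncancer)

    def levels_for(self, design: DesignMatrix) -> np.ndarray:
        """Embed a (possibly reduced-panel) design into this truth's panel."""
        full = np.zeros((design.n_conditions, len(self.panel)), dtype=int)
        pos = {n: k for k, n in enumerate(self.panel.names)}
        for j, name in enumerate(design.panel.names):
            full[:, pos[name]] = design.rows[:, j]
        return full

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drugs": [
                {
                    "name": d.name,
                    "dose_low_uM": d.dose_low,
                    "dose_high_uM": d.dose_high,
                    "dose_ceiling_uM": d.dose_ceiling,
                }
                for d in self.panel
            ],
            "beta_cancer": self.beta_cancer,
            "beta_noncancer": self.beta_noncancer,
            "planted_odc": {
                "members": list(self.planted_odc.members),
                "levels": self.planted_odc.levels,
            },
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def make_ground_truth(
    n_drugs: int = 7,
    n_synergies: int = 2,
    n_antagonisms: int = 1,
    effect_scale: float = 12.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    main_range: tuple[float, float] = (8.0, 16.0),
    quad_scale: float = 2.0,
    n_inert: int = 0,
    noncancer_scale: float = 0.3,
) -> GroundTruth:
    """Draw a random ground truth with planted pairwise interactions.

    Coefficients live on the presence scale (u_i = level/2): a drug's
    first-order term is its full-dose viability shift in percentage
    points, and a pairwise term acts only when both drugs are dosed.
    First-order effects are cytotoxic (negative), drawn from
    −U(main_range); the strongest are assigned to the drugs of the
    synergistic pairs and the weakest to the drugs of the antagonistic
    pairs, mirroring a screen whose antagonism-prone drugs are also the
    less active ones.  ``n_inert`` drugs get a near-zero first-order
    effect instead.  Pairwise terms have magnitude ≈ ``effect_scale``
    (negative = synergistic, positive = antagonistic), quadratic terms are
    mild (±``quad_scale``).  The optimal four-drug candidate of the
    noiseless cancer surface is found exhaustively and recorded.
    """
    n_pairs_max = n_drugs * (n_drugs - 1) // 2
    if n_synergies + n_antagonisms > n_pairs_max:
        raise ValueError("more planted pairs than drug pairs exist")
    if n_drugs < 4:
        raise ValueError("need at least 4 drugs")
    rng = np.random.default_rng(seed)

    names = [f"drug{i + 1:02d}" for i in range(n_drugs)]
    ic20 = 10.0 ** rng.uniform(-1, 1, size=n_drugs)
    panel = DrugPanel(
        tuple(
            DrugSpec.from_ic20(nm, float(d), dose_ceiling=float(4 * d))
            for nm, d in zip(names, ic20)
        )
    )

    # planted pairs: disjoint when enough drugs, otherwise distinct pairs
    n_pairs = n_synergies + n_antagonisms
    if 2 * n_pairs <= n_drugs:
        chosen = rng.permutation(n_drugs)[: 2 * n_pairs]
        pairs = [tuple(sorted((names[chosen[2 * k]], names[chosen[2 * k + 1]]))) for k in range(n_pairs)]
    else:
        from itertools import combinations

        all_pairs = list(combinations(names, 2))
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[i] for i in idx]
    syn_pairs, ant_pairs = pairs[:n_synergies], pairs[n_synergies:]

    # first-order effects: strongest → synergy drugs, weakest → antagonism drugs
    syn_drugs = sorted({d for p in syn_pairs for d in p})
    ant_drugs = sorted({d for p in ant_pairs for d in p} - set(syn_drugs))
    rest = [n for n in names if n not in syn_drugs and n not in ant_drugs]
    inert = set(rest[-n_inert:]) if n_inert else set()
    magnitudes = np.sort(rng.uniform(*main_range, size=n_drugs))[::-1]
    ordering = syn_drugs + [r for r in rest if r not in inert] + ant_drugs + sorted(inert)
    beta: dict[str, float] = {}
    for drug, mag in zip(ordering, magnitudes):
        beta[drug] = float(rng.uniform(-0.5, 0.5)) if drug in inert else float(-mag)

    for p in syn_pairs:
        beta[f"{p[0]}:{p[1]}"] = float(-effect_scale * rng.uniform(0.9, 1.1))
    for p in ant_pairs:
        beta[f"{p[0]}:{p[1]}"] = float(effect_scale * rng.uniform(0.9, 1.1))
    for nm in names:
        beta[f"{nm}^2"] = float(rng.uniform(-quad_scale, quad_scale))

    # Calibrate the drawn effects so the polynomial itself respects the
    # physical viability range over the whole level grid: a surface that
    # would cross 0 at heavily dosed conditions would otherwise have to be
    # truncated there, putting the generated data outside the quadratic
    # family the screen models fit.  One common rescale preserves every
    # effect ratio (and hence the identity of the optimal candidate).
    from itertools import product as _product

    grid = np.array(list(_product((0, 1, 2), repeat=n_drugs)), dtype=float) / 2.0
    terms = list(beta)
    raw = 100.0 + model_matrix(grid, names, terms) @ np.array([beta[t] for t in terms])
    # the floor keeps the most-dosed conditions clear of the zero-truncation
    # zone of the replicate noise (≈3 sd), so readouts stay effectively
    # Gaussian around the polynomial everywhere
    floor = max(VIABILITY_RANGE[0] + 2.0, 3.0 * noise_sd)
    ceil = VIABILITY_RANGE[1]
    scale = 1.0
    if raw.min() < floor:
        scale = min(scale, (100.0 - floor) / (100.0 - raw.min()))
    if raw.max() > ceil:
        scale = min(scale, (ceil - 100.0) / (raw.max() - 100.0))
    if scale < 1.0:
        log.info("make_ground_truth: rescaled effects by %.3f to keep the surface in range", scale)
        beta = {t: scale * v for t, v in beta.items()}

    beta_cancer = {"Intercept": 100.0, **beta}
    beta_noncancer = {"Intercept": 100.0, **{t: noncancer_scale * v for t, v in beta.items()}}

    # exhaustive argmin of the noiseless cancer surface over the candidate space
    truth = GroundTruth(
        panel=panel,
        beta_cancer=beta_cancer,
        beta_noncancer=beta_noncancer,
        planted_odc=CandidateCombination(tuple(names[:4]), {n: 2 for n in names[:4]}),
        noise_sd=noise_sd,
        seed=seed,
    )
    candidates = enumerate_candidates(panel, 4, 2)
    rows = np.stack([c.coded_row(panel.names) for c in candidates])
    viab = truth.cancer_surface(rows)
    best = candidates[int(np.argmin(viab))]
    object.__setattr__(truth, "planted_odc", best)
    return truth


def simulate_screen(
    truth: GroundTruth,
    design: DesignMatrix,
    n_replicates: int = 3,
    seed: int = 0,
    model: str = "cancer",
) -> ScreenDataset:
    """Simulate replicate viability readouts for one biological model.

    Per replicate: surface value at the condition's coded levels plus
    Gaussian noise of sd ``truth.noise_sd``, clipped at 0, then normalized
    to % of the mean control readout (the design's all-zero row).
    """
    if model not in ("cancer", "noncancer"):
        raise ValueError("model must be 'cancer' or 'noncancer'")
    rng = np.random.default_rng(seed)
    levels = truth.levels_for(design)
    surface = truth.cancer_surface(levels) if model == "cancer" else truth.noncancer_surface(levels)
    raw = surface[:, None] + rng.normal(0.0, truth.noise_sd, size=(len(surface), n_replicates))
    n_clip = int(np.sum(raw < 0))
    if n_clip:
        log.info("simulate_screen: clipped %d negative readout(s) to 0", n_clip)
    raw = np.maximum(raw, 0.0)
    records = []
    for rid, vals in zip(design.row_ids, raw):
        for r, v in enumerate(vals, start=1):
            records.append({"condition_id": rid, "replicate": r, "signal": v})
    signals = pd.DataFrame(records)
    return ScreenDataset.from_signals(design, model, signals)
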
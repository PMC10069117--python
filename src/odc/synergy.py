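"""Chou–Talalay combination index for a multi-drug treatment.

For an observed fraction affected fa, each drug's equivalent monotherapy
dose is Dx_i = Dm_i · (fa/(1−fa))^(1/m_i) from its median-effect fit, and
the combination index is the Loewe-type sum CI = Σ_i D_i / Dx_i (the
mutually-exclusive, no-cross-term form).  CI < 1 flags synergy, CI ≈ 1
additivity, CI > 1 antagonism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .dose_response import MedianEffectFit, inhibitory_dose

__all__ = ["CombinationIndexResult", "combination_index", "label_ci", "ADDITIVITY_TOL"]

ADDITIVITY_TOL = 1e-6


@dataclass(frozen=True)
class CombinationIndexResult:
    combo: dict[str, float]  # drug → administered dose (µM)
    fa: float
    ci: float
    per_drug_dx: dict[str, float]  # drug → Dx (µM) at effect fa

    @property
    def label(self) -> str:
        return label_ci(self.ci)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "combo_uM": self.combo,
                    "fa": self.fa,
                    "ci": self.ci,
                    "label": self.label,
                    "per_drug_dx_uM": self.per_drug_dx,
                },
                indent=2,
            )
            + "\n"
        )


def combination_index(
    combo_doses: Mapping[str, float],
    fits: Mapping[str, MedianEffectFit],
    fa: float,
) -> CombinationIndexResult:
    """CI = Σ_i D_i / Dx_i at the combination's observed fraction affected."""
    if not (0.0 < fa < 1.0):
        raise ValueError(f"fraction affected must be in (0, 1), got {fa}")
    if not combo_doses:
        raise ValueError("empty combination")
    missing = set(combo_doses) - set(fits)
    if missing:
        raise KeyError(f"no median-effect fit for: {sorted(missing)}")
    dx: dict[str, float] = {}
    ci = 0.0
    for drug, dose in combo_doses.items():
        if dose <= 0:
            raise ValueError(f"{drug}: dose must be positive, got {dose}")
        dx[drug] = inhibitory_dose(fits[drug], 100.0 * fa)
        ci += dose / dx[drug]
    return CombinationIndexResult(
        combo=dict(combo_doses), fa=fa, ci=ci, per_drug_dx=dx
    )


def label_ci(ci: float) -> str:
    """synergistic (CI < 1), additive (CI = 1 within tolerance), antagonistic."""
    if ci <= 0:
        raise ValueError(f"combination index must be positive, got {ci}")
    if abs(ci - 1.0) <= ADDITIVITY_TOL:
        return "additive"
    return "synergistic" if ci < 1.0 else "antagonistic"
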
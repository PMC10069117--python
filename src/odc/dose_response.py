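"""Monotherapy dose–response via the median-effect model.

The median-effect equation fa/(1−fa) = (D/Dm)^m links the fraction of
cells affected (fa) to dose D through the median-effect dose Dm (the dose
giving fa = 0.5) and a Hill-type slope m.  On the linearized scale,
log(fa/(1−fa)) is a straight line in log D, so the fit is an ordinary
least-squares regression; Dm and m feed the combination-index module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MedianEffectFit",
    "InvalidControlError",
    "InsufficientDataError",
    "fraction_affected",
    "fit_median_effect",
    "inhibitory_dose",
    "fits_from_monotherapy_table",
]

log = logging.getLogger(__name__)


class InvalidControlError(ValueError):
    """Control signal is non-positive; fraction affected is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than three usable dose points for the median-effect fit."""


@dataclass(frozen=True)
class MedianEffectFit:
    drug: str
    Dm: float  # median-effect dose, µM
    m: float  # slope (dimensionless)
    r2: float  # goodness of fit on the linearized scale

    def __post_init__(self) -> None:
        if not (self.Dm > 0 and self.m > 0):
            raise ValueError(f"{self.drug}: Dm and m must be positive")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"{self.drug}: r2 outside [0, 1]")


def fraction_affected(treated_signal, control_signal) -> np.ndarray | float:
    """FA = 1 − treated/control, clipped into [0, 1].

    Signals are raw ATP luminescence; clipping (treated above control, or
    negative readouts) is logged, not an error.
    """
    treated = np.asarray(treated_signal, dtype=float)
    control = np.asarray(control_signal, dtype=float)
    if np.any(control <= 0):
        raise InvalidControlError("control signal must be positive")
    if np.any(treated < 0):
        raise ValueError("treated signal must be non-negative")
    fa = 1.0 - treated / control
    n_clip = int(np.sum((fa < 0) | (fa > 1)))
    if n_clip:
        log.warning("fraction_affected: clipped %d value(s) into [0, 1]", n_clip)
    clipped = np.clip(fa, 0.0, 1.0)
    return float(clipped) if clipped.ndim == 0 else clipped


def fit_median_effect(drug: str, doses, fa) -> MedianEffectFit:
    """Least-squares median-effect fit on the linearized scale.

    Points with fa exactly 0 or 1 are excluded (their logit is undefined);
    at least three usable points must remain.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have the same length")
    if np.any(doses <= 0):
        raise ValueError(f"{drug}: doses must be positive")
    usable = (fa > 0.0) & (fa < 1.0)
    n_drop = int((~usable).sum())
    if n_drop:
        log.info("fit_median_effect(%s): excluded %d point(s) with fa in {0,1}", drug, n_drop)
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"{drug}: {int(usable.sum())} usable dose points, need ≥ 3"
        )
    x = np.log(doses[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError(f"{drug}: fitted slope m = {m:.3g} is not positive")
    Dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(drug=drug, Dm=Dm, m=m, r2=float(res.rvalue**2))


def inhibitory_dose(fit: MedianEffectFit, x: float) -> float:
    """Dose producing x% inhibition: Dx = Dm · (fa/(1−fa))^(1/m), fa = x/100."""
    if not (0.0 < x < 100.0):
        raise ValueError(f"effect level must be in (0, 100), got {x}")
    fa = x / 100.0
    return fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def fits_from_monotherapy_table(df: pd.DataFrame) -> dict[str, MedianEffectFit]:
    """Fit every drug in a monotherapy table.

    Expected columns: ``drug, dose_uM`` and either raw ``signal`` together
    with dose-0 control rows, or ``viability_pct`` (FA = 1 − viability/100).
    Replicates are averaged per dose before fitting.
    """
    fits: dict[str, MedianEffectFit] = {}
    for drug, grp in df.groupby("drug", sort=True):
        if "viability_pct" in grp.columns and grp["viability_pct"].notna().any():
            per_dose = grp[grp["dose_uM"] > 0].groupby("dose_uM")["viability_pct"].mean()
            fa = 1.0 - per_dose.to_numpy() / 100.0
            fa = np.clip(fa, 0.0, 1.0)
        else:
            controls = grp.loc[grp["dose_uM"] == 0, "signal"]
            if controls.empty:
                raise InvalidControlError(f"{drug}: no dose-0 control rows")
            per_dose = grp[grp["dose_uM"] > 0].groupby("dose_uM")["signal"].mean()
            fa = fraction_affected(per_dose.to_numpy(), controls.mean())
        fits[str(drug)] = fit_median_effect(str(drug), per_dose.index.to_numpy(), np.atleast_1d(fa))
    return fits


def fits_to_json(fits: dict[str, MedianEffectFit], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: asdict(v) for k, v in fits.items()}, indent=2) + "\n"
    )


def fits_from_json(path: str | Path) -> dict[str, MedianEffectFit]:
    raw = json.loads(Path(path).read_text())
    return {k: MedianEffectFit(**v) for k, v in raw.items()}
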
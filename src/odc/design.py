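"""Combination-screen designs and the four-drug candidate space.

A screen round tests each drug of a panel at three coded levels —
0 (absent), 1 (low dose, IC20/2) and 2 (high dose, IC20) — across a small
set of multi-drug conditions.  The first search round over a seven-drug
panel uses an orthogonal-array composite design: a resolution-IV two-level
fractional factorial (levels {0,2}) stacked with the classical 18-run
three-level orthogonal array, 50 conditions in total, which supports the
full second-order polynomial model (intercept, 7 linear, 21 pairwise,
7 quadratic terms).  Later rounds over the surviving drugs use a generic
composite constructor.

Candidate therapies are all four-drug subsets of the panel with each
member at level 1 or 2; :func:`enumerate_candidates` spans that space
deterministically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrugSpec",
    "DrugPanel",
    "DesignMatrix",
    "CandidateCombination",
    "InvalidPanelError",
    "UnsupportedDesignSizeError",
    "build_search1_design",
    "build_generic_design",
    "decode_design",
    "enumerate_candidates",
]


class InvalidPanelError(ValueError):
    """The drug panel cannot support the requested design."""


class UnsupportedDesignSizeError(ValueError):
    """No fixed composite table exists for this panel size."""


@dataclass(frozen=True)
class DrugSpec:
    """A screened drug with its two nonzero dose levels.

    ``dose_high`` is the screen's level-2 concentration (the IC20 by the
    platform's convention) and ``dose_low`` the level-1 concentration
    (half the IC20 unless stated otherwise).  ``dose_ceiling`` is the
    clinically used dose; screen doses never exceed it.
    """

    name: str
    dose_low: float
    dose_high: float
    dose_ceiling: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("drug name must be non-empty")
        if not (0.0 < self.dose_low < self.dose_high):
            raise ValueError(
                f"{self.name}: require 0 < dose_low < dose_high, "
                f"got {self.dose_low} / {self.dose_high}"
            )
        if self.dose_ceiling is not None and self.dose_high > self.dose_ceiling:
            raise ValueError(
                f"{self.name}: dose_high {self.dose_high} µM exceeds the "
                f"clinical ceiling {self.dose_ceiling} µM"
            )

    @classmethod
    def from_ic20(
        cls, name: str, ic20: float, dose_ceiling: float | None = None
    ) -> "DrugSpec":
        """Build a spec from a single IC20: level 2 = IC20, level 1 = IC20/2."""
        return cls(name, ic20 / 2.0, ic20, dose_ceiling)

    def dose_at_level(self, level: int) -> float:
        return (0.0, self.dose_low, self.dose_high)[level]


@dataclass(frozen=True)
class DrugPanel:
    """Ordered collection of :class:`DrugSpec`; the order fixes design columns."""

    drugs: tuple[DrugSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise InvalidPanelError(f"duplicate drug names in panel: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drugs)

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self) -> Iterator[DrugSpec]:
        return iter(self.drugs)

    def __getitem__(self, name: str) -> DrugSpec:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "DrugPanel":
        """Surviving-panel constructor: keeps this panel's column order."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"drugs not in panel: {sorted(missing)}")
        return DrugPanel(tuple(d for d in self.drugs if d.name in keep))

    # ---- round trips -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "name": d.name,
                "dose_low_uM": d.dose_low,
                "dose_high_uM": d.dose_high,
                "dose_ceiling_uM": d.dose_ceiling,
            }
            for d in self.drugs
        ]
        Path(path).write_text(json.dumps(records, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DrugPanel":
        records = json.loads(Path(path).read_text())
        return cls(
            tuple(
                DrugSpec(
                    r["name"],
                    float(r["dose_low_uM"]),
                    float(r["dose_high_uM"]),
                    None if r.get("dose_ceiling_uM") is None else float(r["dose_ceiling_uM"]),
                )
                for r in records
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugPanel":
        df = pd.read_csv(path)
        return cls(
            tuple(
                DrugSpec(
                    str(r["name"]),
                    float(r["dose_low_uM"]),
                    float(r["dose_high_uM"]),
                    None if pd.isna(r.get("dose_ceiling_uM")) else float(r["dose_ceiling_uM"]),
                )
                for _, r in df.iterrows()
            )
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Coded experimental plan: one row per condition, one column per drug."""

    panel: DrugPanel
    rows: np.ndarray  # (n_conditions, n_drugs) int, entries in {0,1,2}
    row_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=int)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        if rows.ndim != 2 or rows.shape[1] != len(self.panel):
            raise ValueError(
                f"rows shape {rows.shape} does not match panel of {len(self.panel)}"
            )
        if len(self.row_ids) != rows.shape[0]:
            raise ValueError("row_ids length must equal the number of conditions")
        if not np.isin(rows, (0, 1, 2)).all():
            raise ValueError("coded levels must be 0, 1 or 2")
        nonzero = rows[rows.any(axis=1)]
        if len(nonzero) != len({tuple(r) for r in nonzero}):
            raise ValueError("duplicate rows are only permitted for the control")

    @property
    def n_conditions(self) -> int:
        return self.rows.shape[0]

    def coded_scores(self) -> np.ndarray:
        """Orthogonal recode {0,1,2} → {−1,0,+1} used by the regression engine."""
        return self.rows.astype(float) - 1.0

    def control_ids(self) -> tuple[str, ...]:
        mask = ~self.rows.any(axis=1)
        return tuple(rid for rid, m in zip(self.row_ids, mask) if m)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=list(self.panel.names))
        df.insert(0, "condition_id", list(self.row_ids))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, panel: DrugPanel) -> "DesignMatrix":
        df = pd.read_csv(path)
        missing = set(panel.names) - set(df.columns)
        if missing:
            raise InvalidPanelError(f"design file lacks columns for {sorted(missing)}")
        return cls(
            panel,
            df[list(panel.names)].to_numpy(dtype=int),
            tuple(df["condition_id"].astype(str)),
        )


@dataclass
class CandidateCombination:
    """A four-drug candidate therapy at fixed levels, later filled with predictions."""

    members: tuple[str, ...]
    levels: dict[str, int]
    pred_cancer_viability: float | None = None
    pred_healthy_viability: float | None = None
    ptw: float | None = None

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if len(set(self.members)) != len(self.members):
            raise ValueError("candidate members must be distinct")
        if set(self.levels) != set(self.members):
            raise ValueError("levels must be given exactly for the members")
        if any(lv < 1 for lv in self.levels.values()):
            raise ValueError("every member must have a nonzero level")

    def coded_row(self, panel_names: Sequence[str]) -> np.ndarray:
        """Coded levels of this candidate on a full panel (absent drugs at 0)."""
        row = np.zeros(len(panel_names), dtype=int)
        for drug, lv in self.levels.items():
            if drug not in panel_names:
                raise KeyError(drug)
            row[list(panel_names).index(drug)] = lv
        return row

    def key(self) -> tuple:
        return (self.members, tuple(self.levels[m] for m in self.members))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

# Classical 18-run three-level orthogonal array (the seven 3-level columns of
# the 2^1 x 3^7 table, levels shifted to {0,1,2}; its 2-level column is not
# used).  Strength 2: every pair of columns shows all nine level pairs twice.
# Columns are embedded through the fixed permutation _OA18_COLS, chosen (by
# exhaustive search over the 7! assignments) to (i) avoid duplicating any
# non-control run of the stacked two-level fraction and (ii) minimize the
# worst-case variance of the pairwise-interaction coefficients, which for a
# resolution-IV fraction are partially aliased and rely on the array block
# for separation (A-optimal embedding).
_OA18 = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0],
        [0, 1, 1, 1, 1, 1, 1],
        [0, 2, 2, 2, 2, 2, 2],
        [1, 0, 0, 1, 1, 2, 2],
        [1, 1, 1, 2, 2, 0, 0],
        [1, 2, 2, 0, 0, 1, 1],
        [2, 0, 1, 0, 2, 1, 2],
        [2, 1, 2, 1, 0, 2, 0],
        [2, 2, 0, 2, 1, 0, 1],
        [0, 0, 2, 2, 1, 1, 0],
        [0, 1, 0, 0, 2, 2, 1],
        [0, 2, 1, 1, 0, 0, 2],
        [1, 0, 1, 2, 0, 2, 1],
        [1, 1, 2, 0, 1, 0, 2],
        [1, 2, 0, 1, 2, 1, 0],
        [2, 0, 2, 1, 2, 0, 1],
        [2, 1, 0, 2, 0, 1, 2],
        [2, 2, 1, 0, 1, 2, 0],
    ],
    dtype=int,
)

_OA18_COLS = (3, 4, 0, 5, 1, 6, 2)


def _fractional_factorial_7() -> np.ndarray:
    """2^(7−2) resolution-IV fraction on ±1, as coded levels {0,2}.

    Base factors A–E in full factorial; F = −ABCD, G = −ABDE.  The sign
    choice selects the fraction containing the all-minus run, which maps
    to the all-zero (untreated control) condition.
    """
    rows = []
    for bits in itertools.product((-1, 1), repeat=5):
        a, b, c, d, e = bits
        f = -(a * b * c * d)
        g = -(a * b * d * e)
        rows.append((a, b, c, d, e, f, g))
    ff = np.array(rows, dtype=int)
    return np.where(ff == 1, 2, 0)


def build_search1_design(panel: DrugPanel) -> DesignMatrix:
    """First-round composite design for a seven-drug panel (50 conditions).

    Stacks a 32-run resolution-IV two-level fraction on levels {0,2} with
    the 18-run three-level orthogonal array on levels {0,1,2}.  Other
    panel sizes are served by :func:`build_generic_design`.
    """
    if len(panel) < 4:
        raise InvalidPanelError(
            f"panel of {len(panel)} drugs cannot support a combination screen (need ≥ 4)"
        )
    if len(panel) != 7:
        raise UnsupportedDesignSizeError(
            f"no fixed 50-run composite table for {len(panel)} drugs; "
            "use build_generic_design for other panel sizes"
        )
    rows = np.vstack([_fractional_factorial_7(), _OA18[:, _OA18_COLS]])
    ids = [f"ff{i + 1:02d}" for i in range(32)] + [f"oa{i + 1:02d}" for i in range(18)]
    return DesignMatrix(panel, rows, tuple(ids))


def build_generic_design(panel: DrugPanel) -> DesignMatrix:
    """Composite design for the later (smaller) search rounds.

    Same structure as the first-round design, scaled down: a two-level
    block on {0,2} — full factorial for up to 5 drugs, a half fraction
    (last factor = −(product of the others), resolution ≥ V) for 6, the
    32-run resolution-IV fraction for 7 — stacked with the first n
    three-level columns of the 18-run orthogonal array, which carry the
    level-1 (half-dose) information the quadratic terms and the final
    dose-optimization round need.  Duplicate conditions created by the
    column slicing are dropped (first occurrence kept).
    """
    n = len(panel)
    if n < 4:
        raise InvalidPanelError(
            f"panel of {len(panel)} drugs cannot support a combination screen (need ≥ 4)"
        )
    if n <= 5:
        two = np.array(list(itertools.product((0, 2), repeat=n)), dtype=int)
    elif n == 6:
        rows = []
        for bits in itertools.product((-1, 1), repeat=5):
            last = -int(np.prod(bits))
            rows.append(tuple(bits) + (last,))
        two = np.where(np.array(rows, dtype=int) == 1, 2, 0)
    elif n == 7:
        two = _fractional_factorial_7()
    else:
        raise UnsupportedDesignSizeError(
            f"generic composite designs cover 4–7 drugs, got {n}"
        )
    if not (two == 0).all(axis=1).any():  # ensure an embedded control row
        two = np.vstack([np.zeros(n, dtype=int), two])
    oa = _OA18[:, _OA18_COLS][:, :n]
    rows = np.vstack([two, oa])
    ids = [f"ff{i + 1:02d}" for i in range(len(two))] + [
        f"oa{i + 1:02d}" for i in range(len(oa))
    ]
    seen: dict[tuple, int] = {}
    keep = []
    for k, r in enumerate(rows):
        key = tuple(r)
        if key not in seen:
            seen[key] = k
            keep.append(k)
    return DesignMatrix(panel, rows[keep], tuple(ids[k] for k in keep))


def decode_design(design: DesignMatrix) -> pd.DataFrame:
    """Concentration table (µM): level 0 → 0, 1 → dose_low, 2 → dose_high."""
    doses = np.empty(design.rows.shape, dtype=float)
    for j, drug in enumerate(design.panel):
        lut = np.array([0.0, drug.dose_low, drug.dose_high])
        doses[:, j] = lut[design.rows[:, j]]
    df = pd.DataFrame(doses, columns=list(design.panel.names))
    df.insert(0, "condition_id", list(design.row_ids))
    return df


def enumerate_candidates(
    drugs: int | Sequence[str] | DrugPanel,
    combo_size: int = 4,
    n_levels: int = 2,
) -> list[CandidateCombination]:
    """All C(n, combo_size) · n_levels^combo_size candidate combinations.

    ``drugs`` may be a panel, a sequence of names, or a count (names then
    default to ``drug01`` …).  Nonzero levels run 1..n_levels.  Order is
    deterministic: lexicographic in member names, then in level tuples.
    An oversized ``combo_size`` yields an empty list.
    """
    if isinstance(drugs, DrugPanel):
        names: Sequence[str] = drugs.names
    elif isinstance(drugs, int):
        names = [f"drug{i + 1:02d}" for i in range(drugs)]
    else:
        names = list(drugs)
    if n_levels < 1:
        raise ValueError("n_levels must be ≥ 1")
    out: list[CandidateCombination] = []
    for members in itertools.combinations(sorted(names), combo_size):
        for levels in itertools.product(range(1, n_levels + 1), repeat=combo_size):
            out.append(CandidateCombination(members, dict(zip(members, levels))))
    return out
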
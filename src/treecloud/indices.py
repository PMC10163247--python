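"""Spectral-index construction over 4 multispectral bands.

Twenty-two formula categories are defined on the band reflectances R_i
(single-band transforms F1–F7 and two-band combinations F8–F22).  Two of
the printed two-band categories (F20, F22) are typographic duplicates of
F12 — all three read ln(R_i)/(R_i − R_j) — and are therefore collapsed into
a single canonical category.  Enumerating the 7 single-band categories over
4 bands (28), the 3 order-symmetric categories (F8, F10, F14) over the 6
unordered band pairs (18) and the remaining 10 asymmetric categories over
the 12 ordered pairs (120) yields the full feature set of 166 distinct
spectral indices.

Evaluations with a near-zero denominator (|den| < ``DENOM_EPS``) or a
non-positive logarithm argument yield NaN missing-markers instead of
infinities; downstream screening treats them pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import BAND_COLUMNS, N_BANDS

DENOM_EPS = 1e-12  # denominator guard on the reflectance scale

_Arr = np.ndarray


def _guard_div(num: _Arr, den: _Arr) -> _Arr:
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        safe = np.where(np.abs(den) < DENOM_EPS, 1.0, den)
        return np.where(np.abs(den) < DENOM_EPS, np.nan, num / safe)


def _guard_log(x: _Arr) -> _Arr:
    return np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)


# category -> (formula, needs_j, symmetric in (i, j))
_CATEGORIES: dict[str, tuple[Callable[..., _Arr], bool, bool]] = {
    "F1": (lambda ri: ri, False, False),
    "F2": (lambda ri: ri**2, False, False),
    "F3": (lambda ri: ri**3, False, False),
    "F4": (lambda ri: ri**0.5, False, False),
    "F5": (lambda ri: ri ** (1.0 / 3.0), False, False),
    "F6": (lambda ri: np.exp(ri), False, False),
    "F7": (lambda ri: _guard_log(ri), False, False),
    "F8": (lambda ri, rj: ri + rj, True, True),
    "F9": (lambda ri, rj: ri - rj, True, False),
    "F10": (lambda ri, rj: ri * rj, True, True),
    "F11": (lambda ri, rj: _guard_div(ri, rj), True, False),
    "F12": (lambda ri, rj: _guard_div(_guard_log(ri), ri - rj), True, False),
    "F13": (lambda ri, rj: _guard_div(ri - rj, ri + rj), True, False),
    "F14": (lambda ri, rj: _guard_div(ri * rj, ri + rj), True, True),
    "F15": (lambda ri, rj: _guard_div(_guard_div(ri, rj), ri + rj), True, False),
    "F16": (lambda ri, rj: _guard_div(ri - rj, ri * rj), True, False),
    "F17": (lambda ri, rj: _guard_div(_guard_div(ri, rj), ri - rj), True, False),
    "F18": (lambda ri, rj: (ri + rj) / np.exp(ri), True, False),
    "F19": (lambda ri, rj: (ri - rj) / np.exp(ri), True, False),
    # F20 and F22 print identically to F12 and carry no separate definition.
    "F21": (lambda ri, rj: _guard_div(_guard_log(ri), ri + rj), True, False),
}

DUPLICATE_CATEGORIES = {"F20": "F12", "F22": "F12"}


@dataclass(frozen=True)
class IndexDefinition:
    """One spectral index: a category formula bound to concrete bands."""

    category: str
    i: int
    j: Optional[int] = None

    def __post_init__(self) -> None:
        cat = DUPLICATE_CATEGORIES.get(self.category, self.category)
        if cat not in _CATEGORIES:
            raise ValueError(f"unknown index category {self.category!r}")
        formula, needs_j, _ = _CATEGORIES[cat]
        if not 1 <= self.i <= N_BANDS:
            raise ValueError("band index i out of range 1..4")
        if needs_j:
            if self.j is None or not 1 <= self.j <= N_BANDS:
                raise ValueError(f"{self.category} requires band index j in 1..4")
            if self.i == self.j:
                raise ValueError(f"{self.category} requires i != j")
        elif self.j is not None:
            raise ValueError(f"{self.category} takes a single band")

    @property
    def canonical_key(self) -> str:
        """Symbolic normal form; identical keys <=> identical formulas."""
        cat = DUPLICATE_CATEGORIES.get(self.category, self.category)
        _, needs_j, symmetric = _CATEGORIES[cat]
        if not needs_j:
            return f"{cat}_i{self.i}"
        i, j = self.i, self.j
        if symmetric and j < i:
            i, j = j, i
        return f"{cat}_i{i}_j{j}"

    @property
    def feature_id(self) -> str:
        return self.canonical_key

    def __call__(self, bands: _Arr) -> _Arr:
        """Evaluate on an (n, 4) reflectance array."""
        cat = DUPLICATE_CATEGORIES.get(self.category, self.category)
        formula, needs_j, _ = _CATEGORIES[cat]
        ri = bands[..., self.i - 1]
        if needs_j:
            return formula(ri, bands[..., self.j - 1])
        return formula(ri)


def enumerate_indices() -> list[IndexDefinition]:
    """Full deduplicated enumeration: 28 + 18 + 120 = 166 definitions."""
    out: list[IndexDefinition] = []
    for cat, (_, needs_j, symmetric) in _CATEGORIES.items():
        if not needs_j:
            out.extend(IndexDefinition(cat, i) for i in range(1, N_BANDS + 1))
        elif symmetric:
            out.extend(
                IndexDefinition(cat, i, j)
                for i in range(1, N_BANDS + 1)
                for j in range(i + 1, N_BANDS + 1)
            )
        else:
            out.extend(
                IndexDefinition(cat, i, j)
                for i in range(1, N_BANDS + 1)
                for j in range(1, N_BANDS + 1)
                if i != j
            )
    return out


def _band_array(samples: pd.DataFrame | _Arr) -> _Arr:
    if isinstance(samples, pd.DataFrame):
        return samples[BAND_COLUMNS].to_numpy(dtype=float)
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_BANDS:
        raise ValueError("expected an (n, 4) reflectance array")
    return arr


def evaluate_index(defn: IndexDefinition, samples: pd.DataFrame | _Arr) -> _Arr:
    """Evaluate one index elementwise over a sample table; NaN marks
    guarded singularities (zero denominators, non-positive log arguments)."""
    return defn(_band_array(samples))


def build_feature_matrix(
    samples: pd.DataFrame | _Arr,
    definitions: Optional[Sequence[IndexDefinition]] = None,
) -> pd.DataFrame:
    """Evaluate every definition over the samples.

    Returns an (n_samples, n_definitions) DataFrame with one column per
    definition in enumeration order, named by ``canonical_key``.
    """
    if definitions is None:
        definitions = enumerate_indices()
    definitions = list(definitions)
    if not definitions:
        raise ValueError("at least one index definition is required")
    bands = _band_array(samples)
    if bands.shape[0] == 0:
        raise ValueError("at least one sample is required")
    cols = {d.canonical_key: d(bands) for d in definitions}
    if len(cols) != len(definitions):
        raise ValueError("definitions contain duplicate canonical keys")
    fm = pd.DataFrame(cols)
    if isinstance(samples, pd.DataFrame):
        fm.index = samples.index
    return fm


def parse_feature_id(feature_id: str) -> IndexDefinition:
    """Inverse of ``canonical_key``, e.g. ``'F13_i4_j3'``."""
    parts = feature_id.split("_")
    cat = parts[0]
    i = int(parts[1][1:])
    j = int(parts[2][1:]) if len(parts) > 2 else None
    return IndexDefinition(cat, i, j)
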
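"""Fixed-effect design matrices for factor models.

A tiny, deterministic treatment-coded design builder: intercept, dummy
columns for each factor's non-reference levels, and elementwise products
for two-way interactions. Level order is order of first appearance unless
the column is an ordered pandas Categorical; the first level is the
reference. The :class:`Design` object can re-encode new rows (prediction
grids), which is what the marginal-means machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import UsageError


def _levels(data: pd.DataFrame, factor: str) -> list[str]:
    col = data[factor]
    if isinstance(col.dtype, pd.CategoricalDtype):
        return [str(l) for l in col.cat.categories]
    seen: list[str] = []
    for v in col.astype(str):
        if v not in seen:
            seen.append(v)
    return seen


@dataclass
class Design:
    """Treatment-coded design for main effects and two-way interactions.

    ``terms`` are factor names, or ``"a:b"`` for an interaction of two
    factors already present as main effects.
    """

    terms: tuple[str, ...]
    levels: dict[str, list[str]] = field(default_factory=dict)
    column_names: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(cls, data: pd.DataFrame, terms: list[str] | tuple[str, ...]
                   ) -> "Design":
        terms = tuple(terms)
        factors = [t for t in terms if ":" not in t]
        for t in terms:
            for f in t.split(":"):
                if f not in data.columns:
                    raise UsageError(f"factor {f!r} not in data")
                if f not in factors:
                    raise UsageError(
                        f"interaction {t!r} requires main effect {f!r}")
        design = cls(terms=terms)
        design.levels = {f: _levels(data, f) for f in factors}
        design.column_names = design._make_names()
        return design

    def _make_names(self) -> list[str]:
        names = ["Intercept"]
        for term in self.terms:
            if ":" not in term:
                names += [f"{term}[{l}]" for l in self.levels[term][1:]]
            else:
                a, b = term.split(":")
                names += [f"{a}[{la}]:{b}[{lb}]"
                          for la in self.levels[a][1:]
                          for lb in self.levels[b][1:]]
        return names

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Encode rows of ``data`` with this design's level order."""
        n = len(data)
        dummies: dict[str, dict[str, np.ndarray]] = {}
        for f, levels in self.levels.items():
            col = data[f].astype(str).to_numpy()
            unknown = set(col) - set(levels)
            if unknown:
                raise UsageError(f"factor {f!r}: unseen level(s) {sorted(unknown)}")
            dummies[f] = {l: (col == l).astype(float) for l in levels}
        cols = [np.ones(n)]
        for term in self.terms:
            if ":" not in term:
                cols += [dummies[term][l] for l in self.levels[term][1:]]
            else:
                a, b = term.split(":")
                cols += [dummies[a][la] * dummies[b][lb]
                         for la in self.levels[a][1:]
                         for lb in self.levels[b][1:]]
        return np.column_stack(cols)

    @property
    def n_params(self) -> int:
        return len(self.column_names)

    def factors(self) -> list[str]:
        return list(self.levels)

    def grid(self) -> pd.DataFrame:
        """Full factorial grid over all factor levels (for marginal means)."""
        idx = pd.MultiIndex.from_product(
            [self.levels[f] for f in self.levels], names=list(self.levels))
        return idx.to_frame(index=False)
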
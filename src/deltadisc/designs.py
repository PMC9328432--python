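"""Exact designs and optimization of the delta criterion over them.

An exact design is a multiset of n points of the finite design space; the
equivalent counting-measure view assigns each distinct point its multiplicity.
Designs are kept in a canonical (lexicographically sorted) order so that equal
multisets compare equal and serialize identically.

Optimization is over all n-point designs: complete enumeration for small
problems and a seeded exchange heuristic (of the KL-exchange family) for
larger ones.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .criterion import _delta_sq_core
from .models import DiscriminationProblem

__all__ = ["ExactDesign", "SearchResult", "kl_exchange", "exhaustive_search", "efficiency"]


@dataclass(frozen=True)
class ExactDesign:
    """A multiset of design points, stored in canonical sorted order."""

    points: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        pts = tuple(sorted(tuple(float(c) for c in np.atleast_1d(p)) for p in self.points))
        if len(pts) == 0:
            raise ValueError("a design must contain at least one point")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_points(cls, points) -> "ExactDesign":
        arr = np.atleast_1d(np.asarray(points, dtype=float))
        if arr.ndim == 1:
            arr = arr[:, None]
        return cls(tuple(map(tuple, arr)))

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def dim_x(self) -> int:
        return len(self.points[0])

    @property
    def counting_view(self) -> list[tuple[tuple[float, ...], int]]:
        """Distinct points with multiplicities (sums to n, no duplicates)."""
        out: dict[tuple[float, ...], int] = {}
        for p in self.points:
            out[p] = out.get(p, 0) + 1
        return sorted(out.items())

    def replicate(self, s: int) -> "ExactDesign":
        return ExactDesign(self.points * s)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{j + 1}": [] for j in range(self.dim_x)}
        mult = []
        for p, k in self.counting_view:
            for j, c in enumerate(p):
                cols[f"x{j + 1}"].append(c)
            mult.append(k)
        cols["multiplicity"] = mult
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExactDesign":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        pts = []
        for _, row in df.iterrows():
            p = tuple(float(row[c]) for c in xcols)
            pts.extend([p] * int(row["multiplicity"]))
        return cls(tuple(pts))

    def to_dict(self) -> dict:
        return {"points": [list(p) for p, k in self.counting_view],
                "multiplicities": [k for _, k in self.counting_view]}

    @classmethod
    def from_dict(cls, d) -> "ExactDesign":
        pts = []
        for p, k in zip(d["points"], d["multiplicities"]):
            pts.extend([tuple(p)] * int(k))
        return cls(tuple(pts))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "ExactDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SearchResult:
    """Outcome of a delta-optimal design search."""

    best_design: ExactDesign
    best_delta_sq: float
    n_evaluations: int
    per_start: list[float]
    seed: Optional[int]
    r: float
    method: str

    def to_dict(self) -> dict:
        return {
            "best_design": self.best_design.to_dict(),
            "best_delta_sq": self.best_delta_sq,
            "n_evaluations": self.n_evaluations,
            "per_start": self.per_start,
            "seed": self.seed,
            "r": None if np.isinf(self.r) else self.r,
            "method": self.method,
        }


def _design_from_indices(problem, idx) -> ExactDesign:
    return ExactDesign.from_points(problem.design_space[np.asarray(idx, dtype=int)])


def kl_exchange(
    problem: DiscriminationProblem,
    n: int,
    r: float,
    n_starts: int = 20,
    seed: Optional[int] = None,
    tol: float = 1e-12,
) -> SearchResult:
    """Maximize delta_r^2 over n-point designs by a seeded exchange heuristic.

    Each start samples n points uniformly with replacement; passes then scan
    the design slots in a fresh random order and replace a slot by its best
    candidate point whenever that improves the criterion by more than ``tol``,
    terminating at a local optimum.  The best local optimum over all starts is
    returned.  With a fixed seed the search is reproducible.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    d = problem.n_points
    r = float(r)
    n_eval = 0

    def value(idx):
        nonlocal n_eval
        n_eval += 1
        return _delta_sq_core(problem, idx, r).delta_sq

    best_val = -np.inf
    best_idx = None
    per_start = []
    for _ in range(n_starts):
        idx = rng.integers(0, d, size=n)
        cur = value(idx)
        improved = True
        while improved:
            improved = False
            for slot in rng.permutation(n):
                old = idx[slot]
                cand_best, cand_val = old, cur
                for j in range(d):
                    if j == old:
                        continue
                    idx[slot] = j
                    v = value(idx)
                    if v > cand_val + tol:
                        cand_best, cand_val = j, v
                idx[slot] = cand_best
                if cand_best != old:
                    cur = cand_val
                    improved = True
        per_start.append(cur)
        if cur > best_val:
            best_val, best_idx = cur, idx.copy()

    if best_val <= tol:
        warnings.warn(
            "best delta^2 is numerically zero: the models are indistinguishable "
            "at this dilation r (r is at or beyond a set upper bound)",
            UserWarning,
            stacklevel=2,
        )
    return SearchResult(
        best_design=_design_from_indices(problem, best_idx),
        best_delta_sq=float(best_val),
        n_evaluations=n_eval,
        per_start=per_start,
        seed=seed,
        r=r,
        method="kl_exchange",
    )


def exhaustive_search(
    problem: DiscriminationProblem,
    n: int,
    r: float,
    max_multisets: int = 200_000,
) -> SearchResult:
    """Exact optimum by complete enumeration of n-point multisets."""
    d = problem.n_points
    total = math.comb(d + n - 1, n)
    if total > max_multisets:
        raise ValueError(
            f"{total} candidate multisets exceed max_multisets={max_multisets}; "
            "use kl_exchange instead"
        )
    r = float(r)
    best_val, best_idx, n_eval = -np.inf, None, 0
    for combo in combinations_with_replacement(range(d), n):
        idx = np.asarray(combo)
        v = _delta_sq_core(problem, idx, r).delta_sq
        n_eval += 1
        if v > best_val:
            best_val, best_idx = v, idx
    return SearchResult(
        best_design=_design_from_indices(problem, best_idx),
        best_delta_sq=float(best_val),
        n_evaluations=n_eval,
        per_start=[float(best_val)],
        seed=None,
        r=r,
        method="exhaustive",
    )


def efficiency(problem: DiscriminationProblem, design1: ExactDesign,
               design2: ExactDesign, r: float) -> float:
    """Relative delta-efficiency delta_r^2(D1) / delta_r^2(D2)."""
    from .criterion import delta_sq

    d2 = delta_sq(problem, design2, r).delta_sq
    if d2 <= 0:
        raise ValueError("efficiency undefined: delta^2 of the reference design is 0")
    d1 = delta_sq(problem, design1, r).delta_sq
    return d1 / d2
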
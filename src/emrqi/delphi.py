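"""Delphi expert-consultation reliability statistics.

A single-round Delphi consultation asks a panel of experts to rate indicator
importance on a 5-point Likert scale. Four families of statistics summarize
how trustworthy the panel's answers are:

* response rates (positive coefficient, effective rate),
* expert authority: familiarity coefficient Cs, judgment coefficient Ca and
  their average, the authority coefficient Cr (acceptable at >= 0.7),
* per-indicator coefficient of variation (consensus if < 0.25),
* Kendall's coefficient of concordance W across indicators (acceptable > 0.2),
  with tie correction and the chi-square significance approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "ExpertProfile",
    "DEFAULT_FAMILIARITY_SCORES",
    "DEFAULT_JUDGMENT_TABLE",
    "response_rates",
    "familiarity_coefficient",
    "judgment_coefficient",
    "authority_coefficient",
    "coefficient_of_variation",
    "kendalls_w",
]

#: Conventional Delphi familiarity mapping (the score each self-reported
#: familiarity category contributes to Cs).
DEFAULT_FAMILIARITY_SCORES: dict[str, float] = {
    "very_familiar": 1.0,
    "familiar": 0.8,
    "somewhat_familiar": 0.6,
    "unfamiliar": 0.4,
    "very_unfamiliar": 0.2,
}

#: Conventional judgment-basis table: per basis, the score contributed at
#: high / medium / low influence. Rows sum to 1.0 at maximal influence.
DEFAULT_JUDGMENT_TABLE: dict[str, dict[str, float]] = {
    "practical_experience": {"high": 0.5, "medium": 0.4, "low": 0.3},
    "theoretical_analysis": {"high": 0.3, "medium": 0.2, "low": 0.1},
    "peer_knowledge": {"high": 0.1, "medium": 0.1, "low": 0.1},
    "intuition": {"high": 0.1, "medium": 0.1, "low": 0.1},
}


@dataclass
class ExpertProfile:
    """One expert's self-assessment feeding Cs and Ca."""

    expert_id: str
    familiarity: str
    judgment_basis: dict[str, str] = field(default_factory=dict)


@dataclass
class RatingsMatrix:
    """Experts x indicators Likert grid; NaN marks a missing rating."""

    values: pd.DataFrame  # index: expert ids, columns: indicator ids
    scale: tuple[int, int] = (1, 5)

    def __post_init__(self):
        lo, hi = self.scale
        arr = self.values.to_numpy(dtype=float)
        present = arr[~np.isnan(arr)]
        if present.size and ((present < lo) | (present > hi)).any():
            bad = sorted(set(present[(present < lo) | (present > hi)]))
            raise ValueError(f"ratings outside scale [{lo}, {hi}]: {bad}")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RatingsMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df, **kwargs)

    @property
    def n_experts(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]


def response_rates(invited: int, responded: int,
                   valid: int) -> tuple[float, float]:
    """Positive coefficient and effective response rate, both in percent.

    positive = responded / invited * 100; effective = valid / responded * 100.
    A positive coefficient of 70% or higher is conventionally satisfactory.
    """
    if not (0 <= valid <= responded <= invited) or invited <= 0:
        raise ValueError(
            f"counts must satisfy 0 <= valid <= responded <= invited > 0; "
            f"got invited={invited}, responded={responded}, valid={valid}"
        )
    positive = responded / invited * 100.0
    effective = (valid / responded * 100.0) if responded else 0.0
    return positive, effective


def familiarity_coefficient(
    profiles: Sequence[ExpertProfile],
    mapping: Mapping[str, float] | None = None,
) -> float:
    """Cs: mean of the experts' mapped familiarity scores, in [0, 1]."""
    mapping = dict(mapping or DEFAULT_FAMILIARITY_SCORES)
    if not profiles:
        raise ValueError("at least one expert profile required")
    scores = []
    for p in profiles:
        if p.familiarity not in mapping:
            raise ValueError(
                f"expert {p.expert_id}: unknown familiarity category "
                f"{p.familiarity!r} (known: {sorted(mapping)})"
            )
        scores.append(mapping[p.familiarity])
    return float(np.mean(scores))


def judgment_coefficient(
    profiles: Sequence[ExpertProfile],
    basis_table: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Ca: mean over experts of their summed per-basis influence scores."""
    table = {k: dict(v) for k, v in (basis_table or DEFAULT_JUDGMENT_TABLE).items()}
    if not profiles:
        raise ValueError("at least one expert profile required")
    totals = []
    for p in profiles:
        total = 0.0
        for basis, level in p.judgment_basis.items():
            if basis not in table:
                raise ValueError(f"expert {p.expert_id}: unknown judgment basis {basis!r}")
            if level not in table[basis]:
                raise ValueError(
                    f"expert {p.expert_id}: unknown influence level {level!r} "
                    f"for basis {basis!r}"
                )
            total += table[basis][level]
        totals.append(total)
    return float(np.mean(totals))


def authority_coefficient(cs: float, ca: float) -> tuple[float, bool]:
    """Cr = (Cs + Ca) / 2; acceptable when Cr >= 0.7."""
    for label, v in (("Cs", cs), ("Ca", ca)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{label} must lie in [0, 1], got {v}")
    cr = (cs + ca) / 2.0
    return cr, cr >= 0.7


def coefficient_of_variation(ratings: RatingsMatrix,
                             threshold: float = 0.25) -> pd.DataFrame:
    """Per-indicator CV = sample SD / mean (missing ratings dropped pairwise).

    Returns a frame with columns ``cv``, ``n``, ``flagged`` (CV >= threshold)
    and ``defined`` (False when the mean is zero or fewer than two ratings
    are present — reported, never silently dropped).
    """
    rows = []
    for col in ratings.values.columns:
        x = ratings.values[col].dropna().to_numpy(dtype=float)
        n = x.size
        if n < 2 or np.isclose(x.mean(), 0.0):
            rows.append({"indicator": col, "cv": np.nan, "n": n,
                         "flagged": False, "defined": False})
            continue
        cv = x.std(ddof=1) / x.mean()
        rows.append({"indicator": col, "cv": cv, "n": n,
                     "flagged": bool(cv >= threshold), "defined": True})
    return pd.DataFrame(rows).set_index("indicator")


def kendalls_w(ratings: RatingsMatrix) -> tuple[float, float, float]:
    """Kendall's coefficient of concordance with tie correction.

    Experts with any missing rating are excluded listwise. Within each
    expert, ratings are converted to average ranks; with rank sums R_j,

        W = (S - n(n+1)^2 * m^2 / 4... )  -- computed as the tie-corrected
        W = [sum R_j^2 - m^2 n (n+1)^2 / 4] / [m^2 (n^3 - n)/12 - m T /12]

    where T = sum over experts of sum(t^3 - t) across their tie groups.
    Significance uses the chi-square approximation chi2 = m (n - 1) W with
    n - 1 degrees of freedom.

    Returns (W, chi_square, p).
    """
    complete = ratings.values.dropna(axis=0, how="any")
    m, n = complete.shape
    if m < 2 or n < 2:
        raise ValueError(
            f"need >= 2 complete experts and >= 2 indicators, got {m} x {n}"
        )
    ranks = complete.rank(axis=1, method="average").to_numpy()
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum(rank_sums ** 2) - m ** 2 * n * (n + 1) ** 2 / 4.0)
    tie_term = 0.0
    for row in complete.to_numpy():
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = m ** 2 * (n ** 3 - n) / 12.0 - m * tie_term / 12.0
    if denom <= 0:  # every expert rated every indicator identically
        w = 0.0
    else:
        w = s / denom
    w = float(min(max(w, 0.0), 1.0))
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df=n - 1))
    return w, chi2, p
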
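"""Analytic Hierarchy Process weight derivation.

Sibling indicators under a common parent are compared pairwise: mean expert
importance ratings m_i give a judgment matrix a_ij = m_i / m_j (a positive
reciprocal matrix, exactly consistent by construction; optional snapping to
the Saaty 1-9 scale introduces the realistic inconsistency the consistency
ratio guards against). Relative weights are the normalized principal right
eigenvector, obtained by power iteration; absolute weights multiply down the
hierarchy. Every matrix must pass the consistency test CR < 0.1.

Third-level (leaf) groups use the simpler percentage rule by default:
relative weight = mean rating / sum of sibling mean ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .registry import IndexSystem, IndicatorNode

__all__ = [
    "JudgmentMatrix",
    "ConsistencyResult",
    "ConsistencyError",
    "SAATY_RI",
    "judgment_matrix_from_means",
    "principal_eigenvector",
    "row_geometric_mean",
    "consistency_ratio",
    "derive_weights",
]

#: Saaty random-consistency index for matrix orders 1..15 (orders 11-15 from
#: the standard extended tables).
SAATY_RI: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54, 13: 1.56, 14: 1.57, 15: 1.58,
}

_SAATY_LEVELS = np.array(
    [1 / 9, 1 / 8, 1 / 7, 1 / 6, 1 / 5, 1 / 4, 1 / 3, 1 / 2,
     1, 2, 3, 4, 5, 6, 7, 8, 9]
)


class ConsistencyError(ValueError):
    """A judgment matrix failed the CR < 0.1 gate."""


@dataclass
class JudgmentMatrix:
    """Positive reciprocal pairwise-comparison matrix over sibling items."""

    entries: np.ndarray
    item_ids: list[str]

    def __post_init__(self):
        a = np.asarray(self.entries, dtype=float)
        n = a.shape[0]
        if a.ndim != 2 or a.shape != (n, n) or n != len(self.item_ids):
            raise ValueError("judgment matrix must be square and match item_ids")
        if not (a > 0).all():
            raise ValueError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValueError("judgment matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-9):
            raise ValueError("judgment matrix must be reciprocal (a_ij * a_ji = 1)")
        self.entries = a

    @property
    def order(self) -> int:
        return self.entries.shape[0]


@dataclass
class ConsistencyResult:
    lambda_max: float
    CI: float
    RI: float
    CR: float

    @property
    def passed(self) -> bool:
        return self.CR < 0.1


def judgment_matrix_from_means(
    mean_ratings: Mapping[str, float] | Sequence[float],
    snap_to_saaty: bool = False,
) -> JudgmentMatrix:
    """Build the pairwise matrix a_ij = mean_i / mean_j from mean ratings.

    With ``snap_to_saaty`` each off-diagonal ratio is rounded to the nearest
    value on the reciprocal 1-9 scale (reciprocity enforced from the upper
    triangle), mimicking an expert forced onto the discrete scale.
    """
    if isinstance(mean_ratings, Mapping):
        ids = list(mean_ratings)
        means = np.array([mean_ratings[k] for k in ids], dtype=float)
    else:
        means = np.asarray(mean_ratings, dtype=float)
        ids = [f"item{i + 1}" for i in range(means.size)]
    if (means <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(means <= 0)]
        raise ValueError(f"mean ratings must be positive; offending items: {bad}")
    a = means[:, None] / means[None, :]
    if snap_to_saaty:
        n = means.size
        for i in range(n):
            for j in range(i + 1, n):
                snapped = _SAATY_LEVELS[np.argmin(np.abs(_SAATY_LEVELS - a[i, j]))]
                a[i, j] = snapped
                a[j, i] = 1.0 / snapped
    return JudgmentMatrix(entries=a, item_ids=ids)


def principal_eigenvector(
    matrix: JudgmentMatrix,
    tolerance: float = 1e-10,
    max_iterations: int = 1000,
) -> np.ndarray:
    """Normalized (sum = 1) principal right eigenvector by power iteration.

    Positive reciprocal matrices are primitive, so power iteration converges
    to the Perron vector; convergence is declared when successive normalized
    iterates differ by less than ``tolerance`` in max norm.
    """
    a = matrix.entries
    n = matrix.order
    if n == 1:
        return np.array([1.0])
    w = np.full(n, 1.0 / n)
    for _ in range(max_iterations):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tolerance:
            return nxt
        w = nxt
    residual = float(np.max(np.abs(a @ w / (a @ w).sum() - w)))
    raise ArithmeticError(
        f"power iteration failed to converge in {max_iterations} iterations "
        f"(last residual {residual:.3e})"
    )


def row_geometric_mean(matrix: JudgmentMatrix) -> np.ndarray:
    """Row-geometric-mean weights; agrees with the eigenvector when consistent."""
    g = np.exp(np.log(matrix.entries).mean(axis=1))
    return g / g.sum()


def _lambda_max(matrix: JudgmentMatrix, weights: np.ndarray) -> float:
    aw = matrix.entries @ weights
    return float(np.mean(aw / weights))


def consistency_ratio(matrix: JudgmentMatrix) -> ConsistencyResult:
    """CI = (lambda_max - n)/(n - 1); CR = CI / RI(n); CR = 0 for n <= 2."""
    n = matrix.order
    if n > max(SAATY_RI):
        raise ValueError(f"no random index tabulated for order {n} (max {max(SAATY_RI)})")
    w = principal_eigenvector(matrix)
    lam = _lambda_max(matrix, w)
    if n <= 2:
        return ConsistencyResult(lambda_max=lam, CI=0.0, RI=SAATY_RI[n], CR=0.0)
    ci = (lam - n) / (n - 1)
    ri = SAATY_RI[n]
    return ConsistencyResult(lambda_max=lam, CI=ci, RI=ri, CR=ci / ri)


def derive_weights(
    topology: IndexSystem,
    mean_ratings: Mapping[str, float],
    snap_to_saaty: bool = False,
    leaf_rule: str = "percentage",
) -> tuple[IndexSystem, dict[str, ConsistencyResult]]:
    """Derive a fully weighted index system from per-indicator mean ratings.

    ``topology`` supplies the tree shape (its stored weights are ignored);
    ``mean_ratings`` maps every node id (all levels) to the panel's mean
    importance rating. Level-1 and level-2 sibling groups are weighted by the
    AHP eigenvector of their ratio judgment matrix; leaf groups use the
    percentage rule by default (``leaf_rule="ahp"`` switches them to AHP —
    identical for unsnapped ratio matrices).

    Fails closed with :class:`ConsistencyError` if any group's CR >= 0.1.

    Returns the reweighted system and the per-group consistency results
    (keyed by parent id; the level-1 group is keyed ``"<root>"``).
    """
    if leaf_rule not in ("percentage", "ahp"):
        raise ValueError(f"unknown leaf_rule {leaf_rule!r}")

    groups: list[tuple[str, list[IndicatorNode]]] = [("<root>", topology.level(1))]
    for parent in topology.level(1) + topology.level(2):
        kids = topology.children(parent.id)
        if kids:
            groups.append((parent.id, kids))

    relative: dict[str, float] = {}
    consistency: dict[str, ConsistencyResult] = {}
    for parent_id, members in groups:
        ids = [n.id for n in members]
        missing = [i for i in ids if i not in mean_ratings]
        if missing:
            raise ValueError(f"group {parent_id}: missing mean ratings for {missing}")
        means = {i: float(mean_ratings[i]) for i in ids}
        is_leaf_group = members[0].level == 3
        if is_leaf_group and leaf_rule == "percentage":
            total = sum(means.values())
            if total <= 0:
                raise ValueError(f"group {parent_id}: nonpositive rating total")
            for i in ids:
                relative[i] = means[i] / total
            continue
        jm = judgment_matrix_from_means(means, snap_to_saaty=snap_to_saaty)
        res = consistency_ratio(jm)
        consistency[parent_id] = res
        if not res.passed:
            raise ConsistencyError(
                f"group {parent_id}: CR = {res.CR:.4f} >= 0.1; judgment matrix rejected"
            )
        w = principal_eigenvector(jm)
        for i, wi in zip(ids, w):
            relative[i] = float(wi)

    absolute: dict[str, float] = {}
    for node in topology.level(1):
        absolute[node.id] = relative[node.id]
    for level in (2, 3):
        for node in topology.level(level):
            absolute[node.id] = relative[node.id] * absolute[node.parent_id]

    new_nodes = {
        nid: IndicatorNode(
            id=n.id, name=n.name, level=n.level, parent_id=n.parent_id,
            calculator_id=n.calculator_id, absolute_weight=absolute[nid],
        )
        for nid, n in topology.nodes.items()
    }
    system = IndexSystem(nodes=new_nodes, name=topology.name,
                         version=topology.version + "+derived",
                         provenance="weights derived from panel mean ratings")
    return system, consistency
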
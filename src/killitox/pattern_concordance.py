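"""Trend-pattern grouping and gene-behavior concordance.

Each endpoint (gene or behavior) is summarized as a trend vector: its
ordered Pos/Neg/NS calls over the comparison plan, encoded +/-/0.  Endpoints
whose vectors are identical respond the same across all treatment
comparisons and are grouped; genes and behaviors are then matched when their
vectors are element-wise identical ("original" match) or element-wise
negated ("opposite" match).  Vectors with no significant entry are
ineligible: an all-NS endpoint carries no treatment pattern to match.

Strict matching (the default) requires equality on every plan position,
zeros included, because the full treatment pattern is what is being
compared.  A relaxed mode compares only positions where at least one of the
two vectors is significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .treatment_stats import ComparisonPlan

_CALL_TO_SYMBOL = {"Pos": "+", "Neg": "-", "NS": "0"}
_SYMBOL_TO_CALL = {v: k for k, v in _CALL_TO_SYMBOL.items()}
_NEGATE = {"+": "-", "-": "+", "0": "0"}


@dataclass(frozen=True)
class TrendVector:
    """Ordered +/-/0 calls for one endpoint over the comparison plan."""

    id: str
    calls: tuple[str, ...]
    kind: str = "behavior"  # or "gene"

    def __post_init__(self) -> None:
        if any(c not in ("+", "-", "0") for c in self.calls):
            raise ValueError("trend-vector entries must be '+', '-' or '0'")
        if self.kind not in ("gene", "behavior"):
            raise ValueError("kind must be 'gene' or 'behavior'")

    @property
    def eligible(self) -> bool:
        """Eligible for matching: at least one significant (non-zero) entry."""
        return any(c != "0" for c in self.calls)

    @property
    def pattern(self) -> str:
        return "".join(self.calls)

    def negated(self) -> "TrendVector":
        return TrendVector(self.id, tuple(_NEGATE[c] for c in self.calls), self.kind)

    def decode(self) -> list[str]:
        """Back to Pos/Neg/NS calls in plan order."""
        return [_SYMBOL_TO_CALL[c] for c in self.calls]


def encode_trend_vector(
    calls: pd.DataFrame,
    plan: ComparisonPlan,
    kind: str = "behavior",
    id_column: str | None = None,
) -> list[TrendVector]:
    """Encode per-comparison Pos/Neg/NS calls into trend vectors.

    ``calls`` has columns ``endpoint`` or ``gene`` (auto-detected, or pass
    ``id_column``), ``comparison`` and ``call``.  Comparisons missing for an
    id encode as 0; conflicting duplicate calls for one (id, comparison)
    raise.
    """
    if id_column is None:
        id_column = "gene" if "gene" in calls.columns else "endpoint"
    order = plan.comparison_ids
    vectors = []
    for ident, df in calls.groupby(id_column, sort=True):
        symbols = {}
        for _, row in df.iterrows():
            comp, call = row["comparison"], row["call"]
            if comp not in order:
                raise ValueError(f"call references comparison {comp!r} outside the plan")
            sym = _CALL_TO_SYMBOL[call]
            if comp in symbols and symbols[comp] != sym:
                raise ValueError(f"conflicting duplicate calls for ({ident!r}, {comp!r})")
            symbols[comp] = sym
        vectors.append(
            TrendVector(str(ident), tuple(symbols.get(c, "0") for c in order), kind)
        )
    return vectors


def group_by_pattern(vectors: Iterable[TrendVector]) -> list[tuple[str, list[str]]]:
    """Partition eligible ids by identical trend vector.

    Returns ``(pattern, ids)`` groups ordered by decreasing size, ties broken
    lexicographically by pattern; ids within a group are sorted.
    """
    groups: dict[str, list[str]] = {}
    for v in vectors:
        if not v.eligible:
            continue
        groups.setdefault(v.pattern, []).append(v.id)
    return sorted(
        ((pat, sorted(ids)) for pat, ids in groups.items()),
        key=lambda g: (-len(g[1]), g[0]),
    )


def match_gene_behavior(
    gene_vectors: Iterable[TrendVector],
    behavior_vectors: Iterable[TrendVector],
    allow_opposite: bool = False,
    strict: bool = True,
) -> pd.DataFrame:
    """Match genes to behavior endpoints by shared treatment pattern.

    A pair matches "original" when the vectors are element-wise identical
    and "opposite" when element-wise negated (only if ``allow_opposite``).
    All-NS vectors never match.  In relaxed mode (``strict=False``) only
    positions where at least one of the two vectors is non-zero are
    compared.

    Returns columns ``gene``, ``behavior``, ``pattern``, ``match_type``.
    """
    gene_vectors = [v for v in gene_vectors if v.eligible]
    behavior_vectors = [v for v in behavior_vectors if v.eligible]
    rows = []
    for g in gene_vectors:
        for b in behavior_vectors:
            if _vectors_equal(g.calls, b.calls, strict):
                rows.append((g.id, b.id, g.pattern, "original"))
            elif allow_opposite and _vectors_equal(g.negated().calls, b.calls, strict):
                rows.append((g.id, b.id, g.pattern, "opposite"))
    return pd.DataFrame(rows, columns=["gene", "behavior", "pattern", "match_type"])


def _vectors_equal(a: tuple[str, ...], b: tuple[str, ...], strict: bool) -> bool:
    if len(a) != len(b):
        raise ValueError("trend vectors must share the plan length")
    if strict:
        return a == b
    compared = [(x, y) for x, y in zip(a, b) if x != "0" or y != "0"]
    return bool(compared) and all(x == y for x, y in compared)
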
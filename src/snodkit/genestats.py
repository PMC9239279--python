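"""Functional-category and length statistics of specific genes.

Summaries operate on :class:`~snodkit.io.SpecificGeneRecord` lists such as
the packaged annotation table. Quartiles use linear interpolation at
positions 1 + p(n-1) (the numpy default), and the "at least" length count
is inclusive.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .io import MappingTool, SpecificGeneRecord

__all__ = [
    "no_hit_subset",
    "hit_subset",
    "length_stats",
    "count_at_least",
    "category_counts",
    "product_count",
    "category_summary",
]


def no_hit_subset(records: list[SpecificGeneRecord]) -> list[SpecificGeneRecord]:
    """Records without any database hit (mapping tool ``none``)."""
    return [r for r in records if r.mapping_tool is MappingTool.NONE]


def hit_subset(records: list[SpecificGeneRecord]) -> list[SpecificGeneRecord]:
    """Complement of :func:`no_hit_subset`."""
    return [r for r in records if r.mapping_tool is not MappingTool.NONE]


def length_stats(records: list[SpecificGeneRecord]) -> tuple[float, float]:
    """Median and interquartile range of protein lengths (aa)."""
    if not records:
        raise ValueError("length_stats on an empty record list")
    lengths = np.array([r.length_aa for r in records], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1)


def count_at_least(records: list[SpecificGeneRecord], threshold: int = 100) -> int:
    """Number of records with length >= ``threshold`` aa (inclusive)."""
    return sum(1 for r in records if r.length_aa >= threshold)


def _norm(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip()).lower()


def category_counts(
    records: list[SpecificGeneRecord],
    category: str,
    group: str | None = None,
) -> int:
    """Number of records in ``category`` (case/whitespace-normalised),
    optionally within one group block; unknown categories count 0 with a
    warning."""
    scope = [r for r in records if group is None or r.group == group]
    want = _norm(category)
    known = {_norm(r.category) for r in records}
    if want not in known:
        warnings.warn(f"category {category!r} not present in the table", stacklevel=2)
        return 0
    return sum(1 for r in scope if _norm(r.category) == want)


def product_count(
    records: list[SpecificGeneRecord],
    product: str,
    group: str | None = None,
) -> int:
    """Number of records whose product description equals ``product``."""
    want = _norm(product)
    return sum(
        1
        for r in records
        if (group is None or r.group == group) and _norm(r.product) == want
    )


def category_summary(
    records: list[SpecificGeneRecord],
) -> dict[str, dict[str, int]]:
    """Per-group category counts plus a ``total`` row."""
    out: dict[str, dict[str, int]] = {}
    for r in records:
        out.setdefault(r.group, {})
        out[r.group][r.category] = out[r.group].get(r.category, 0) + 1
        out.setdefault("total", {})
        out["total"][r.category] = out["total"].get(r.category, 0) + 1
    return out
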
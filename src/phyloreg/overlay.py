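"""Phyloregulatory overlay: binary feature calls and per-subfamily enrichment.

Elements receive binary calls per regulatory mark from peak-interval
overlap, top-septile signal, or an expression threshold; calls are then
aggregated per subfamily and compared with chi-square (Fisher fallback
for sparse tables) under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Element, GenomicInterval
from .subfamily import Partition

PEAK_OVERLAP = "peak_overlap"
SEPTILE = "septile"
EXPRESSION = "expression_threshold"


def _calls_frame(rows):
    return pd.DataFrame(rows, columns=["element_id", "mark", "call", "source"])


def _intervals(elements):
    for e in elements:
        if isinstance(e, Element):
            yield e.id, e.interval
        else:
            yield e  # (id, GenomicInterval)


def merge_intervals(peaks: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [tuple(x) for x in out]
    return merged


def total_overlap(elements, peaks: list[GenomicInterval]) -> dict[str, int]:
    """Total merged-peak overlap in bp per element, by sorted sweep."""
    merged = merge_intervals(peaks)
    out = {}
    per_chrom: dict[str, list] = {}
    for eid, iv in _intervals(elements):
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, eid))
        out[eid] = 0
    from bisect import bisect_right

    for chrom, elems in per_chrom.items():
        elems.sort()
        pk = merged.get(chrom, [])
        ends = [e for _, e in pk]
        for start, end, eid in elems:
            # merged peaks are disjoint and sorted, so ends are sorted too
            k = bisect_right(ends, start)
            acc = 0
            while k < len(pk) and pk[k][0] < end:
                acc += min(end, pk[k][1]) - max(start, pk[k][0])
                k += 1
            out[eid] = acc
    return out


def call_peak_overlap(
    elements,
    peaks: list[GenomicInterval],
    mark: str = "mark",
    min_bp: int = 1,
    min_frac: float = 0.0,
) -> pd.DataFrame:
    """Binary call per element from peak overlap.

    bp mode (default): positive iff total overlap >= ``min_bp``.
    fraction mode (``min_frac`` > 0): positive iff overlap / element
    length >= ``min_frac``.
    """
    ov = total_overlap(elements, peaks)
    rows = []
    for eid, iv in _intervals(elements):
        if min_frac > 0:
            call = int(ov[eid] / (iv.end - iv.start) >= min_frac)
        else:
            call = int(ov[eid] >= min_bp)
        rows.append((eid, mark, call, PEAK_OVERLAP))
    return _calls_frame(rows)


def call_top_septile(signal: dict, mark: str = "GRO-seq", elements=None) -> pd.DataFrame:
    """Top-septile signal call: positive iff signal >= the 6/7 quantile.

    Boundary ties are all included.  Elements absent from ``signal`` are
    treated as 0 with a warning.
    """
    ids = list(elements) if elements is not None else list(signal)
    if len(ids) < 7:
        raise ValueError("need >= 7 elements for septiles")
    missing = [e for e in ids if e not in signal]
    if missing:
        warnings.warn(f"{len(missing)} element(s) missing signal, treated as 0")
    vals = np.array([float(signal.get(e, 0.0)) for e in ids])
    thresh = np.quantile(vals, 6.0 / 7.0, method="higher")
    if np.all(vals == vals[0]):
        warnings.warn("degenerate signal: all values equal, all called positive")
    rows = [(e, mark, int(v >= thresh), SEPTILE) for e, v in zip(ids, vals)]
    return _calls_frame(rows)


def call_expression(
    fpkm: dict, threshold: float = 2.0, mark: str = "RNA-seq", elements=None
) -> pd.DataFrame:
    """Highly-transcribed call: positive iff fpkm strictly exceeds threshold."""
    ids = list(elements) if elements is not None else list(fpkm)
    rows = [
        (e, mark, int(float(fpkm.get(e, 0.0)) > threshold), EXPRESSION) for e in ids
    ]
    return _calls_frame(rows)


def calls_matrix(calls: pd.DataFrame, elements=None) -> pd.DataFrame:
    """elements x marks 0/1 matrix; absent rows count as negative."""
    mat = calls.pivot_table(
        index="element_id", columns="mark", values="call", aggfunc="max", fill_value=0
    )
    if elements is not None:
        mat = mat.reindex(list(elements), fill_value=0)
    return mat.astype(int)


def subfamily_proportions(calls: pd.DataFrame, partition: Partition) -> pd.DataFrame:
    """subfamily x mark proportion of positive members.

    Members without a call row are negative; unassigned elements are
    excluded; empty subfamilies give NA."""
    marks = sorted(calls["mark"].unique())
    mat = calls_matrix(calls)
    data = {}
    for name in partition.subfamilies():
        members = partition.members(name)
        if not members:
            data[name] = [np.nan] * len(marks)
            continue
        sub = mat.reindex(members, fill_value=0)
        data[name] = [float(sub[m].mean()) if m in sub else 0.0 for m in marks]
    return pd.DataFrame(data, index=marks).T


@dataclass
class EnrichmentResult:
    mark: str
    group_a: str
    group_b: str
    table: tuple  # ((a_pos, a_neg), (b_pos, b_neg))
    chi2: float
    p: float
    padj: float
    n_tests: int
    method: str = "chi2"


def enrichment_tests(
    calls: pd.DataFrame,
    partition: Partition,
    focal_group: str,
    marks: list[str] | None = None,
    comparators: list[str] | None = None,
) -> list[EnrichmentResult]:
    """2x2 chi-square (no continuity correction) of positive/negative x
    focal/comparator per (mark, comparator) pair.

    Bonferroni n = the number of tests performed in this invocation.
    When any expected cell < 1 the Fisher exact test substitutes, flagged
    in ``method``.  Results are sorted by padj.
    """
    marks = marks or sorted(calls["mark"].unique())
    comparators = comparators or [
        s for s in partition.subfamilies() if s != focal_group
    ]
    mat = calls_matrix(calls)
    focal_members = partition.members(focal_group)
    if not focal_members:
        raise ValueError(f"focal group {focal_group!r} is empty")
    results = []
    for mark in marks:
        col = mat[mark] if mark in mat else pd.Series(0, index=mat.index)
        f = col.reindex(focal_members, fill_value=0)
        for comp in comparators:
            members = partition.members(comp)
            if not members:
                raise ValueError(f"comparator group {comp!r} is empty")
            c = col.reindex(members, fill_value=0)
            table = np.array(
                [[int(f.sum()), int(len(f) - f.sum())],
                 [int(c.sum()), int(len(c) - c.sum())]]
            )
            method = "chi2"
            expected = stats.contingency.expected_freq(table) if table.sum() else None
            if expected is None or (expected < 1).any():
                odds, p = stats.fisher_exact(table)
                chi2 = np.nan
                method = "fisher"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            results.append(
                EnrichmentResult(
                    mark, focal_group, comp,
                    tuple(map(tuple, table.tolist())),
                    float(chi2), float(p), np.nan, 0, method,
                )
            )
    n = len(results)
    for r in results:
        r.n_tests = n
        r.padj = min(1.0, r.p * n)
    results.sort(key=lambda r: (r.padj, r.p, r.mark, r.group_b))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mark": [r.mark for r in results],
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "a_pos": [r.table[0][0] for r in results],
            "a_neg": [r.table[0][1] for r in results],
            "b_pos": [r.table[1][0] for r in results],
            "b_neg": [r.table[1][1] for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
            "method": [r.method for r in results],
        }
    )
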
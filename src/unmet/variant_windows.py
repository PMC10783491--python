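"""Windowed variant statistics and reliable/unreliable site labeling.

Two indicators summarize the variant catalog around each position p over
the closed window [p−N, p+N] (2N+1 bp, default 25):

* VD (variant density) — count of observed variant records in the window
  divided by the window size 2N+1. Records are counted per alternate
  allele, so a biallelic position contributes 2.
* VFR (variant filter rate) — filtered records divided by all records in
  the window; undefined when the window holds no variants.

Ground-truth labels: a variant position inside a CDS is *unreliable*
(positive) when its window has VFR = 1.0 and VD ≥ 0.12 (at least three
variants in 25 bp) and the focal variant itself is filtered; *reliable*
(negative) when VFR = 0.0, VD ≥ 0.12 and the focal variant passed. Only
SNV positions are labeled; indel positions are held out for evaluation.
The focal variant is counted in its own window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FILTERED, IntervalSet, PASSED, SNV, VariantSite

logger = logging.getLogger("unmet")

UNRELIABLE = "unreliable"
RELIABLE = "reliable"

DEFAULT_FLANK = 12
DEFAULT_VD_MIN = 0.12


@dataclass(frozen=True)
class SiteWindowStats:
    """VD/VFR and raw counts for one position's 2N+1 window.

    ``vfr`` is None when the window contains no variants (VD = 0)."""

    chrom: str
    pos: int
    n_variants: int
    n_filtered: int
    vd: float
    vfr: float | None


@dataclass(frozen=True)
class LabeledSite:
    """A labeled training position with its originating window stats."""

    chrom: str
    pos: int
    label: str
    stats: SiteWindowStats


class _ChromIndex:
    """Sorted per-chromosome arrays of variant positions and filter flags."""

    def __init__(self, sites: Sequence[VariantSite]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[VariantSite]] = {}
        for s in sites:
            grouped.setdefault(s.chrom, []).append(s)
        for chrom, group in grouped.items():
            group.sort(key=lambda s: s.pos)
            pos = np.array([s.pos for s in group], dtype=np.int64)
            filt = np.array([s.status == FILTERED for s in group], dtype=np.int64)
            csum = np.concatenate([[0], np.cumsum(filt)])
            self.by_chrom[chrom] = (pos, filt, csum)

    def counts(self, chrom: str, position: int, flank: int) -> tuple[int, int]:
        if chrom not in self.by_chrom:
            return 0, 0
        pos, _filt, csum = self.by_chrom[chrom]
        lo = int(np.searchsorted(pos, position - flank, side="left"))
        hi = int(np.searchsorted(pos, position + flank, side="right"))
        return hi - lo, int(csum[hi] - csum[lo])


def _stats(chrom: str, position: int, n: int, nf: int, flank: int) -> SiteWindowStats:
    width = 2 * flank + 1
    vd = n / width
    vfr = (nf / n) if n > 0 else None
    return SiteWindowStats(chrom, position, n, nf, vd, vfr)


def window_stats(
    sites: Sequence[VariantSite],
    position: int,
    flank: int = DEFAULT_FLANK,
    chrom: str | None = None,
) -> SiteWindowStats:
    """VD/VFR for the closed window [position−N, position+N].

    Every variant record (per alternate allele) whose position falls in
    the window is counted. The VD denominator is always 2N+1, even when
    the window overhangs a chromosome end (truncation affects only which
    variants can exist). With no variants in the window, VD = 0 and VFR
    is None (undefined).
    """
    if chrom is None:
        chroms = {s.chrom for s in sites}
        if len(chroms) > 1:
            raise ValueError("sites span multiple chromosomes; pass chrom explicitly")
        chrom = next(iter(chroms)) if chroms else ""
    idx = _ChromIndex(sites)
    n, nf = idx.counts(chrom, position, flank)
    return _stats(chrom, position, n, nf, flank)


def label_sites(
    sites: Sequence[VariantSite],
    cds: IntervalSet,
    flank: int = DEFAULT_FLANK,
    vd_min: float = DEFAULT_VD_MIN,
) -> list[LabeledSite]:
    """Label CDS SNV positions as unreliable/reliable from their windows.

    Labels attach to deduplicated positions, not alleles. All variant
    records (SNV and indel, inside or outside the CDS) contribute to
    window counts; only positions carrying at least one SNV record and
    lying inside a CDS interval are candidates for labels. Positions
    whose window has 0 < VFR < 1 or VD below ``vd_min`` stay unlabeled.
    """
    if len(cds) == 0:
        raise ValueError("CDS interval set is empty")
    idx = _ChromIndex(sites)

    # candidate positions: deduplicated SNV positions with focal statuses
    focal: dict[tuple[str, int], set[str]] = {}
    for s in sites:
        if s.var_class == SNV:
            focal.setdefault((s.chrom, s.pos), set()).add(s.status)

    labeled: list[LabeledSite] = []
    by_chrom: dict[str, list[tuple[int, set[str]]]] = {}
    for (chrom, pos), statuses in focal.items():
        by_chrom.setdefault(chrom, []).append((pos, statuses))
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        positions = np.array([p for p, _ in entries], dtype=np.int64)
        in_cds = cds.contains(chrom, positions)
        for (pos, statuses), ok in zip(entries, in_cds):
            if not ok:
                continue
            n, nf = idx.counts(chrom, pos, flank)
            st = _stats(chrom, pos, n, nf, flank)
            if st.vfr is None or st.vd < vd_min:
                continue
            if st.vfr == 1.0 and FILTERED in statuses:
                labeled.append(LabeledSite(chrom, pos, UNRELIABLE, st))
            elif st.vfr == 0.0 and PASSED in statuses:
                labeled.append(LabeledSite(chrom, pos, RELIABLE, st))
    return labeled


def labels_to_frame(labeled: Sequence[LabeledSite]) -> pd.DataFrame:
    """Labels as a table (pos reported 1-based for the TSV interface)."""
    rows = [
        {
            "chrom": ls.chrom,
            "pos": ls.pos + 1,
            "label": ls.label,
            "n_variants": ls.stats.n_variants,
            "n_filtered": ls.stats.n_filtered,
            "VD": ls.stats.vd,
            "VFR": ls.stats.vfr,
        }
        for ls in labeled
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "label", "n_variants", "n_filtered", "VD", "VFR"]
    )


def catalog_summary(sites: Sequence[VariantSite], cds: IntervalSet) -> pd.DataFrame:
    """Descriptive counts over CDS positions with observed variants.

    Reports how many CDS positions carry variants and, of those, the
    fractions with passed-only records, with at least one filtered
    record, with mixed passed+filtered records, and with two or more
    filtered records (recurrent)."""
    statuses: dict[tuple[str, int], list[str]] = {}
    for s in sites:
        statuses.setdefault((s.chrom, s.pos), []).append(s.status)
    by_chrom: dict[str, list[tuple[int, list[str]]]] = {}
    for (chrom, pos), st in statuses.items():
        by_chrom.setdefault(chrom, []).append((pos, st))

    cds_positions = cds.total_length()
    n_with = n_passed_only = n_with_filtered = n_mixed = n_recurrent = 0
    for chrom, entries in by_chrom.items():
        positions = np.array([p for p, _ in entries], dtype=np.int64)
        in_cds = cds.contains(chrom, positions)
        for (pos, st), ok in zip(entries, in_cds):
            if not ok:
                continue
            n_with += 1
            nf = sum(1 for x in st if x == FILTERED)
            if nf == 0:
                n_passed_only += 1
            else:
                n_with_filtered += 1
                if nf < len(st):
                    n_mixed += 1
                if nf >= 2:
                    n_recurrent += 1

    def frac(num: int, den: int) -> float:
        return num / den if den else 0.0

    rows = [
        ("cds_positions", cds_positions, 1.0),
        ("positions_with_variants", n_with, frac(n_with, cds_positions)),
        ("passed_only", n_passed_only, frac(n_passed_only, n_with)),
        ("with_filtered", n_with_filtered, frac(n_with_filtered, n_with)),
        ("mixed", n_mixed, frac(n_mixed, n_with)),
        ("recurrent_filtered", n_recurrent, frac(n_recurrent, n_with)),
    ]
    return pd.DataFrame(rows, columns=["metric", "count", "fraction"])
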
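"""Grouping significant markers into QTL regions."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class QtlRegion:
    chrom: str
    start: int              # 1-based inclusive
    end: int
    peak_marker: str
    peak_p: float
    peak_pos: int = 0
    environments: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start exceeds end")


def call_qtl_regions(
    assoc: pd.DataFrame,
    fdr: float = 0.05,
    window: int = 50_000,
    environment: str | None = None,
) -> list[QtlRegion]:
    """Greedy peak-centred grouping of markers significant at q < fdr.

    Markers on the same chromosome within ``window`` bp of a group's peak
    join that group; the region spans its member markers and the peak is
    the member with the smallest p (ties: leftmost position).  The result
    is independent of the input row order.
    """
    sig = assoc[assoc["q"] < fdr].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")
    regions: list[QtlRegion] = []
    assigned = pd.Series(False, index=sig.index)
    for marker in sig.index:
        if assigned[marker]:
            continue
        peak = sig.loc[marker]
        members = sig[
            (sig["chrom"] == peak["chrom"])
            & ((sig["pos"] - peak["pos"]).abs() <= window)
            & ~assigned
        ]
        assigned[members.index] = True
        envs = frozenset([environment]) if environment else frozenset()
        regions.append(
            QtlRegion(
                chrom=str(peak["chrom"]),
                start=int(members["pos"].min()),
                end=int(members["pos"].max()),
                peak_marker=str(marker),
                peak_p=float(peak["p"]),
                peak_pos=int(peak["pos"]),
                environments=envs,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def merge_region_peaks(per_env_regions: dict[str, list[QtlRegion]],
                       window: int = 50_000) -> list[QtlRegion]:
    """Merge per-environment regions that share a peak neighbourhood.

    Used to build the candidate-locus pool for the multi-environment growth
    genetic model: regions from different environments whose peaks lie
    within ``window`` bp on the same chromosome collapse to the single
    region with the smallest peak p, with environments unioned.
    """
    flat: list[QtlRegion] = []
    for env, regs in per_env_regions.items():
        for r in regs:
            flat.append(QtlRegion(r.chrom, r.start, r.end, r.peak_marker, r.peak_p,
                                  r.peak_pos, frozenset([env]) | r.environments))
    flat.sort(key=lambda r: (r.peak_p, r.chrom, r.start))
    merged: list[QtlRegion] = []
    for r in flat:
        hit = None
        for i, m in enumerate(merged):
            if m.chrom == r.chrom and abs(r.peak_pos - m.peak_pos) <= window:
                hit = i
                break
        if hit is None:
            merged.append(r)
        else:
            m = merged[hit]
            merged[hit] = QtlRegion(
                m.chrom, min(m.start, r.start), max(m.end, r.end),
                m.peak_marker, m.peak_p, m.peak_pos, m.environments | r.environments,
            )
    merged.sort(key=lambda r: (r.chrom, r.start))
    return merged
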
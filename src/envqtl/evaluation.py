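"""Benchmark-harness utilities that compare rankings with simulation labels.

These helpers consume the ground-truth role table that the simulator emits
alongside a synthetic dataset.  The analysis pipeline itself never reads
those labels; only evaluation harnesses (tests, benchmark reports) do.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data import GenotypeMatrix
from .growth import Term

CONFUSER_ROLES = ("side_effect", "dependent", "consequence")


def nearest_true_marker(term_marker: str, qtl_markers: list[str],
                        marker_map: pd.DataFrame) -> str | None:
    """Map a detected peak marker to the same-chromosome true QTL marker."""
    ch = marker_map.at[term_marker, "chrom"]
    pos = marker_map.at[term_marker, "pos"]
    cands = [m for m in qtl_markers if marker_map.at[m, "chrom"] == ch]
    if not cands:
        return None
    return min(cands, key=lambda m: abs(marker_map.at[m, "pos"] - pos))


def mediator_auroc(
    per_term_ranked: dict[Term, pd.DataFrame],
    roles: pd.DataFrame,
    qtl_markers: list[str],
    genotypes: GenotypeMatrix,
) -> tuple[float, dict[Term, float]]:
    """AUROC of true mediators vs all other genotype-associated genes.

    Per term, positives are the mediators of the matching true QTL and
    negatives every side-effect, environment-dependent and consequence gene;
    mediators of other QTLs and pure-noise genes are excluded.  Returns the
    across-term mean and per-term values.
    """
    per_term: dict[Term, float] = {}
    neg_genes = set(roles[roles["role"].isin(CONFUSER_ROLES)].index)
    for term, ranked in per_term_ranked.items():
        tm = nearest_true_marker(term[0], qtl_markers, genotypes.marker_map)
        pos_genes = set(roles[(roles["role"] == "mediator")
                              & (roles["marker"] == tm)].index)
        if not pos_genes:
            continue
        sub = ranked[ranked["gene"].isin(pos_genes | neg_genes)]
        y = sub["gene"].isin(pos_genes).astype(int).to_numpy()
        per_term[term] = float(roc_auc_score(y, sub["posterior"].to_numpy()))
    mean = float(np.mean(list(per_term.values()))) if per_term else float("nan")
    return mean, per_term
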
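"""Directional validation of candidate rankings against deletion fitness.

A candidate gene validates when its deletion has a significant fitness
effect in the relevant environment AND the effect's direction is consistent
with the candidate's expression-growth correlation: expression positively
correlated with growth implies the deletion should be detrimental, and vice
versa.  Fold enrichment compares the top-n validation rate to the rate
expected for a random selection of assayed genes carrying random directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import Term


def _call_lookup(calls: pd.DataFrame, environment: str) -> pd.Series:
    sub = calls[calls["environment"] == environment]
    return sub.set_index("gene")["call"]


def background_rate(calls: pd.DataFrame, environment: str,
                    ignore_direction: bool = False) -> float:
    """Validation rate of a random gene in one environment.

    With direction matching, a random candidate carries a random direction,
    so only half of the significant calls would validate it.
    """
    lut = _call_lookup(calls, environment)
    if len(lut) == 0:
        return float("nan")
    sig = float((lut != "none").mean())
    return sig if ignore_direction else sig / 2.0


def validates(direction: int, call: str, ignore_direction: bool = False) -> bool:
    if call == "none" or pd.isna(call):
        return False
    if ignore_direction:
        return True
    if direction > 0:
        return call == "detrimental"
    if direction < 0:
        return call == "beneficial"
    return False


@dataclass
class ValidationResult:
    term: Term
    top_n: int
    n_validated: int
    rate: float
    background: float
    fold_enrichment: float


def validation_rate(
    ranked: pd.DataFrame,
    calls: pd.DataFrame,
    environment: str,
    top_n: int = 100,
    ignore_direction: bool = False,
    term: Term = ("", ""),
) -> ValidationResult:
    """Directional validation of the top-n candidates of one ranking.

    ``ranked`` must have columns gene and direction, ordered best-first and
    restricted (or restrictable) to genes present in the deletion calls.
    """
    lut = _call_lookup(calls, environment)
    cand = ranked[ranked["gene"].isin(lut.index)]
    if top_n > len(cand):
        top_n = len(cand)
    top = cand.head(top_n)
    n_val = sum(
        validates(int(d), lut.get(g, "none"), ignore_direction)
        for g, d in zip(top["gene"], top["direction"])
    )
    bg = background_rate(calls, environment, ignore_direction)
    rate = n_val / top_n if top_n else float("nan")
    fold = rate / bg if bg and bg > 0 else float("nan")
    return ValidationResult(term, top_n, n_val, rate, bg, fold)


def jackknife_enrichment(per_qtl_rates: list[float]) -> tuple[float, float]:
    """Leave-one-out mean and jackknife standard deviation over QTLs."""
    rates = np.asarray(per_qtl_rates, dtype=float)
    m = len(rates)
    if m < 2:
        raise ValueError("jackknife requires at least 2 QTLs")
    loo = np.array([np.delete(rates, i).mean() for i in range(m)])
    mean = float(rates.mean())
    sd = math.sqrt((m - 1) / m * float(((loo - loo.mean()) ** 2).sum()))
    return mean, sd


def enrichment_curve(
    ranked: pd.DataFrame,
    calls: pd.DataFrame,
    environment: str,
    ignore_direction: bool = False,
) -> pd.DataFrame:
    """Cumulative validated count vs number predicted, plus random expectation."""
    lut = _call_lookup(calls, environment)
    cand = ranked[ranked["gene"].isin(lut.index)]
    flags = np.array([
        validates(int(d), lut.get(g, "none"), ignore_direction)
        for g, d in zip(cand["gene"], cand["direction"])
    ])
    n = np.arange(1, len(cand) + 1)
    bg = background_rate(calls, environment, ignore_direction)
    return pd.DataFrame({
        "n_predicted": n,
        "n_validated": np.cumsum(flags),
        "expected_random": bg * n,
    })


def pooled_enrichment_curve(
    per_term_ranked: dict[Term, pd.DataFrame],
    calls: pd.DataFrame,
    score_column: str = "posterior",
    ascending: bool = False,
    ignore_direction: bool = False,
) -> pd.DataFrame:
    """Enrichment curve pooled across growth-model terms.

    Candidate (gene, term) pairs from all terms are interleaved by
    prediction confidence; each pair is validated in its own term's
    environment.  The random expectation accumulates each environment's
    background rate.
    """
    frames = []
    for term, ranked in per_term_ranked.items():
        lut = _call_lookup(calls, term[1])
        sub = ranked[ranked["gene"].isin(lut.index)].copy()
        sub["environment"] = term[1]
        sub["validated"] = [
            validates(int(d), lut.get(g, "none"), ignore_direction)
            for g, d in zip(sub["gene"], sub["direction"])
        ]
        sub["background"] = background_rate(calls, term[1], ignore_direction)
        sub["_score"] = sub[score_column]
        frames.append(sub[["gene", "environment", "_score", "validated", "background"]])
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values(["_score", "gene", "environment"],
                            ascending=[ascending, True, True], kind="mergesort")
    pool = pool.reset_index(drop=True)
    return pd.DataFrame({
        "n_predicted": np.arange(1, len(pool) + 1),
        "n_validated": np.cumsum(pool["validated"].to_numpy()),
        "expected_random": np.cumsum(pool["background"].to_numpy()),
        "gene": pool["gene"],
        "environment": pool["environment"],
    })


def curve_value_at(curve: pd.DataFrame, n: int) -> float:
    """Validated count at n predicted (last row if the curve is shorter)."""
    if curve.empty:
        return float("nan")
    idx = min(n, len(curve)) - 1
    return float(curve["n_validated"].iloc[idx])
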
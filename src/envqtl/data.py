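"""Core in-memory containers shared across the pipeline.

Genotypes are biallelic allele codes for haploid meiotic segregants of a
two-parent cross: 0 denotes the laboratory-strain (S) allele and 1 the
clinical-isolate (Y) allele.  Phenotypes are a complete growth-rate table
(segregant x environment) plus an expression tensor stored as one
segregant x gene matrix per environment; unprofiled cells are NaN, which
encodes the checkered profiling design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InvalidDesignError(ValueError):
    """Raised when a simulation design or data container is inconsistent."""


@dataclass
class GenotypeMatrix:
    """Segregant x marker allele codes with a genomic marker map.

    Parameters
    ----------
    alleles : pandas.DataFrame
        Rows are segregants, columns are marker ids, entries in {0, 1}
        (0 = S allele, 1 = Y allele).  No missing entries.
    marker_map : pandas.DataFrame
        Indexed by marker id with columns ``chrom`` and ``pos`` (1-based).
    """

    alleles: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.alleles.shape[1] == 0:
            raise InvalidDesignError("genotype matrix has no markers")
        if self.alleles.isna().any().any():
            raise InvalidDesignError("genotype matrix contains missing entries")
        vals = np.unique(self.alleles.to_numpy())
        if not np.isin(vals, (0, 1)).all():
            raise InvalidDesignError("allele codes must be 0 (S) or 1 (Y)")
        if not self.alleles.columns.equals(self.marker_map.index):
            raise InvalidDesignError("alleles columns and marker map disagree")
        if (self.marker_map["pos"] < 1).any():
            raise InvalidDesignError("marker positions must be 1-based")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise InvalidDesignError(
                    "marker positions must be strictly increasing per chromosome"
                )

    @property
    def segregants(self) -> pd.Index:
        return self.alleles.index

    @property
    def markers(self) -> pd.Index:
        return self.alleles.columns

    @property
    def n_segregants(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def column(self, marker: str) -> np.ndarray:
        return self.alleles[marker].to_numpy(dtype=float)


@dataclass
class CheckeredMask:
    """Per-environment lists of segregants selected for expression profiling."""

    profiled: dict[str, list[str]]

    def __post_init__(self) -> None:
        for env, ids in self.profiled.items():
            if len(set(ids)) != len(ids):
                raise InvalidDesignError(f"duplicated segregants in mask for {env!r}")

    def n_per_env(self) -> dict[str, int]:
        return {env: len(ids) for env, ids in self.profiled.items()}


@dataclass
class MultiEnvPhenotypes:
    """Growth table plus per-environment expression matrices.

    ``growth`` is complete (growth was assayed for every segregant in every
    environment); ``expression[env]`` has NaN rows for strains not profiled
    in that environment once a checkered design is applied.
    """

    growth: pd.DataFrame                      # segregants x environments
    expression: dict[str, pd.DataFrame]       # env -> segregants x genes
    mask: CheckeredMask | None = None

    def __post_init__(self) -> None:
        for env, mat in self.expression.items():
            if env not in self.growth.columns:
                raise InvalidDesignError(f"expression environment {env!r} not in growth table")
            if not mat.index.equals(self.growth.index):
                raise InvalidDesignError(f"segregant index mismatch for {env!r}")

    @property
    def environments(self) -> list[str]:
        return list(self.growth.columns)

    @property
    def expr_environments(self) -> list[str]:
        return list(self.expression)

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.expression.values())).columns

    def profiled_ids(self, env: str) -> pd.Index:
        """Segregants with non-missing expression in ``env``."""
        mat = self.expression[env]
        return mat.index[~mat.isna().all(axis=1)]

    def stacked(self, genotypes: GenotypeMatrix | None = None):
        """Long-format view over profiled (segregant, environment) samples.

        Returns a DataFrame indexed 0..n-1 with columns ``segregant``,
        ``environment`` and ``growth``; expression values are looked up
        lazily by callers via :meth:`stacked_expression`.
        """
        rows = []
        for env in self.expr_environments:
            for seg in self.profiled_ids(env):
                rows.append((seg, env, self.growth.at[seg, env]))
        return pd.DataFrame(rows, columns=["segregant", "environment", "growth"])

    def stacked_expression(self, gene: str, stack: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(stack))
        for i, (seg, env) in enumerate(zip(stack["segregant"], stack["environment"])):
            out[i] = self.expression[env].at[seg, gene]
        return out

    def stacked_all(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Stack all profiled samples at once.

        Returns ``(stack, expr)`` where ``stack`` has columns segregant,
        environment, growth and ``expr`` is the row-aligned samples x genes
        expression matrix.
        """
        stacks, exprs = [], []
        for env in self.expr_environments:
            ids = self.profiled_ids(env)
            stacks.append(pd.DataFrame({
                "segregant": ids,
                "environment": env,
                "growth": self.growth.loc[ids, env].to_numpy(),
            }))
            exprs.append(self.expression[env].loc[ids])
        stack = pd.concat(stacks, ignore_index=True)
        expr = pd.concat(exprs, ignore_index=True)
        expr.index = stack.index
        return stack, expr
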
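"""Treatment-coded design matrices for the factorial cohort design.

Shared between the cohort simulator and the hierarchical model so that
declared effect sizes and fitted coefficients refer to the same columns.
Reference levels are the first entry of each factor's enumeration
(sham, contralesional, L2/3, female, negative).
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FACTOR_LEVELS, ValidationError

__all__ = ["design_matrix", "term_names", "balanced_grid"]


def _main_effect_columns(df: pd.DataFrame, factor: str) -> dict[str, np.ndarray]:
    levels = FACTOR_LEVELS[factor]
    values = df[factor].to_numpy()
    unknown = set(values) - set(levels)
    if unknown:
        raise ValidationError(f"unknown {factor} levels {sorted(unknown)}")
    return {
        f"{factor}[{lev}]": (values == lev).astype(float)
        for lev in levels[1:]  # treatment coding, first level is reference
    }


def design_matrix(
    df: pd.DataFrame,
    factors: Sequence[str],
    interaction_order: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept + treatment-coded design matrix.

    Parameters
    ----------
    df : DataFrame
        Must contain one column per factor with canonical levels.
    factors : sequence of str
        Factor names in display order.
    interaction_order : int, optional
        Highest interaction order to include; defaults to the full
        factorial (``len(factors)``).  ``1`` gives main effects only.

    Returns
    -------
    X : (n, p) array
    names : list of str
        Column names, e.g. ``"group[stroke]:sex[male]"``.
    """
    if interaction_order is None:
        interaction_order = len(factors)
    if factors and interaction_order < 1:
        raise ValidationError("interaction_order must be >= 1")
    mains = {f: _main_effect_columns(df, f) for f in factors}
    columns: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(df))}
    for order in range(1, interaction_order + 1):
        for combo in itertools.combinations(factors, order):
            for parts in itertools.product(*(mains[f].items() for f in combo)):
                name = ":".join(p[0] for p in parts)
                col = np.prod(np.column_stack([p[1] for p in parts]), axis=1)
                columns[name] = col
    names = list(columns)
    return np.column_stack([columns[n] for n in names]), names


def term_names(factors: Sequence[str], interaction_order: int | None = None) -> list[str]:
    """Column names :func:`design_matrix` would produce, without data."""
    grid = balanced_grid(factors)
    _, names = design_matrix(grid, factors, interaction_order)
    return names


def balanced_grid(factors: Sequence[str]) -> pd.DataFrame:
    """Equal-weight grid of all factor-level combinations.

    gfp's 'unknown' level is a data placeholder, not part of the grid.
    An empty factor list yields the single (intercept-only) cell.
    """
    if not factors:
        return pd.DataFrame(index=[0])
    levels = [FACTOR_LEVELS[f][:2] for f in factors]
    rows = list(itertools.product(*levels))
    return pd.DataFrame(rows, columns=list(factors))
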
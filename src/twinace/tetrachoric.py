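"""Threshold and tetrachoric-correlation estimation on fourfold tables.

A tetrachoric correlation is the latent correlation of a bivariate
normal pair inferred from the 2x2 table of its dichotomized indicators.
Estimation is two-step: thresholds from the margins by normal-quantile
inversion, then the correlation by one-dimensional maximization of the
multinomial likelihood whose cell probabilities are bivariate-normal
rectangle probabilities (computed from Owen's T function, absolute
accuracy ~1e-14).  This is the standard approach for descriptive twin
correlations; model fitting elsewhere uses the full likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from .mvnorm import bvn_cdf

__all__ = [
    "FourfoldTable",
    "TetrachoricResult",
    "margin_threshold",
    "tetrachoric_ml",
    "twin_correlation_table",
    "TWIN_TABLE_COLUMNS",
]

TWIN_TABLE_COLUMNS = ("MZ_M", "DZ_M", "MZ_F", "DZ_F", "DZ_OS")

_RHO_LIM = 1.0 - 1e-9
_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 counts; first index is the row variable's value (1 then 0)."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def row1(self) -> int:
        return self.n11 + self.n10

    @property
    def col1(self) -> int:
        return self.n11 + self.n01

    def transpose(self) -> "FourfoldTable":
        return FourfoldTable(n11=self.n11, n10=self.n01,
                             n01=self.n10, n00=self.n00)

    def with_correction(self, c: float = 0.5) -> "FourfoldTable":
        """Add a continuity correction to every cell (optional use)."""
        return FourfoldTable(self.n11 + c, self.n10 + c,
                             self.n01 + c, self.n00 + c)


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    tau_row: float
    tau_col: float
    se_rho: float
    boundary: bool = False
    loglik: float = float("nan")


def margin_threshold(p: float) -> float:
    """Liability threshold z with P(Z > z) = p, i.e. ndtri(1 - p)."""
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"prevalence must be strictly inside (0, 1); got {p} "
            f"(threshold undefined or infinite)")
    return float(ndtri(1.0 - p))


def _cell_probs(tau_r: float, tau_c: float, rho: float) -> np.ndarray:
    """Multinomial cell probabilities (p11, p10, p01, p00)."""
    p_r = 1.0 - ndtr(tau_r)  # P(row = 1)
    p_c = 1.0 - ndtr(tau_c)
    # P(X > tau_r, Y > tau_c) via the survival identity
    p11 = 1.0 - ndtr(tau_r) - ndtr(tau_c) + bvn_cdf(tau_r, tau_c, rho)
    p10 = p_r - p11
    p01 = p_c - p11
    p00 = 1.0 - p_r - p_c + p11
    return np.clip(np.array([p11, p10, p01, p00]), 1e-300, 1.0)


def tetrachoric_ml(table: FourfoldTable,
                   correction: float = 0.0) -> TetrachoricResult:
    """Two-step ML tetrachoric correlation on a fourfold table.

    Thresholds come from the margins; rho maximizes the multinomial
    log-likelihood to ~1e-9.  Tables with both off-diagonal (or both
    diagonal) cells empty sit on the boundary and are reported at
    rho = +/-1 with the boundary flag set and an undefined SE.  An
    optional ``correction`` adds +c to every cell first.
    """
    if correction:
        table = table.with_correction(correction)
    n = table.total
    if n <= 0:
        raise ValueError("empty fourfold table")
    if table.row1 in (0, n) or table.col1 in (0, n):
        raise ValueError("degenerate margin: a row or column total is zero")

    tau_r = margin_threshold(table.row1 / n)
    tau_c = margin_threshold(table.col1 / n)
    counts = np.array([table.n11, table.n10, table.n01, table.n00],
                      dtype=float)

    def nll(rho: float) -> float:
        return -float(counts @ np.log(_cell_probs(tau_r, tau_c, rho)))

    if table.n10 == 0 and table.n01 == 0:
        return TetrachoricResult(rho=1.0, tau_row=tau_r, tau_col=tau_c,
                                 se_rho=float("nan"), boundary=True,
                                 loglik=-nll(_RHO_LIM))
    if table.n11 == 0 and table.n00 == 0:
        return TetrachoricResult(rho=-1.0, tau_row=tau_r, tau_col=tau_c,
                                 se_rho=float("nan"), boundary=True,
                                 loglik=-nll(-_RHO_LIM))

    res = minimize_scalar(nll, bounds=(-_RHO_LIM, _RHO_LIM),
                          method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    rho = float(res.x)
    boundary = 1.0 - abs(rho) < _BOUNDARY_TOL

    h = 5e-4
    if boundary:
        se = float("nan")
    else:
        hh = min(h, (1.0 - abs(rho)) / 2)
        d2 = (nll(rho + hh) - 2.0 * nll(rho) + nll(rho - hh)) / hh ** 2
        se = 1.0 / math.sqrt(d2) if d2 > 0 else float("nan")
    return TetrachoricResult(rho=rho, tau_row=tau_r, tau_col=tau_c,
                             se_rho=se, boundary=boundary,
                             loglik=-float(res.fun))


def twin_correlation_table(records, traits=("rsi", "ci"),
                           min_pairs: int = 2) -> pd.DataFrame:
    """Cross-twin tetrachoric correlations by group and sex-zygosity cell.

    Rows are (trait, group); columns MZ_M, DZ_M, MZ_F, DZ_F, DZ_OS.
    Tables come from double-entered complete pairs; cells with no
    usable pairs (for example opposite-sex cells in a same-sex-only
    cohort) or a degenerate margin are NaN.
    """
    from .data import cross_tab

    records = list(records)
    groups = sorted({r.group for r in records})
    rows = []
    for trait in traits:
        tables = cross_tab(records, "cross_twin_same_trait", trait=trait,
                           strata=("group", "sex_zygosity"))
        for g in groups:
            row = {"trait": trait, "group": g}
            for cell in TWIN_TABLE_COLUMNS:
                tab = tables.get((g, cell))
                if tab is None or tab.total < 2 * min_pairs:
                    row[cell] = np.nan
                    continue
                try:
                    row[cell] = tetrachoric_ml(tab).rho
                except ValueError:
                    row[cell] = np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["trait", "group"])
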
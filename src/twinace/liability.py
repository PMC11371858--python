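"""Bivariate binary liability-threshold ACE model.

Two binary phenotypes per twin -- regular smoking initiation (RSI) and
cannabis initiation (CI) -- are modelled as indicators that latent
standard-normal liabilities exceed trait-specific thresholds.  Liability
variance per trait decomposes into additive genetic (A), shared
environmental (C) and unique environmental (E) parts, with cross-trait
covariance components (cov_a, cov_c, cov_e) on the same standardized
scale.  Components are parameterized directly ("direct symmetric"
convention), so point estimates may be negative; only the implied
liability covariance matrices must be positive definite.

The model is identified by fixing each liability mean to zero (plus an
optional linear age effect) and its variance to one; thresholds are then
z-scores.  Pair covariance structure: MZ twins share A fully, DZ twins
share half of A; C is shared fully by both, E not at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .mvnorm import DEFAULT_N_NODES, mvn_rectangle_batch

logger = logging.getLogger(__name__)

__all__ = [
    "BivariateACEParams",
    "expected_covariance",
    "os_cross_covariance",
    "pattern_probability",
    "loglik",
    "implied_rp",
    "decomposed_correlations",
    "predicted_threshold",
    "ZYGOSITIES",
    "TRAITS",
]

ZYGOSITIES = ("MZ", "DZ_SS", "DZ_OS")
TRAITS = ("rsi", "ci")

# flat serialization order for parameter dictionaries
PARAM_NAMES = (
    "tau_rsi", "tau_ci", "beta_rsi", "beta_ci",
    "a_rsi", "c_rsi", "e_rsi", "a_ci", "c_ci", "e_ci",
    "cov_a", "cov_c", "cov_e",
)

_UNIT_SUM_TOL = 1e-6
_PD_EPS = 1e-10


@dataclass
class BivariateACEParams:
    """Parameters of the bivariate ACE liability model for one group.

    ``tau_*`` are thresholds (z-units at the reference age), ``beta_*``
    linear age slopes on the liability mean (per year), ``a/c/e_*``
    standardized variance components (summing to one per trait), and
    ``cov_a/c/e`` cross-trait covariance components.
    """

    tau_rsi: float
    tau_ci: float
    a_rsi: float
    c_rsi: float
    e_rsi: float
    a_ci: float
    c_ci: float
    e_ci: float
    cov_a: float
    cov_c: float
    cov_e: float
    beta_rsi: float = 0.0
    beta_ci: float = 0.0

    # -- construction helpers ------------------------------------------

    @classmethod
    def from_components(cls, tau, a, c, r_a, r_c, r_e, beta=(0.0, 0.0)):
        """Build from per-trait (tau, A, C) and factor correlations.

        E is the unit-sum remainder; cross covariances are
        ``r_x * sqrt(x_rsi * x_ci)``, which requires non-negative
        components.
        """
        e = (1.0 - a[0] - c[0], 1.0 - a[1] - c[1])
        for x in (*a, *c, *e):
            if x < 0:
                raise ValueError(
                    "from_components needs non-negative variance components; "
                    "construct directly for the direct-symmetric case"
                )
        return cls(
            tau_rsi=tau[0], tau_ci=tau[1],
            a_rsi=a[0], c_rsi=c[0], e_rsi=e[0],
            a_ci=a[1], c_ci=c[1], e_ci=e[1],
            cov_a=r_a * math.sqrt(a[0] * a[1]),
            cov_c=r_c * math.sqrt(c[0] * c[1]),
            cov_e=r_e * math.sqrt(e[0] * e[1]),
            beta_rsi=beta[0], beta_ci=beta[1],
        )

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "BivariateACEParams":
        return cls(**{name: float(d[name]) for name in PARAM_NAMES
                      if name in d})

    # -- accessors ------------------------------------------------------

    def tau(self, trait: str) -> float:
        return self.tau_rsi if trait == "rsi" else self.tau_ci

    def beta(self, trait: str) -> float:
        return self.beta_rsi if trait == "rsi" else self.beta_ci

    def ace(self, trait: str) -> tuple[float, float, float]:
        if trait == "rsi":
            return (self.a_rsi, self.c_rsi, self.e_rsi)
        return (self.a_ci, self.c_ci, self.e_ci)

    @property
    def rp(self) -> float:
        return self.cov_a + self.cov_c + self.cov_e

    def validate(self) -> None:
        """Check unit-variance sums and positive definiteness."""
        for trait in TRAITS:
            s = sum(self.ace(trait))
            if abs(s - 1.0) > _UNIT_SUM_TOL:
                raise ValueError(
                    f"A+C+E for {trait} is {s:.6f}, not 1 "
                    f"(unit liability variance is required)"
                )
        for zyg in ("MZ", "DZ_SS"):
            expected_covariance(self, zyg)  # raises if not PD


def _check_pd(mat: np.ndarray, what: str) -> np.ndarray:
    eigmin = float(np.linalg.eigvalsh(mat).min())
    if eigmin <= _PD_EPS:
        raise ValueError(
            f"{what} is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    return mat


def _within_block(params: BivariateACEParams) -> np.ndarray:
    rp = params.rp
    return np.array([[1.0, rp], [rp, 1.0]])


def _cross_block_ss(params: BivariateACEParams, alpha: float) -> np.ndarray:
    same_rsi = alpha * params.a_rsi + params.c_rsi
    same_ci = alpha * params.a_ci + params.c_ci
    cross = alpha * params.cov_a + params.cov_c
    return np.array([[same_rsi, cross], [cross, same_ci]])


def expected_covariance(params: BivariateACEParams, zygosity: str) -> np.ndarray:
    """Implied 4x4 liability covariance for a same-sex twin pair.

    Variable ordering: (twin1 RSI, twin1 CI, twin2 RSI, twin2 CI).
    Cross-twin same-trait covariance is ``alpha*A + C`` with ``alpha`` 1
    for MZ and 0.5 for DZ; cross-twin cross-trait is
    ``alpha*cov_a + cov_c``; within-person cross-trait is
    ``cov_a + cov_c + cov_e``.
    """
    if zygosity == "MZ":
        alpha = 1.0
    elif zygosity in ("DZ_SS", "DZ", "DZ_OS"):
        alpha = 0.5
    else:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    w = _within_block(params)
    x = _cross_block_ss(params, alpha)
    cov = np.block([[w, x], [x.T, w]])
    return _check_pd(cov, f"{zygosity} liability covariance")


_BRIDGE_WARNED: set[str] = set()


def _bridge(x: float, y: float, label: str) -> float:
    """Sign-preserving geometric mean, arithmetic-mean fallback.

    Used to combine male and female components in the opposite-sex
    cross-twin block.  When either component is negative the geometric
    mean is undefined; the arithmetic mean is used instead and a warning
    logged (once per component), since the resulting covariance no
    longer factorizes.
    """
    if x >= 0.0 and y >= 0.0:
        return math.sqrt(x * y)
    if label not in _BRIDGE_WARNED:
        _BRIDGE_WARNED.add(label)
        logger.warning(
            "opposite-sex bridge for %s: component(s) negative "
            "(%.4f, %.4f); falling back to the arithmetic mean "
            "(warning emitted once)", label, x, y,
        )
    return 0.5 * (x + y)


def os_cross_covariance(params_m: BivariateACEParams,
                        params_f: BivariateACEParams) -> np.ndarray:
    """Cross-twin 2x2 covariance block for opposite-sex DZ pairs.

    Assumes a cross-sex genetic correlation of 1 (no qualitative sex
    limitation): each component is bridged across sexes by a
    sign-preserving geometric mean, weighted 0.5 for A as for any DZ
    pair.  Rows index twin1's traits, columns twin2's.
    """
    same_rsi = (0.5 * _bridge(params_m.a_rsi, params_f.a_rsi, "A(rsi)")
                + _bridge(params_m.c_rsi, params_f.c_rsi, "C(rsi)"))
    same_ci = (0.5 * _bridge(params_m.a_ci, params_f.a_ci, "A(ci)")
               + _bridge(params_m.c_ci, params_f.c_ci, "C(ci)"))
    cross = (0.5 * _bridge(params_m.cov_a, params_f.cov_a, "cov_a")
             + _bridge(params_m.cov_c, params_f.cov_c, "cov_c"))
    return np.array([[same_rsi, cross], [cross, same_ci]])


def pair_covariance(params1: BivariateACEParams,
                    params2: BivariateACEParams | None,
                    zygosity: str) -> np.ndarray:
    """4x4 liability covariance allowing twin-specific parameter sets."""
    if params2 is None or params2 is params1:
        return expected_covariance(params1, "DZ_SS" if zygosity == "DZ_OS"
                                   else zygosity)
    if zygosity == "MZ":
        if params1.to_dict() != params2.to_dict():
            raise ValueError("MZ twins must share one parameter set")
        return expected_covariance(params1, "MZ")
    w1 = _within_block(params1)
    w2 = _within_block(params2)
    if zygosity == "DZ_OS":
        x = os_cross_covariance(params1, params2)
    else:
        if params1.to_dict() != params2.to_dict():
            raise ValueError("same-sex pairs must share one parameter set")
        x = _cross_block_ss(params1, 0.5)
    cov = np.block([[w1, x], [x.T, w2]])
    return _check_pd(cov, f"{zygosity} liability covariance")


def effective_thresholds(params1: BivariateACEParams,
                         params2: BivariateACEParams | None,
                         age: float = 0.0, age_ref: float = 0.0) -> np.ndarray:
    """Age-adjusted thresholds for the 4 liability dimensions."""
    if params2 is None:
        params2 = params1
    da = age - age_ref
    return np.array([
        params1.tau_rsi - params1.beta_rsi * da,
        params1.tau_ci - params1.beta_ci * da,
        params2.tau_rsi - params2.beta_rsi * da,
        params2.tau_ci - params2.beta_ci * da,
    ])


def _pattern_bounds(pattern, thresholds):
    """Observed-dimension indices and rectangle bounds for one pattern."""
    idx, lower, upper = [], [], []
    for j, v in enumerate(pattern):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        idx.append(j)
        if int(v) == 1:
            lower.append(thresholds[j])
            upper.append(math.inf)
        else:
            lower.append(-math.inf)
            upper.append(thresholds[j])
    return idx, np.array(lower), np.array(upper)


def pattern_probability(params: BivariateACEParams, zygosity: str, pattern,
                        age: float = 0.0, age_ref: float = 0.0,
                        params2: BivariateACEParams | None = None,
                        n_nodes: int = DEFAULT_N_NODES) -> float:
    """Probability of one pair's observed response pattern.

    ``pattern`` is a length-4 sequence over {0, 1, None/NaN} ordered as
    (twin1 RSI, twin1 CI, twin2 RSI, twin2 CI).  Missing dimensions are
    integrated out exactly by dropping them from the rectangle.
    """
    def _code(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return -1
        return int(v)

    pattern = [_code(v) for v in pattern]
    if params2 is None or params2 is params:
        # exchangeable twins: canonicalize orientation so numerically
        # identical rectangles are used for mirrored patterns
        if (pattern[0], pattern[1]) > (pattern[2], pattern[3]):
            pattern = pattern[2:] + pattern[:2]
    pattern = [None if v == _MISS else v for v in pattern]
    cov = pair_covariance(params, params2, zygosity)
    tau = effective_thresholds(params, params2, age, age_ref)
    idx, lower, upper = _pattern_bounds(pattern, tau)
    if not idx:
        return 1.0
    sub = cov[np.ix_(idx, idx)]
    return float(mvn_rectangle_batch(lower[None, :], upper[None, :], sub,
                                     n_nodes)[0])


# ---------------------------------------------------------------------
# full-information log-likelihood
# ---------------------------------------------------------------------

_MISS = -1  # missing-phenotype code inside aggregated tables


def _norm_params_by_group(params_by_group) -> dict:
    out = {}
    for g, v in params_by_group.items():
        if isinstance(v, BivariateACEParams):
            out[g] = {"M": v, "F": v}
        else:
            out[g] = dict(v)
    return out


def aggregate_patterns(frame: pd.DataFrame, use_age: bool,
                       age_decimals: int = 1) -> pd.DataFrame:
    """Collapse pair rows to unique response patterns with multiplicities.

    Keys: group, zygosity, per-twin sex and the four phenotype codes
    (missing -> -1), plus age rounded to ``age_decimals`` when age enters
    the likelihood.  Aggregation is exact when age is excluded or ages
    are already discrete at that resolution.
    """
    df = frame.copy()
    for col in ("rsi1", "ci1", "rsi2", "ci2"):
        df[col] = df[col].astype(float).fillna(_MISS).astype(int)
    df["sex2"] = df["sex2"].fillna("")
    # canonicalize twin order within same-sex pairs (their exchange
    # leaves the pair probability invariant, so the likelihood becomes
    # exactly order-invariant and patterns aggregate further)
    k1 = (df["rsi1"] + 1) * 4 + (df["ci1"] + 1)
    k2 = (df["rsi2"] + 1) * 4 + (df["ci2"] + 1)
    swap = (df["sex1"] == df["sex2"]) & (k1 > k2)
    if swap.any():
        cols1, cols2 = ["rsi1", "ci1"], ["rsi2", "ci2"]
        tmp = df.loc[swap, cols1].to_numpy()
        df.loc[swap, cols1] = df.loc[swap, cols2].to_numpy()
        df.loc[swap, cols2] = tmp
    keys = ["group", "zygosity", "sex1", "sex2",
            "rsi1", "ci1", "rsi2", "ci2"]
    if use_age:
        df["age_key"] = df["age1"].astype(float).round(age_decimals)
        keys.append("age_key")
    else:
        df["age_key"] = 0.0
        keys.append("age_key")
    out = df.groupby(keys, dropna=False, observed=True).size()
    return out.rename("count").reset_index()


class _PatternBatch:
    """Patterns sharing group, zygosity, sexes, age and missingness."""

    __slots__ = ("group", "zygosity", "sex1", "sex2", "age",
                 "idx", "vals", "counts")

    def __init__(self, group, zygosity, sex1, sex2, age, idx, vals, counts):
        self.group = group
        self.zygosity = zygosity
        self.sex1 = sex1
        self.sex2 = sex2
        self.age = age
        self.idx = idx          # observed dimensions (tuple of ints)
        self.vals = vals        # (B, len(idx)) 0/1 matrix
        self.counts = counts    # (B,) multiplicities


def compile_table(table: pd.DataFrame) -> list[_PatternBatch]:
    """Pre-split an aggregated pattern table into numpy batches.

    Fitting evaluates the likelihood thousands of times; compiling the
    table once keeps the hot loop free of pandas overhead.
    """
    batches = []
    group_cols = ["group", "zygosity", "sex1", "sex2", "age_key"]
    for (g, zyg, sex1, sex2, age), sub in table.groupby(
            group_cols, dropna=False, observed=True):
        pat = sub[["rsi1", "ci1", "rsi2", "ci2"]].to_numpy()
        counts = sub["count"].to_numpy(dtype=float)
        obs_mask = pat != _MISS
        keep = obs_mask.any(axis=1)  # all-missing rows contribute zero
        pat, counts, obs_mask = pat[keep], counts[keep], obs_mask[keep]
        if len(pat) == 0:
            continue
        mask_codes = obs_mask @ (1 << np.arange(4))
        for code in np.unique(mask_codes):
            rows = mask_codes == code
            idx = tuple(j for j in range(4) if (code >> j) & 1)
            batches.append(_PatternBatch(
                g, zyg, sex1, sex2, float(age), idx,
                pat[rows][:, list(idx)], counts[rows]))
    return batches


def loglik_compiled(batches: list[_PatternBatch], lookup,
                    age_ref: float = 0.0,
                    n_nodes: int = DEFAULT_N_NODES) -> float:
    """Log-likelihood over compiled pattern batches (hot path)."""
    total = 0.0
    for b in batches:
        p1 = lookup(b.group, b.sex1)
        p2 = lookup(b.group, b.sex2) if b.sex2 else None
        tau = effective_thresholds(p1, p1 if p2 is None else p2,
                                   b.age, age_ref)
        idx = b.idx
        if idx[-1] < 2:
            sub_cov = _within_block(p1)[np.ix_(idx, idx)]
        elif idx[0] >= 2:
            j = [k - 2 for k in idx]
            sub_cov = _within_block(p2 if p2 is not None else p1)[
                np.ix_(j, j)]
        else:
            cov = pair_covariance(p1, p2, b.zygosity)
            sub_cov = cov[np.ix_(idx, idx)]
        tau_sub = tau[list(idx)]
        lower = np.where(b.vals == 1, tau_sub, -np.inf)
        upper = np.where(b.vals == 1, np.inf, tau_sub)
        probs = mvn_rectangle_batch(lower, upper, sub_cov, n_nodes)
        total += float(b.counts @ np.log(np.clip(probs, 1e-300, 1.0)))
    return total


def loglik_from_table(table: pd.DataFrame, lookup, age_ref: float = 0.0,
                      n_nodes: int = DEFAULT_N_NODES) -> float:
    """Log-likelihood of an aggregated pattern table.

    ``lookup(group, sex)`` must return the BivariateACEParams for that
    stratum (sex is ignored by unstratified lookups).
    """
    return loglik_compiled(compile_table(table), lookup,
                           age_ref=age_ref, n_nodes=n_nodes)


def loglik(params_by_group, records, age_ref: float = 0.0,
           n_nodes: int = DEFAULT_N_NODES) -> float:
    """Full-information log-likelihood over twin-pair records.

    ``params_by_group`` maps group label to either one parameter set or
    a ``{"M": ..., "F": ...}`` pair.  Complete pairs contribute 4-D (or
    lower, with missing responses) rectangle probabilities; single
    responders contribute marginal probabilities.  Identical patterns
    are aggregated before integration; aggregation keys include age
    (rounded to 0.1 y) only when some age slope is non-zero.
    """
    from .data import records_to_frame  # local import, avoids cycle

    frame = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    by_group = _norm_params_by_group(params_by_group)

    missing = set(frame["group"]) - set(by_group)
    if missing:
        ids = frame.loc[frame["group"].isin(missing), "pair_id"].tolist()[:10]
        raise ValueError(
            f"no parameters for group(s) {sorted(missing)}; "
            f"offending pair ids (first 10): {ids}"
        )

    use_age = any(p.beta_rsi != 0.0 or p.beta_ci != 0.0
                  for d in by_group.values() for p in d.values())
    table = aggregate_patterns(frame, use_age=use_age)

    def lookup(group, sex):
        d = by_group[group]
        return d.get(sex) or next(iter(d.values()))

    return loglik_from_table(table, lookup, age_ref=age_ref,
                             n_nodes=n_nodes)


# ---------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------

def implied_rp(params: BivariateACEParams) -> float:
    """Phenotypic (liability) correlation: cov_a + cov_c + cov_e."""
    return params.rp


def decomposed_correlations(params: BivariateACEParams) -> dict:
    """Factor correlations rA, rC, rE; NaN where undefined.

    ``r_x = cov_x / sqrt(x_rsi * x_ci)`` requires both components
    strictly positive; a negative point estimate makes the correlation
    inestimable (reported as NaN, not an error).  Values beyond +/-1 from
    rounding are clipped and flagged.
    """
    out = {}
    pairs = {
        "rA": (params.a_rsi, params.a_ci, params.cov_a),
        "rC": (params.c_rsi, params.c_ci, params.cov_c),
        "rE": (params.e_rsi, params.e_ci, params.cov_e),
    }
    out["clipped"] = []
    for name, (x1, x2, cx) in pairs.items():
        if x1 <= 0.0 or x2 <= 0.0:
            out[name] = float("nan")
            continue
        r = cx / math.sqrt(x1 * x2)
        if abs(r) > 1.0:
            out["clipped"].append(name)
            r = math.copysign(1.0, r)
        out[name] = r
    return out


def predicted_threshold(params: BivariateACEParams, trait: str,
                        age: float, age_ref: float = 0.0) -> float:
    """Threshold (z-score) at a given age: tau - beta * (age - age_ref)."""
    return params.tau(trait) - params.beta(trait) * (age - age_ref)


def predicted_prevalence(params: BivariateACEParams, trait: str,
                         age: float = 0.0, age_ref: float = 0.0) -> float:
    """Model-implied endorsement probability at a given age."""
    return float(1.0 - ndtr(predicted_threshold(params, trait, age, age_ref)))
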
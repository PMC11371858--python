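"""Maximum-likelihood fitting, stratification, LRTs and profile CIs.

The bivariate ACE liability model is fitted by full-information ML over
aggregated response patterns.  A ``ModelSpec`` describes the grouping
structure (unstratified, by group, or by group x sex), equality
constraints across strata (the device behind country and sex
comparisons), and fixed parameters (the device behind profile
likelihoods).

Internally the unit-variance constraint is eliminated by substitution
(E = 1 - A - C per trait), while reported free-parameter counts follow
the conventional bookkeeping that counts all of A, C and E with the
unit sum as a constraint: an unstratified model has 13 parameters
(2 thresholds + 2 age slopes + 6 variance components + 3 cross-trait
components) and a six-group model 78.  Both counts are reported.

Equality constraints may also target the derived factor correlations
(rA, rC, rE) or the phenotypic correlation rP; these are imposed by
reparameterizing the corresponding cross-trait covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtri
from scipy.stats import chi2 as chi2_dist

from .data import records_to_frame
from .liability import (
    BivariateACEParams,
    aggregate_patterns,
    compile_table,
    decomposed_correlations,
    expected_covariance,
    implied_rp,
    loglik_compiled,
)
from .tetrachoric import FourfoldTable, tetrachoric_ml

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "EqualityConstraint",
    "FitResult",
    "ProfileCI",
    "unstratified_spec",
    "stratified_spec",
    "count_free_parameters",
    "fit",
    "lrt",
    "aic",
    "equality_test_suite",
    "profile_ci",
]

# parameters optimized directly (E substituted out)
INTERNAL_PARAMS = (
    "tau_rsi", "tau_ci", "beta_rsi", "beta_ci",
    "a_rsi", "c_rsi", "a_ci", "c_ci",
    "cov_a", "cov_c", "cov_e",
)
DERIVED_PARAMS = ("rA", "rC", "rE", "rP")
_CARRIER = {"rA": "cov_a", "rC": "cov_c", "rE": "cov_e", "rP": "cov_e"}

DEFAULT_BOUNDS = {
    "tau_rsi": (-4.0, 4.0), "tau_ci": (-4.0, 4.0),
    "beta_rsi": (-0.5, 0.5), "beta_ci": (-0.5, 0.5),
    "a_rsi": (-1.0, 1.5), "c_rsi": (-1.0, 1.5),
    "a_ci": (-1.0, 1.5), "c_ci": (-1.0, 1.5),
    "cov_a": (-1.0, 1.0), "cov_c": (-1.0, 1.0), "cov_e": (-1.0, 1.0),
    "rA": (-1.0, 1.0), "rC": (-1.0, 1.0), "rE": (-1.0, 1.0),
    "rP": (-1.0, 1.0),
}

_JITTER_SCALE = {
    "tau_rsi": 0.10, "tau_ci": 0.10, "beta_rsi": 0.01, "beta_ci": 0.01,
    "a_rsi": 0.08, "c_rsi": 0.08, "a_ci": 0.08, "c_ci": 0.08,
    "cov_a": 0.05, "cov_c": 0.05, "cov_e": 0.05,
    "rA": 0.10, "rC": 0.10, "rE": 0.10, "rP": 0.05,
}

_PENALTY = 1.0e8
_VAR_FLOOR = 1e-6  # floor inside sqrt when reparameterizing rA/rC/rE


@dataclass(frozen=True)
class EqualityConstraint:
    """Force one parameter equal across strata, optionally at a value.

    ``param`` is an internal parameter name or one of rA/rC/rE/rP;
    ``strata`` is "all" or an explicit tuple of stratum labels;
    ``value`` fixes the shared parameter (used by profile likelihoods)
    instead of leaving it free.
    """

    param: str
    strata: object = "all"
    value: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Grouping structure, constraints and optimization metadata."""

    grouping: tuple[str, ...] = ()
    constraints: tuple[EqualityConstraint, ...] = ()
    fixed: dict = field(default_factory=dict)  # "param" or "stratum:param"
    bounds: dict = field(default_factory=dict)
    starts: dict = field(default_factory=dict)
    strata: tuple[str, ...] | None = None

    def with_constraint(self, c: EqualityConstraint) -> "ModelSpec":
        return replace(self, constraints=self.constraints + (c,))

    def with_fixed(self, **kv) -> "ModelSpec":
        return replace(self, fixed={**self.fixed, **kv})


def unstratified_spec(fix_betas: bool = False) -> ModelSpec:
    fixed = {"beta_rsi": 0.0, "beta_ci": 0.0} if fix_betas else {}
    return ModelSpec(grouping=(), fixed=fixed, strata=("pooled",))


def stratified_spec(groups, sexes=("M", "F"),
                    fix_betas: bool = False) -> ModelSpec:
    strata = tuple(f"{g}|{s}" for g in groups for s in sexes)
    fixed = {"beta_rsi": 0.0, "beta_ci": 0.0} if fix_betas else {}
    return ModelSpec(grouping=("group", "sex"), fixed=fixed, strata=strata)


# ---------------------------------------------------------------------
# parameterization machinery
# ---------------------------------------------------------------------

class _Parameterization:
    """Maps the free vector to per-stratum parameter sets."""

    def __init__(self, spec: ModelSpec, strata: tuple[str, ...]):
        self.spec = spec
        self.strata = tuple(strata)
        sset = set(self.strata)

        # which variable carries each cross-trait covariance per stratum
        self.carrier: dict[tuple[str, str], str] = {
            (s, p): p for s in self.strata for p in INTERNAL_PARAMS}
        con_strata: dict[int, tuple[str, ...]] = {}
        for ci, con in enumerate(spec.constraints):
            cs = self.strata if con.strata == "all" else tuple(con.strata)
            unknown = set(cs) - sset
            if unknown:
                raise ValueError(
                    f"constraint on {con.param!r} references absent "
                    f"strata {sorted(unknown)}")
            con_strata[ci] = cs
            if con.param in DERIVED_PARAMS:
                tgt = _CARRIER[con.param]
                for s in cs:
                    cur = self.carrier[(s, tgt)]
                    if cur not in (tgt, con.param):
                        raise ValueError(
                            f"conflicting constraints on {tgt} in {s}: "
                            f"{cur} vs {con.param}")
                    self.carrier[(s, tgt)] = con.param
            elif con.param not in INTERNAL_PARAMS:
                raise ValueError(f"unknown parameter {con.param!r}")

        # resolve each slot to fixed value or free index (with ties)
        self.slot: dict[tuple[str, str], tuple] = {}
        self.names: list[str] = []
        class_index: dict[tuple, int] = {}

        def fixed_value(s, var):
            if f"{s}:{var}" in spec.fixed:
                return spec.fixed[f"{s}:{var}"]
            if var in spec.fixed:
                return spec.fixed[var]
            return None

        for s in self.strata:
            for p in INTERNAL_PARAMS:
                var = self.carrier[(s, p)]
                fv = fixed_value(s, var)
                tie = None
                for ci, con in enumerate(spec.constraints):
                    if con.param == var and s in con_strata[ci]:
                        if con.value is not None:
                            fv = con.value
                        else:
                            tie = ci
                if fv is not None:
                    self.slot[(s, p)] = ("fixed", float(fv))
                    continue
                key = (var, tie) if tie is not None else (var, f"s:{s}")
                if key not in class_index:
                    class_index[key] = len(self.names)
                    label = var if tie is not None else f"{s}:{var}"
                    self.names.append(label)
                self.slot[(s, p)] = ("free", class_index[key])

        self.n_free = len(self.names)
        self._bounds = []
        for name in self.names:
            var = name.split(":")[-1]
            self._bounds.append(spec.bounds.get(var, DEFAULT_BOUNDS[var]))

    # -- vector <-> parameter sets -------------------------------------

    def _raw(self, x, s):
        out = {}
        for p in INTERNAL_PARAMS:
            kind, v = self.slot[(s, p)]
            out[p] = x[v] if kind == "free" else v
        return out

    def unpack(self, x) -> dict[str, BivariateACEParams]:
        params = {}
        for s in self.strata:
            raw = self._raw(x, s)
            e_rsi = 1.0 - raw["a_rsi"] - raw["c_rsi"]
            e_ci = 1.0 - raw["a_ci"] - raw["c_ci"]

            def _gm(x1, x2):
                return math.sqrt(max(x1, _VAR_FLOOR) * max(x2, _VAR_FLOOR))

            cov_a = raw["cov_a"]
            if self.carrier[(s, "cov_a")] == "rA":
                cov_a = raw["cov_a"] * _gm(raw["a_rsi"], raw["a_ci"])
            cov_c = raw["cov_c"]
            if self.carrier[(s, "cov_c")] == "rC":
                cov_c = raw["cov_c"] * _gm(raw["c_rsi"], raw["c_ci"])
            cov_e = raw["cov_e"]
            car_e = self.carrier[(s, "cov_e")]
            if car_e == "rE":
                cov_e = raw["cov_e"] * _gm(e_rsi, e_ci)
            elif car_e == "rP":
                cov_e = raw["cov_e"] - cov_a - cov_c
            params[s] = BivariateACEParams(
                tau_rsi=raw["tau_rsi"], tau_ci=raw["tau_ci"],
                beta_rsi=raw["beta_rsi"], beta_ci=raw["beta_ci"],
                a_rsi=raw["a_rsi"], c_rsi=raw["c_rsi"], e_rsi=e_rsi,
                a_ci=raw["a_ci"], c_ci=raw["c_ci"], e_ci=e_ci,
                cov_a=cov_a, cov_c=cov_c, cov_e=cov_e)
        return params

    def pack(self, starts: dict[str, dict]) -> np.ndarray:
        """Build a start vector from per-stratum parameter dicts."""
        x = np.zeros(self.n_free)
        seen = np.zeros(self.n_free, dtype=bool)
        for s in self.strata:
            sv = starts[s]
            derived = {
                "rA": sv.get("rA"), "rC": sv.get("rC"),
                "rE": sv.get("rE"), "rP": sv.get("rP"),
            }
            for p in INTERNAL_PARAMS:
                kind, v = self.slot[(s, p)]
                if kind != "free" or seen[v]:
                    continue
                var = self.carrier[(s, p)]
                val = derived[var] if var in DERIVED_PARAMS else sv.get(p)
                if val is None:
                    val = 0.0
                lo, hi = self._bounds[v]
                x[v] = float(np.clip(val, lo + 1e-6, hi - 1e-6))
                seen[v] = True
        return x

    @property
    def bounds(self):
        return list(self._bounds)

    # -- bookkeeping ----------------------------------------------------

    def n_free_conventional(self) -> int:
        """Free-parameter count under the A+C+E-all-counted convention."""
        n = self.n_free
        for trait in ("rsi", "ci"):
            classes = set()
            for s in self.strata:
                ka = self.slot[(s, f"a_{trait}")]
                kc = self.slot[(s, f"c_{trait}")]
                if ka[0] == "fixed" and kc[0] == "fixed":
                    continue
                classes.add((ka, kc))
            n += len(classes)
        return n


def count_free_parameters(spec: ModelSpec,
                          strata: tuple[str, ...] | None = None) -> int:
    """Free parameters under the conventional count (A, C and E all
    counted, unit variance handled as a constraint)."""
    strata = strata or spec.strata
    if strata is None:
        strata = ("pooled",) if not spec.grouping else None
    if strata is None:
        raise ValueError("strata must be supplied for stratified specs")
    return _Parameterization(spec, strata).n_free_conventional()


# ---------------------------------------------------------------------
# start values
# ---------------------------------------------------------------------

_DEFAULT_START = {
    "a_rsi": 0.40, "c_rsi": 0.25, "a_ci": 0.40, "c_ci": 0.25,
    "cov_a": 0.18, "cov_c": 0.12, "cov_e": 0.10,
    "beta_rsi": 0.0, "beta_ci": 0.0,
}


def _stratum_mask(frame, grouping, stratum, twin):
    if not grouping:
        return np.ones(len(frame), dtype=bool)
    if grouping == ("group",):
        return (frame["group"] == stratum).to_numpy()
    g, s = stratum.split("|")
    return ((frame["group"] == g)
            & (frame[f"sex{twin}"] == s)).to_numpy()


def _falconer(frame, mask, trait):
    """Crude A/C starts from double-entered MZ/DZ tetrachorics."""
    ests = {}
    for zyg, rows in (("MZ", frame["zygosity"] == "MZ"),
                      ("DZ", frame["zygosity"] != "MZ")):
        sub = frame[mask & rows.to_numpy()]
        y1 = sub[f"{trait}1"].to_numpy(dtype=float)
        y2 = sub[f"{trait}2"].to_numpy(dtype=float)
        ok = ~np.isnan(y1) & ~np.isnan(y2)
        y1, y2 = y1[ok], y2[ok]
        if len(y1) < 30:
            return None
        n11 = int(((y1 == 1) & (y2 == 1)).sum() * 2)
        n10 = int(((y1 == 1) & (y2 == 0)).sum() + ((y1 == 0) & (y2 == 1)).sum())
        n00 = int(((y1 == 0) & (y2 == 0)).sum() * 2)
        try:
            ests[zyg] = tetrachoric_ml(
                FourfoldTable(n11=n11, n10=n10, n01=n10, n00=n00)).rho
        except ValueError:
            return None
    a = float(np.clip(2.0 * (ests["MZ"] - ests["DZ"]), 0.05, 0.8))
    c = float(np.clip(2.0 * ests["DZ"] - ests["MZ"], 0.05, 0.8))
    if a + c > 0.9:
        scl = 0.9 / (a + c)
        a, c = a * scl, c * scl
    return a, c


def auto_starts(frame: pd.DataFrame, grouping, strata) -> dict[str, dict]:
    """Data-driven start values per stratum.

    Thresholds invert observed prevalences; A and C come from
    Falconer-style contrasts of MZ/DZ tetrachorics when enough complete
    pairs exist (defaults otherwise); cross-trait covariances split the
    within-person tetrachoric proportionally to sqrt(X1*X2) shares.
    """
    out = {}
    for stratum in strata:
        sv = dict(_DEFAULT_START)
        vals = {"rsi": [], "ci": []}
        for twin in (1, 2):
            mask = _stratum_mask(frame, grouping, stratum, twin)
            for trait in ("rsi", "ci"):
                v = frame.loc[mask, f"{trait}{twin}"].to_numpy(dtype=float)
                vals[trait].append(v[~np.isnan(v)])
        for trait in ("rsi", "ci"):
            v = np.concatenate(vals[trait])
            p = v.mean() if len(v) else 0.5
            p = min(max(p, 1.0 / (len(v) + 2)), 1.0 - 1.0 / (len(v) + 2))
            sv[f"tau_{trait}"] = float(np.clip(ndtri(1.0 - p), -3.0, 3.0))
        mask1 = _stratum_mask(frame, grouping, stratum, 1)
        for trait in ("rsi", "ci"):
            fal = _falconer(frame, mask1, trait)
            if fal is not None:
                sv[f"a_{trait}"], sv[f"c_{trait}"] = fal
        # within-person cross-trait correlation -> covariance split
        y1 = frame.loc[mask1, "rsi1"].to_numpy(dtype=float)
        y2 = frame.loc[mask1, "ci1"].to_numpy(dtype=float)
        ok = ~np.isnan(y1) & ~np.isnan(y2)
        if ok.sum() >= 30:
            tab = FourfoldTable(
                n11=int(((y1 == 1) & (y2 == 1))[ok].sum()),
                n10=int(((y1 == 1) & (y2 == 0))[ok].sum()),
                n01=int(((y1 == 0) & (y2 == 1))[ok].sum()),
                n00=int(((y1 == 0) & (y2 == 0))[ok].sum()))
            try:
                rp = tetrachoric_ml(tab).rho
                shares = {}
                for x in ("a", "c"):
                    shares[x] = math.sqrt(sv[f"{x}_rsi"] * sv[f"{x}_ci"])
                e1 = 1.0 - sv["a_rsi"] - sv["c_rsi"]
                e2 = 1.0 - sv["a_ci"] - sv["c_ci"]
                shares["e"] = math.sqrt(max(e1, 0.01) * max(e2, 0.01))
                tot = sum(shares.values())
                for x in ("a", "c", "e"):
                    sv[f"cov_{x}"] = rp * shares[x] / tot
            except ValueError:
                pass
        sv["rA"], sv["rC"], sv["rE"] = 0.5, 0.5, 0.5
        sv["rP"] = sv["cov_a"] + sv["cov_c"] + sv["cov_e"]
        out[stratum] = sv
    return out


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

@dataclass
class FitResult:
    """ML estimates plus fit statistics for one model."""

    estimates: dict[str, BivariateACEParams]
    minus2lnL: float
    n_free: int            # conventional count (A, C, E all counted)
    n_free_internal: int   # optimizer dimension (E substituted)
    aic: float
    converged: bool
    diagnostics: dict
    spec: ModelSpec
    strata: tuple[str, ...]
    age_ref: float
    x: np.ndarray
    seed: int | None = None
    ci: dict | None = None

    def derived(self, stratum: str | None = None) -> dict:
        s = stratum or self.strata[0]
        p = self.estimates[s]
        d = decomposed_correlations(p)
        d["rP"] = implied_rp(p)
        return d


def _stratum_resolver(grouping):
    if not grouping:
        return lambda g, s: "pooled"
    if grouping == ("group",):
        return lambda g, s: g
    return lambda g, s: f"{g}|{s}"


def _infer_strata(frame, grouping):
    if not grouping:
        return ("pooled",)
    groups = sorted(frame["group"].unique())
    if grouping == ("group",):
        return tuple(groups)
    sexes = sorted(set(frame["sex1"].dropna()) | set(frame["sex2"].dropna()))
    return tuple(f"{g}|{s}" for g in groups for s in sexes)


_PD_MARGIN = 0.005   # hinge barrier activates below this eigenvalue
_PD_HARD = 1e-6      # below this the likelihood is not evaluated


def _min_eigenvalue(params_by_stratum) -> float:
    """Smallest eigenvalue over all implied pair covariance matrices."""
    emin = np.inf
    for p in params_by_stratum.values():
        rp = p.rp
        w = np.array([[1.0, rp], [rp, 1.0]])
        for alpha in (1.0, 0.5):
            x = np.array([
                [alpha * p.a_rsi + p.c_rsi, alpha * p.cov_a + p.cov_c],
                [alpha * p.cov_a + p.cov_c, alpha * p.a_ci + p.c_ci]])
            cov = np.block([[w, x], [x.T, w]])
            emin = min(emin, float(np.linalg.eigvalsh(cov).min()))
    return emin


def _pd_barrier(emin: float) -> float:
    """Smooth hinge keeping iterates strictly inside the PD region.

    Zero when the smallest eigenvalue exceeds the margin; grows
    quadratically as it shrinks, so line searches are pushed away from
    the boundary before the likelihood becomes unevaluable.
    """
    return 1.0e6 * max(0.0, _PD_MARGIN - emin) ** 2


def fit(records, spec: ModelSpec, seed: int | None = None,
        n_starts: int = 5, n_nodes: int = 12, maxiter: int = 500,
        gtol: float = 1e-6, ftol: float = 1e-11,
        start_values: dict | None = None) -> FitResult:
    """Fit a bivariate ACE liability model by full-information ML.

    Multi-start L-BFGS-B on the aggregated-pattern likelihood; starts
    are data-driven (prevalences and tetrachorics) plus seeded jitter.
    Deterministic given ``seed``.  Non-convergence after all starts is
    reported in the result, never silently.
    """
    frame = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    strata = spec.strata or _infer_strata(frame, spec.grouping)
    resolver = _stratum_resolver(spec.grouping)

    # every record must resolve to a parameter stratum
    need = set()
    for g, s1, s2 in frame[["group", "sex1", "sex2"]].itertuples(index=False):
        need.add(resolver(g, s1))
        if isinstance(s2, str) and s2:
            need.add(resolver(g, s2))
    missing = need - set(strata)
    if missing:
        bad = sorted(missing)
        ids = frame["pair_id"].head(5).tolist()
        raise ValueError(
            f"records resolve to strata absent from the spec: {bad} "
            f"(e.g. pairs {ids})")

    par = _Parameterization(spec, strata)

    def beta_free():
        for s in strata:
            for b in ("beta_rsi", "beta_ci"):
                kind, v = par.slot[(s, b)]
                if kind == "free" or (kind == "fixed" and v != 0.0):
                    return True
        return False

    use_age = beta_free()
    ages = frame["age1"].to_numpy(dtype=float)
    age_ref = float(np.nanmean(ages)) if use_age and np.isfinite(
        np.nanmean(ages)) else 0.0
    batches = compile_table(aggregate_patterns(frame, use_age=use_age))

    starts = auto_starts(frame, spec.grouping, strata)
    for s, d in (spec.starts or {}).items():
        starts.setdefault(s, dict(_DEFAULT_START)).update(d)
    if start_values:
        for s, d in start_values.items():
            starts.setdefault(s, dict(_DEFAULT_START)).update(d)

    def objective(x):
        params = par.unpack(x)
        emin = _min_eigenvalue(params)
        if emin <= _PD_HARD:
            return _PENALTY * (1.0 + max(0.0, -emin))
        lookup = lambda g, sx: params[resolver(g, sx)]
        try:
            ll = loglik_compiled(batches, lookup, age_ref=age_ref,
                                 n_nodes=n_nodes)
        except (ValueError, np.linalg.LinAlgError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll + _pd_barrier(emin)

    rng = np.random.default_rng(seed)
    x0 = par.pack(starts)
    start_vecs = [x0]
    for _ in range(max(0, n_starts - 1)):
        xj = x0.copy()
        for i, name in enumerate(par.names):
            var = name.split(":")[-1]
            xj[i] += rng.normal(0.0, _JITTER_SCALE.get(var, 0.05))
        lo = np.array([b[0] for b in par.bounds])
        hi = np.array([b[1] for b in par.bounds])
        start_vecs.append(np.clip(xj, lo + 1e-6, hi - 1e-6))

    def run_one(xs):
        # Restart on line-search failures: the objective is kinked where
        # the opposite-sex bridge switches branch, and the minimum can
        # sit exactly on such a kink (a component estimate of zero).  A
        # fresh inverse-Hessian either gets past the kink or stalls at
        # the same function value; a stalled restart sequence is
        # accepted as a (kink) optimum.
        res = minimize(objective, xs, method="L-BFGS-B", bounds=par.bounds,
                       options={"maxiter": maxiter, "gtol": gtol,
                                "ftol": ftol})
        res.accepted = bool(res.success)
        for _ in range(4):
            if res.success or res.fun >= _PENALTY:
                break
            res2 = minimize(objective, res.x, method="L-BFGS-B",
                            bounds=par.bounds,
                            options={"maxiter": maxiter, "gtol": gtol,
                                     "ftol": ftol})
            improved = res.fun - res2.fun
            if res2.fun <= res.fun:
                res2.accepted = bool(res2.success) or improved < 1e-6
                res = res2
                if res.accepted:
                    break
            else:
                res.accepted = improved > -1e-6
                break
        return res

    if par.n_free == 0:
        # fully constrained model: nothing to optimize
        from types import SimpleNamespace
        f0 = objective(np.zeros(0))
        best = SimpleNamespace(x=np.zeros(0), fun=f0, success=True,
                               nit=0, message="fully constrained",
                               jac=np.zeros(0))
        attempts = [{"fun": float(f0), "success": True, "nit": 0,
                     "message": "fully constrained"}]
    else:
        best = None
        attempts = []
        for xs in start_vecs:
            if objective(xs) >= _PENALTY:  # repair non-PD starts
                xs = x0 if objective(x0) < _PENALTY else xs
            res = run_one(xs)
            attempts.append({"fun": float(res.fun),
                             "success": bool(res.success),
                             "accepted": bool(res.accepted),
                             "nit": int(res.nit),
                             "message": str(res.message)})
            if best is None or res.fun < best.fun:
                best = res

    converged = bool(getattr(best, "accepted", best.success)) \
        and best.fun < _PENALTY
    estimates = par.unpack(best.x)
    m2ll = 2.0 * float(best.fun)
    n_free = par.n_free_conventional()
    result = FitResult(
        estimates=estimates, minus2lnL=m2ll, n_free=n_free,
        n_free_internal=par.n_free, aic=m2ll + 2.0 * n_free,
        converged=converged,
        diagnostics={"attempts": attempts, "n_patterns": int(sum(len(b.counts) for b in batches)),
                     "grad_norm": float(np.max(np.abs(jac)))
                     if (jac := np.atleast_1d(
                         getattr(best, "jac", np.nan))).size else 0.0},
        spec=spec, strata=tuple(strata), age_ref=age_ref,
        x=np.asarray(best.x, dtype=float), seed=seed)
    if not converged:
        logger.warning("fit did not converge: %s", attempts[-1]["message"])
    return result


def aic(fit_result: FitResult) -> float:
    """Parameter-penalized AIC: -2lnL + 2 * (conventional) n_free."""
    if not fit_result.converged:
        raise ValueError("AIC of an unconverged fit is meaningless")
    return fit_result.minus2lnL + 2.0 * fit_result.n_free


def lrt(full: FitResult, reduced: FitResult) -> dict:
    """Likelihood-ratio test of nested fits.

    chi2 is the deviance difference (floored at zero with a warning if
    slightly negative, which indicates optimizer noise); df is the
    difference in conventional free-parameter counts.
    """
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged for an LRT")
    df = full.n_free - reduced.n_free
    if df <= 0:
        raise ValueError(
            f"reduced model must have fewer free parameters "
            f"(full {full.n_free}, reduced {reduced.n_free})")
    chi2 = reduced.minus2lnL - full.minus2lnL
    if chi2 < 0.0:
        if chi2 < -0.1:
            raise ValueError(
                f"reduced model fits better by {-chi2:.3f}; "
                f"models are likely not nested or a fit is at a false "
                f"optimum")
        logger.warning("negative LRT chi2 %.3g floored at 0", chi2)
        chi2 = 0.0
    p = float(chi2_dist.sf(chi2, df))
    return {"chi2": float(chi2), "df": int(df), "p": p}


def equality_test_suite(records, base_spec: ModelSpec, parameter_name: str,
                        mode: str, base_fit: FitResult | None = None,
                        **fit_options) -> pd.DataFrame:
    """Country- and sex-difference tests for one parameter.

    ``across_country_within_sex`` ties the parameter across all groups
    separately for each sex (a 2-df test with three countries);
    ``across_sex_within_country`` ties it across sexes within each
    group (1-df tests).  p-values are raw (no multiplicity adjustment).
    Per-comparison failures are reported in the table, not raised.
    """
    frame = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    if base_spec.grouping != ("group", "sex"):
        raise ValueError("the base spec must stratify by group and sex")
    if base_fit is None:
        base_fit = fit(frame, base_spec, **fit_options)
    strata = base_fit.strata
    groups = sorted({s.split("|")[0] for s in strata})
    sexes = sorted({s.split("|")[1] for s in strata})

    comparisons = []
    if mode == "across_country_within_sex":
        for s in ("M", "F"):
            if s not in sexes:
                raise ValueError(f"stratum absent: no sex {s!r} in data")
            comparisons.append(
                (f"{parameter_name} equal across groups ({s})",
                 tuple(f"{g}|{s}" for g in groups)))
    elif mode == "across_sex_within_country":
        if len(sexes) < 2:
            raise ValueError(
                f"stratum absent: both sexes required, found {sexes}")
        for g in groups:
            comparisons.append(
                (f"{parameter_name} equal across sexes ({g})",
                 tuple(f"{g}|{s}" for s in sexes)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for label, tie_strata in comparisons:
        row = {"comparison": label, "chi2": np.nan, "df": np.nan,
               "p": np.nan, "error": ""}
        try:
            reduced_spec = base_spec.with_constraint(
                EqualityConstraint(parameter_name, strata=tie_strata))
            start_values = {s: base_fit.estimates[s].to_dict()
                            for s in strata}
            reduced = fit(frame, reduced_spec,
                          start_values=start_values, **fit_options)
            res = lrt(base_fit, reduced)
            row.update(res)
        except (ValueError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileCI:
    lower: float
    upper: float
    lower_converged: bool
    upper_converged: bool

    def contains(self, value: float) -> bool:
        lo = self.lower if self.lower_converged else -math.inf
        hi = self.upper if self.upper_converged else math.inf
        return lo <= value <= hi


def _target_value(fit_result: FitResult, stratum: str, param: str) -> float:
    p = fit_result.estimates[stratum]
    if param in DERIVED_PARAMS:
        if param == "rP":
            return implied_rp(p)
        return decomposed_correlations(p)[param]
    if param in INTERNAL_PARAMS:
        return getattr(p, param)
    raise ValueError(f"unknown profile target {param!r}")


def profile_ci(records, spec: ModelSpec, fit_result: FitResult,
               target: str, level: float = 0.95,
               max_expand: int = 25, xtol: float = 1e-4,
               **fit_options) -> ProfileCI:
    """Likelihood-based confidence interval for one (possibly derived)
    parameter.

    Each bound solves "constrained deviance = minimum deviance +
    chi-square(1) quantile" by stepwise bracketing plus Brent root
    finding; derived targets (rA, rC, rE, rP) are profiled through the
    equality-constrained reparameterization.  A bound whose search
    fails (root not bracketed inside the parameter bounds, or the
    constrained fit keeps failing) is flagged unconverged rather than
    reported as a number.
    """
    if not fit_result.converged:
        raise ValueError("cannot profile an unconverged fit")
    frame = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    if ":" in target:
        stratum, param = target.split(":", 1)
    else:
        stratum, param = fit_result.strata[0], target
    theta_hat = _target_value(fit_result, stratum, param)
    if not np.isfinite(theta_hat):
        raise ValueError(f"target {target!r} is not estimable at the MLE")
    crit = float(chi2_dist.ppf(level, 1))
    dev0 = fit_result.minus2lnL
    start_values = {s: fit_result.estimates[s].to_dict()
                    for s in fit_result.strata}
    fit_options = {"n_starts": 2, **fit_options}

    def constrained_spec(value: float) -> ModelSpec:
        if param in DERIVED_PARAMS:
            return spec.with_constraint(EqualityConstraint(
                param, strata=(stratum,), value=value))
        return spec.with_fixed(**{f"{stratum}:{param}": value})

    def excess(value: float) -> float:
        res = fit(frame, constrained_spec(value),
                  start_values=start_values, **fit_options)
        if not res.converged:
            return math.nan
        return res.minus2lnL - dev0 - crit

    lo_b, hi_b = DEFAULT_BOUNDS.get(param, (-4.0, 4.0))
    out = {}
    for side, bound in (("lower", lo_b), ("upper", hi_b)):
        sign = -1.0 if side == "lower" else 1.0
        step = max(0.02, 0.05 * (abs(theta_hat) + 0.5))
        inner, f_inner = theta_hat, -crit
        found = None
        for _ in range(max_expand):
            cand = inner + sign * step
            if sign * (cand - bound) >= 0:
                cand = bound - sign * 1e-6
            f = excess(cand)
            if math.isnan(f):
                step *= 0.5  # constrained fit failed; try closer in
                if step < 1e-4:
                    break
                continue
            if f > 0.0:
                found = (inner, cand) if side == "upper" else (cand, inner)
                break
            inner, f_inner = cand, f
            if abs(cand - (bound - sign * 1e-6)) < 1e-9:
                break
            step *= 1.7
        if found is None:
            out[side] = (math.nan, False)
            continue
        try:
            root = brentq(excess, found[0], found[1], xtol=xtol, maxiter=60)
            out[side] = (float(root), True)
        except (ValueError, RuntimeError):
            out[side] = (math.nan, False)
    return ProfileCI(lower=out["lower"][0], upper=out["upper"][0],
                     lower_converged=out["lower"][1],
                     upper_converged=out["upper"][1])
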
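"""Synthetic twin-study generation under the bivariate ACE liability model.

Pairs are generated exactly as the analysis model assumes: each pair's
4-vector of liabilities (twin1 RSI, twin1 CI, twin2 RSI, twin2 CI) is
multivariate normal with the zygosity-implied covariance, the liability
mean shifts linearly with age, and binary responses are the indicators
of exceeding the thresholds.  Twins share their age (they are born
together).  Group streams are seeded independently from the master seed
keyed by the group label, so adding or permuting groups never perturbs
another group's draws.

A "truth sidecar" (JSON) records every generating parameter next to the
data file so recovery tests can compare estimates against the truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .data import TwinObs, TwinPairRecord, write_pairs
from .liability import (
    BivariateACEParams,
    effective_thresholds,
    pair_covariance,
)

__all__ = [
    "AgeDistribution",
    "GroupSpec",
    "StudySpec",
    "simulate_pairs",
    "simulate_study",
    "write_truth",
    "three_cohort_spec",
]


@dataclass(frozen=True)
class AgeDistribution:
    """Pair-level age law: uniform(low, high) or normal(mean, sd)
    truncated to [low, high]."""

    law: str = "uniform"
    low: float = 18.0
    high: float = 60.0
    mean: float | None = None
    sd: float | None = None

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.law == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.law == "normal":
            a = (self.low - self.mean) / self.sd
            b = (self.high - self.mean) / self.sd
            return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                 size=n, random_state=rng)
        raise ValueError(f"unknown age law {self.law!r}")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class GroupSpec:
    """One cohort's composition and generating parameters.

    ``params`` applies to males (and to everyone when ``params_female``
    is None).  ``sex_ratio`` is the proportion of same-sex pairs that
    are female.  ``n_singletons`` adds pairs whose co-twin did not
    respond, exercising the full-information likelihood.
    """

    label: str
    params: BivariateACEParams
    n_mz: int
    n_dz_ss: int
    n_dz_os: int = 0
    sex_ratio: float = 0.5
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    params_female: BivariateACEParams | None = None
    missing_rate: float = 0.0
    n_singletons: int = 0

    def __post_init__(self):
        for name in ("n_mz", "n_dz_ss", "n_dz_os", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def n_individuals(self) -> int:
        return 2 * (self.n_mz + self.n_dz_ss + self.n_dz_os) \
            + self.n_singletons


@dataclass(frozen=True)
class StudySpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate group labels in {labels}")


def _group_rng(master_seed: int, label: str) -> np.random.Generator:
    # label-keyed substream: independent of group order in the spec
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed),
                                zlib.crc32(label.encode("utf-8"))]))


def _draw_block(rng, params1, params2, zygosity, n, ages, age_ref=0.0):
    """Binary 4-patterns for n pairs of one zygosity/sex composition."""
    if n == 0:
        return np.zeros((0, 4), dtype=int)
    cov = pair_covariance(params1, params2, zygosity)
    chol = np.linalg.cholesky(cov)
    liab = rng.standard_normal((n, 4)) @ chol.T
    tau = np.stack([
        effective_thresholds(params1, params2 or params1, a, age_ref)
        for a in ages
    ])
    return (liab > tau).astype(int)


def simulate_pairs(params: BivariateACEParams, n_mz: int, n_dz_ss: int,
                   n_dz_os: int = 0, age_distribution=None,
                   sex_ratio: float = 0.5, seed=0,
                   params_female: BivariateACEParams | None = None,
                   group: str = "sim", missing_rate: float = 0.0,
                   n_singletons: int = 0, age_ref: float = 0.0,
                   rng: np.random.Generator | None = None,
                   ) -> list[TwinPairRecord]:
    """Simulate twin pairs for one group under the ACE liability model.

    Same-sex pairs are female with probability ``sex_ratio`` and use
    ``params_female`` when provided; opposite-sex pairs are oriented
    male-first.  ``missing_rate`` independently blanks each observed
    phenotype.  Reproducible given ``seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if age_distribution is None:
        age_distribution = AgeDistribution()
    p_m = params
    p_f = params_female if params_female is not None else params

    records: list[TwinPairRecord] = []
    counter = 0

    def emit(zygosity, sex1, sex2, pattern, age, single=False):
        nonlocal counter
        counter += 1
        vals = [None if v is None else int(v) for v in pattern]
        if missing_rate > 0.0:
            for j in range(4):
                if vals[j] is not None and rng.random() < missing_rate:
                    vals[j] = None
        t1 = TwinObs(sex=sex1, age=age, rsi=vals[0], ci=vals[1])
        t2 = None if single else TwinObs(sex=sex2, age=age,
                                         rsi=vals[2], ci=vals[3])
        if t1.has_phenotype or (t2 is not None and t2.has_phenotype):
            records.append(TwinPairRecord(
                pair_id=f"{group}-{counter:06d}", zygosity=zygosity,
                group=group, twin1=t1, twin2=t2))

    for zygosity, n in (("MZ", n_mz), ("DZ_SS", n_dz_ss)):
        if n == 0:
            continue
        female = rng.random(n) < sex_ratio
        ages = age_distribution.draw(n, rng)
        n_f = int(female.sum())
        pat_m = _draw_block(rng, p_m, None, zygosity, n - n_f,
                            ages[~female], age_ref)
        pat_f = _draw_block(rng, p_f, None, zygosity, n_f,
                            ages[female], age_ref)
        im = if_ = 0
        for i in range(n):
            if female[i]:
                emit(zygosity, "F", "F", pat_f[if_], float(ages[i]))
                if_ += 1
            else:
                emit(zygosity, "M", "M", pat_m[im], float(ages[i]))
                im += 1
    if n_dz_os:
        ages = age_distribution.draw(n_dz_os, rng)
        pats = _draw_block(rng, p_m, p_f, "DZ_OS", n_dz_os, ages, age_ref)
        for i in range(n_dz_os):
            emit("DZ_OS", "M", "F", pats[i], float(ages[i]))
    if n_singletons:
        female = rng.random(n_singletons) < sex_ratio
        ages = age_distribution.draw(n_singletons, rng)
        for i in range(n_singletons):
            p = p_f if female[i] else p_m
            pat = _draw_block(rng, p, None, "DZ_SS", 1,
                              ages[i:i + 1], age_ref)[0]
            emit("DZ_SS", "F" if female[i] else "M", None,
                 [pat[0], pat[1], None, None], float(ages[i]), single=True)
    return records


def simulate_study(spec: StudySpec) -> list[TwinPairRecord]:
    """Simulate all groups of a study; per-group independent substreams."""
    records: list[TwinPairRecord] = []
    for g in spec.groups:
        rng = _group_rng(spec.seed, g.label)
        records.extend(simulate_pairs(
            g.params, g.n_mz, g.n_dz_ss, g.n_dz_os,
            age_distribution=g.age_distribution, sex_ratio=g.sex_ratio,
            params_female=g.params_female, group=g.label,
            missing_rate=g.missing_rate, n_singletons=g.n_singletons,
            rng=rng))
    return records


def write_truth(spec: StudySpec, path) -> None:
    """Machine-readable sidecar with all generating parameters."""
    payload = {
        "seed": spec.seed,
        "groups": [
            {
                "label": g.label,
                "params": g.params.to_dict(),
                "params_female": (g.params_female.to_dict()
                                  if g.params_female else None),
                "n_mz": g.n_mz, "n_dz_ss": g.n_dz_ss, "n_dz_os": g.n_dz_os,
                "n_singletons": g.n_singletons,
                "sex_ratio": g.sex_ratio,
                "age_distribution": g.age_distribution.to_dict(),
                "missing_rate": g.missing_rate,
            }
            for g in spec.groups
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_study(spec: StudySpec, out_csv, truth_json=None):
    """Simulate, write the CSV and (optionally) the truth sidecar."""
    records = simulate_study(spec)
    write_pairs(records, out_csv)
    if truth_json is not None:
        write_truth(spec, truth_json)
    return records


# ---------------------------------------------------------------------
# three-cohort template
# ---------------------------------------------------------------------

# Default generating conditions for a three-cohort study: per-country
# sample sizes, sex/zygosity composition, age laws and lifetime
# prevalences mirror the multi-register design this package targets
# (a large Dutch register, a Finnish register, and a same-sex-only US
# register); the variance/covariance structure uses the pooled
# two-trait ACE estimates, shared across cohorts.
_COHORTS = {
    "netherlands": dict(n_individuals=12987, pct_female=0.672, pct_mz=0.470,
                        pct_os=0.253, prev_rsi=0.332, prev_ci=0.295,
                        age=dict(law="normal", mean=32.2, sd=14.8,
                                 low=17.0, high=97.0)),
    "finland": dict(n_individuals=5888, pct_female=0.569, pct_mz=0.322,
                    pct_os=0.355, prev_rsi=0.475, prev_ci=0.257,
                    age=dict(law="normal", mean=31.3, sd=4.2,
                             low=22.0, high=37.0)),
    "minnesota": dict(n_individuals=2742, pct_female=0.552, pct_mz=0.622,
                      pct_os=0.0, prev_rsi=0.447, prev_ci=0.629,
                      age=dict(law="normal", mean=36.2, sd=6.9,
                               low=22.0, high=49.0)),
}

_POOLED_STRUCTURE = dict(a=(0.47, 0.28), c=(0.34, 0.51),
                         r_a=0.74, r_c=0.47, r_e=0.48)


def three_cohort_spec(seed: int = 0, scale: float = 1.0) -> StudySpec:
    """Study spec emulating the three-cohort design.

    Individual counts, sex ratios, zygosity shares, age laws and
    per-country prevalences follow the template above; thresholds are
    the normal quantiles of the prevalences and the ACE structure is the
    pooled estimate.  ``scale`` shrinks every group proportionally for
    quick tests.  An odd individual count is honoured by adding one
    single responder.
    """
    from .tetrachoric import margin_threshold

    groups = []
    for label, c in _COHORTS.items():
        n_ind = int(round(c["n_individuals"] * scale))
        n_pairs, odd = divmod(n_ind, 2)
        n_mz = int(round(c["pct_mz"] * n_pairs))
        n_os = int(round(c["pct_os"] * n_pairs))
        n_dz_ss = n_pairs - n_mz - n_os
        params = BivariateACEParams.from_components(
            tau=(margin_threshold(c["prev_rsi"]),
                 margin_threshold(c["prev_ci"])),
            **_POOLED_STRUCTURE)
        groups.append(GroupSpec(
            label=label, params=params, n_mz=n_mz, n_dz_ss=n_dz_ss,
            n_dz_os=n_os, sex_ratio=c["pct_female"],
            age_distribution=AgeDistribution(**c["age"]),
            n_singletons=odd))
    return StudySpec(groups=tuple(groups), seed=seed)
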
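"""Assembled study outputs: descriptives, twin correlations, model
estimates with confidence intervals, thresholds by age, comparisons.

Rendering conventions: correlations and variance components to two
decimals; p-values in scientific notation; an inestimable decomposed
correlation (a negative component under the square root) is "NA"; a
profile-CI bound whose search did not converge is "-".  Rendering is
deterministic, so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .liability import decomposed_correlations, implied_rp
from .fitting import FitResult, ProfileCI

__all__ = ["ReportBundle", "estimates_table", "thresholds_table",
           "render_bundle"]

_NA = "NA"
_NOCONV = "-"


def _fmt(v, nd=2) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return _NA
    return f"{v:.{nd}f}"


def _fmt_ci(ci: ProfileCI | None, nd=2) -> str:
    if ci is None:
        return ""
    lo = _fmt(ci.lower, nd) if ci.lower_converged else _NOCONV
    hi = _fmt(ci.upper, nd) if ci.upper_converged else _NOCONV
    return f"[{lo}, {hi}]"


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return _NA
    return f"{p:.2e}"


def estimates_table(fit_result: FitResult,
                    cis: dict[str, ProfileCI] | None = None) -> pd.DataFrame:
    """Per-stratum A/C/E components and correlations, formatted.

    ``cis`` maps "stratum:param" to profile intervals.  Decomposed
    correlations with a negative component are rendered NA; unconverged
    CI bounds render as "-".
    """
    cis = cis or {}
    rows = []
    for stratum in fit_result.strata:
        p = fit_result.estimates[stratum]
        dec = decomposed_correlations(p)
        entries = [
            ("RSI", "A", p.a_rsi), ("RSI", "C", p.c_rsi),
            ("RSI", "E", p.e_rsi),
            ("CI", "A", p.a_ci), ("CI", "C", p.c_ci), ("CI", "E", p.e_ci),
            ("Cor.", "Phen.", implied_rp(p)),
            ("Cor.", "A", dec["rA"]), ("Cor.", "C", dec["rC"]),
            ("Cor.", "E", dec["rE"]),
        ]
        for block, comp, val in entries:
            if block == "Cor." and comp != "Phen.":
                key = f"{stratum}:r{comp}"
            else:
                t = "rsi" if block == "RSI" else "ci"
                key = f"{stratum}:{comp.lower()}_{t}" if block != "Cor." \
                    else f"{stratum}:rP"
            rows.append({
                "stratum": stratum, "block": block, "component": comp,
                "estimate": _fmt(val), "ci": _fmt_ci(cis.get(key)),
            })
    return pd.DataFrame(rows)


def thresholds_table(fit_result: FitResult, ages) -> pd.DataFrame:
    """Predicted thresholds (z-scores) at a set of ages per stratum."""
    from .liability import predicted_threshold

    rows = []
    for stratum in fit_result.strata:
        p = fit_result.estimates[stratum]
        for trait in ("rsi", "ci"):
            for a in ages:
                rows.append({
                    "stratum": stratum, "trait": trait, "age": float(a),
                    "threshold": round(predicted_threshold(
                        p, trait, a, fit_result.age_ref), 4),
                })
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """All study outputs; every number traces to a computation."""

    descriptives: pd.DataFrame | None = None
    joint_categories: pd.DataFrame | None = None
    twin_correlations: pd.DataFrame | None = None
    estimates: pd.DataFrame | None = None
    thresholds: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    _SECTIONS = ("descriptives", "joint_categories", "twin_correlations",
                 "estimates", "thresholds", "comparisons")

    def to_dict(self) -> dict:
        out = {"meta": dict(self.meta)}
        for name in self._SECTIONS:
            df = getattr(self, name)
            if df is None:
                out[name] = None
                continue
            d = df.reset_index() if df.index.nlevels > 1 or df.index.name \
                else df
            out[name] = json.loads(d.to_json(orient="records"))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        kwargs = {"meta": d.get("meta", {})}
        for name in cls._SECTIONS:
            v = d.get(name)
            kwargs[name] = None if v is None else pd.DataFrame(v)
        return cls(**kwargs)


def render_bundle(bundle: ReportBundle, out_dir,
                  formats=("tsv", "json", "md")) -> list[Path]:
    """Write report.tsv / report.json / report.md deterministically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    payload = bundle.to_dict()
    if "json" in formats:
        path = out_dir / "report.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)

    sections = [(name, getattr(bundle, name))
                for name in bundle._SECTIONS
                if getattr(bundle, name) is not None]
    if "tsv" in formats:
        path = out_dir / "report.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for name, df in sections:
                fh.write(f"# {name}\n")
                df_out = df.reset_index() if df.index.name \
                    or df.index.nlevels > 1 else df
                fh.write(df_out.to_csv(sep="\t", index=False))
                fh.write("\n")
        written.append(path)
    if "md" in formats:
        path = out_dir / "report.md"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# Bivariate twin-model report\n\n")
            for k in sorted(bundle.meta):
                fh.write(f"- {k}: {bundle.meta[k]}\n")
            for name, df in sections:
                fh.write(f"\n## {name.replace('_', ' ')}\n\n")
                df_out = df.reset_index() if df.index.name \
                    or df.index.nlevels > 1 else df
                fh.write(df_out.to_markdown(index=False))
                fh.write("\n")
        written.append(path)
    return written
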
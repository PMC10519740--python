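"""The heterogeneity model family and its comparison sequence.

Builds the three ACE variants (full, quantitative, homogeneity), runs the
likelihood-ratio comparison ladder, attaches the nested AE/CE/E submodels
to the quantitative kind, and emits fit-statistics and
standardized-component tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ace_engine import (ACEHeterogeneityModel, ACEHeterogeneityResults,
                         GroupedPairData, build_model, lrt)
from .scales import NORMAL_LONG, SHORT

__all__ = ["build_model", "run_sequence", "drop_test", "SequenceResult",
           "standardized_table"]

# (row label, kind, components, reference row label)
_SEQUENCE = [
    ("full_heterogeneity", "full", "ACE", None),
    ("quantitative_heterogeneity", "quantitative", "ACE", "full_heterogeneity"),
    ("homogeneity", "homogeneity", "ACE", "quantitative_heterogeneity"),
    ("quantitative_AE", "quantitative", "AE", "quantitative_heterogeneity"),
    ("quantitative_CE", "quantitative", "CE", "quantitative_heterogeneity"),
    ("quantitative_E", "quantitative", "E", "quantitative_heterogeneity"),
]


@dataclass
class SequenceResult:
    """Fits, the comparison table and the selected best model."""

    fits: dict[str, ACEHeterogeneityResults]
    table: pd.DataFrame
    best: str
    errors: dict[str, str] = field(default_factory=dict)

    def standardized_table(self, ci: bool = True) -> pd.DataFrame:
        return standardized_table(self.fits, ci=ci)


def run_sequence(data: GroupedPairData | pd.DataFrame, seed: int = 0,
                 alpha: float = 0.05, n_starts: int = 5) -> SequenceResult:
    """Fit the model ladder and assemble the fit-statistics table.

    Rows: full, quantitative (compared against full), homogeneity
    (against quantitative), then AE/CE/E submodels of the quantitative
    kind.  The best model is the lowest-AIC row whose LRT against its
    reference is non-significant at ``alpha`` (the full model qualifies
    by construction); ties break toward fewer parameters.  A fit failure
    annotates its row and the sequence continues.
    """
    if isinstance(data, pd.DataFrame):
        model0 = ACEHeterogeneityModel.from_cohort(data)
        data = model0.data

    fits: dict[str, ACEHeterogeneityResults] = {}
    errors: dict[str, str] = {}
    rows = []
    for name, kind, components, ref in _SEQUENCE:
        row = {"model": name, "comparison": ref or "",
               "parameters": build_model(kind, components).n_free}
        try:
            res = ACEHeterogeneityModel(data, kind=kind, components=components
                                        ).fit(seed=seed, n_starts=n_starts)
            fits[name] = res
            row.update({"df": res.df, "minus2ll": res.minus2ll, "aic": res.aic,
                        "converged": res.converged})
            if ref is not None and ref in fits:
                diff, ddf, p = lrt(res, fits[ref])
                row.update({"diff_minus2ll": diff, "diff_df": ddf, "p": p})
        except Exception as exc:  # annotate and continue
            errors[name] = str(exc)
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)

    best = _select_best(table, alpha)
    if best is not None:
        table["best"] = table["model"] == best
    return SequenceResult(fits=fits, table=table, best=best, errors=errors)


def _select_best(table: pd.DataFrame, alpha: float) -> str | None:
    if "minus2ll" not in table.columns:
        return None
    ok = table[table["minus2ll"].notna()].copy()
    if ok.empty:
        return None
    p = ok["p"] if "p" in ok.columns else pd.Series(np.nan, index=ok.index)
    # NaN p (failed or absent reference) never qualifies a compared row
    candidates = ok[(ok["comparison"] == "") | (p >= alpha)]
    if candidates.empty:
        candidates = ok
    candidates = candidates.sort_values(["aic", "parameters"])
    return str(candidates.iloc[0]["model"])


def drop_test(fit_quantitative: ACEHeterogeneityResults, component: str,
              seed: int = 0):
    """Test dropping A or C (in both groups) from the quantitative model.

    Refits the quantitative model without the component and returns the
    2-df likelihood-ratio result ``(diff_minus2ll, diff_df, p)`` together
    with the refitted results object.
    """
    if component not in ("A", "C"):
        raise ValueError("only A or C can be dropped")
    if fit_quantitative.spec.kind != "quantitative":
        raise ValueError("drop_test applies to a quantitative-kind fit")
    if not fit_quantitative.converged:
        raise ValueError("reference fit did not converge")
    submodel = "CE" if component == "A" else "AE"
    res = ACEHeterogeneityModel(fit_quantitative.model.data,
                                kind="quantitative", components=submodel
                                ).fit(seed=seed)
    diff, ddf, p = lrt(res, fit_quantitative)
    return (diff, ddf, p), res


def standardized_table(fits: dict[str, ACEHeterogeneityResults],
                       ci: bool = True) -> pd.DataFrame:
    """Standardized A/C/E per sleep group for the three ACE variants."""
    rows = []
    for name in ("full_heterogeneity", "quantitative_heterogeneity",
                 "homogeneity"):
        if name not in fits:
            continue
        res = fits[name]
        row = {"model": name}
        for lab, tag in ((SHORT, "short"), (NORMAL_LONG, "normal_long")):
            comps = dict(zip("ACE", res.standardized(lab)))
            for comp in "ACE":
                row[f"{comp}_{tag}"] = comps[comp]
                if ci:
                    lo, hi = res.standardized_ci(comp, lab)
                    row[f"{comp}_{tag}_lo"] = lo
                    row[f"{comp}_{tag}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
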
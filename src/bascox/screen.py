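"""Per-metabolite Cox association scan with Benjamini–Hochberg control.

For each bile acid: a crude Cox model (metabolite only) and a multivariable
model adjusted for the 17 clinical confounders, both reporting the hazard
ratio per 1 SD (metabolites are INT-scaled upstream, so one unit is one SD).
BH false-discovery-rate q-values are computed across the metabolite family
separately within each model type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cox import CoxPH, SurvivalData
from .simulate import CohortTable, design_columns

log = logging.getLogger(__name__)


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up q-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _one_fit(time, event, X, names, ties="efron"):
    data = SurvivalData(time=time, event=event, X=X, names=names)
    return CoxPH(data, ties=ties).fit()


def screen_metabolites(
    table: CohortTable,
    outcome: str = "mace",
    adjust: list[str] | None = None,
    ties: str = "efron",
) -> pd.DataFrame:
    """Crude and adjusted per-metabolite Cox scan with BH q-values.

    Returns one row per metabolite: HR, 95% CI and p for both model types,
    plus BH q-values computed within each model type across the metabolites.
    Non-convergent fits are flagged and excluded from the BH family.
    """
    if outcome not in ("mace", "death"):
        raise ValueError("outcome must be 'mace' or 'death'")
    df = table.data
    time = df[f"time_{outcome}"].to_numpy()
    event = df[f"event_{outcome}"].to_numpy()
    design = design_columns(df) if adjust is None else df[list(adjust)]
    adj_names = list(design.columns)
    ba_cols = table.ba_columns()
    if not ba_cols:
        raise ValueError("table has no metabolite columns")

    rows = []
    for name in ba_cols:
        x = df[name].to_numpy(dtype=float)[:, None]
        row = {"metabolite": name, "n_events": int(event.sum())}
        for kind, X, names in (
            ("crude", x, [name]),
            ("adjusted", np.column_stack([x, design.to_numpy(dtype=float)]),
             [name] + adj_names),
        ):
            try:
                fit = _one_fit(time, event, X, names, ties)
                ok = fit.converged
            except Exception as exc:  # degenerate designs surface as flags
                log.warning("screen fit failed for %s (%s): %s", name, kind, exc)
                fit, ok = None, False
            if fit is not None and ok:
                ci = fit.conf_int()
                row[f"{kind}_hr"] = fit.hazard_ratios[0]
                row[f"{kind}_ci_low"] = ci[0, 0]
                row[f"{kind}_ci_high"] = ci[0, 1]
                row[f"{kind}_p"] = fit.pvalues[0]
                row[f"{kind}_converged"] = True
            else:
                if fit is not None:
                    log.warning("non-convergent %s fit for %s: %s",
                                kind, name, fit.diagnostics)
                row[f"{kind}_hr"] = np.nan
                row[f"{kind}_ci_low"] = np.nan
                row[f"{kind}_ci_high"] = np.nan
                row[f"{kind}_p"] = np.nan
                row[f"{kind}_converged"] = False
        rows.append(row)

    out = pd.DataFrame(rows)
    for kind in ("crude", "adjusted"):
        q = np.full(len(out), np.nan)
        ok = out[f"{kind}_converged"].to_numpy()
        if ok.any():
            q[ok] = benjamini_hochberg(out.loc[ok, f"{kind}_p"].to_numpy())
        out[f"{kind}_q"] = q
    return out
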
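"""Edge-wise mixed-effects models of task-evoked connectivity.

For every connection (edge feature) independently, a linear mixed model

    Y = 1 + study + domain * load + (1 | subject)

is fitted by REML, fixed effects and the domain x load interaction are
tested with Wald chi-square tests per term, and p-values are
Benjamini-Hochberg corrected across edges, one family per effect.
Domain and load are categorical by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from wmnet.types import FeatureStack

#: Fixed-effect terms tested per edge, in model order.
EFFECTS = ("study", "domain", "load", "domain:load")

_TERM_NAMES = {
    "study": "C(study)",
    "domain": "C(domain)",
    "load": "C(load)",
    "domain:load": "C(domain):C(load)",
}


@dataclass
class EdgeModelResult:
    """Per-edge test statistics and FDR masks per effect.

    ``table`` is long-format (edge, effect, statistic, p, converged);
    ``masks`` maps effect -> boolean array over edges (FDR at ``q``).
    Non-converged edges are flagged, never dropped silently.
    """

    table: pd.DataFrame
    masks: dict[str, np.ndarray]
    q: float
    edge_names: list[str] = field(default_factory=list)

    def flagged_edges(self, effect: str) -> list[str]:
        mask = self.masks[effect]
        return [e for e, m in zip(self.edge_names, mask) if m]


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def _formula(effects: list[str], categorical_load: bool) -> str:
    load = "C(load)" if categorical_load else "load"
    terms = []
    if "study" in effects:
        terms.append("C(study)")
    if "domain" in effects and ("load" in effects or "domain:load" in effects):
        terms.append(f"C(domain) * {load}")
    elif "domain" in effects:
        terms.append("C(domain)")
    elif "load" in effects:
        terms.append(load)
    return "y ~ " + " + ".join(terms)


def fit_edge_mixed(
    edge_stack: FeatureStack,
    q: float = 0.01,
    categorical_load: bool = True,
) -> EdgeModelResult:
    """Per-edge mixed model with random subject intercepts.

    Effects whose factor has a single level in the data are omitted with
    a warning; non-convergence is flagged per edge. FDR correction runs
    across edges separately for each effect.
    """
    meta = edge_stack.meta
    for col in ("subject", "study", "domain", "load"):
        if col not in meta.columns:
            raise ValueError(f"edge stack metadata lacks {col!r}")

    effects = []
    for eff in ("study", "domain", "load"):
        if meta[eff].nunique() >= 2:
            effects.append(eff)
        else:
            warnings.warn(f"factor {eff!r} has a single level; omitted", stacklevel=2)
    test_effects = list(effects)
    if "domain" in effects and "load" in effects:
        test_effects.append("domain:load")
    if not test_effects:
        raise ValueError("no testable fixed effects")
    formula = _formula(effects, categorical_load)

    load_term = _TERM_NAMES["load"] if categorical_load else "load"
    term_map = dict(_TERM_NAMES)
    term_map["load"] = load_term
    term_map["domain:load"] = f"C(domain):{load_term}"

    base = meta[["subject", "study", "domain", "load"]].copy()
    rows = []
    for j, edge in enumerate(edge_stack.feature_names):
        df = base.copy()
        df["y"] = edge_stack.features[:, j]
        df = df.dropna(subset=["y"])
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                model = smf.mixedlm(formula, df, groups=df["subject"])
                fit = model.fit(reml=True)
                if not fit.converged:
                    converged = False
                wt = fit.wald_test_terms(scalar=True)
            stats_table = wt.table
            for eff in test_effects:
                term = term_map[eff]
                if term not in stats_table.index:
                    continue
                rows.append(
                    {
                        "edge": edge,
                        "effect": eff,
                        "statistic": float(stats_table.loc[term, "statistic"]),
                        "p": float(
                            np.clip(stats_table.loc[term, "pvalue"], 1e-300, 1.0)
                        ),
                        "converged": converged,
                    }
                )
        except (np.linalg.LinAlgError, ValueError) as err:
            for eff in test_effects:
                rows.append(
                    {
                        "edge": edge,
                        "effect": eff,
                        "statistic": np.nan,
                        "p": np.nan,
                        "converged": False,
                    }
                )
            warnings.warn(f"edge {edge!r} failed to fit: {err}", stacklevel=2)

    table = pd.DataFrame(rows)
    masks: dict[str, np.ndarray] = {}
    for eff in test_effects:
        sub = table.loc[table["effect"] == eff].set_index("edge")
        pvals = sub["p"].reindex(edge_stack.feature_names)
        ok = pvals.notna().to_numpy()
        mask = np.zeros(len(edge_stack.feature_names), dtype=bool)
        if ok.any():
            mask[ok] = bh_fdr(pvals.to_numpy()[ok], q)
        masks[eff] = mask
    return EdgeModelResult(
        table=table, masks=masks, q=q, edge_names=list(edge_stack.feature_names)
    )
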
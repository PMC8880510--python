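"""Arm-differential prognostic variable selection.

The screening framework fits a univariable Cox model for every radiomic
feature and clinical covariate *separately in each treatment arm*,
applies Benjamini-Hochberg FDR correction across the radiomic features
within each arm, and flags variables that are differentially prognostic
between arms under either of two scenarios:

(i)  significant association (p < 0.05) with survival in the target arm
     AND no association (p > 0.30) in the other arm; or
(ii) potential association (p < 0.30) in both arms but in *opposite*
     directions (HR > 1 in one arm, HR < 1 in the other).

The p entering the criteria is the BH-adjusted p for radiomic features
and the raw p for clinical covariates.  Correlated candidates are then
pruned to one representative per correlation group (connected components
of the significant-correlation graph), and the survivors are ranked by
the ratio of their two arm-wise p-values (low / high); the lowest ratio
is the most arm-specific signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .encoding import build_encoder, encode
from .simulate import TrialDataset
from .stats import ConvergenceError, bh_adjust, chisq_independence, cox_fit, cox_lrt_p, pearson

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

CLINICAL_SCREEN_VARS = ["age", "histology", "smoking", "grade", "prior_radiotherapy"]


@dataclass
class SelectionConfig:
    alpha_significant: float = 0.05
    alpha_no_association: float = 0.30
    alpha_potential: float = 0.30
    alpha_correlation: float = 0.05
    n_radiomic_selected: int = 1
    ties: str = "efron"
    clinical_vars: list[str] = field(default_factory=lambda: list(CLINICAL_SCREEN_VARS))


def per_arm_screen(
    dataset: TrialDataset,
    arm: str,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Univariable Cox screen of every variable in one arm.

    Returns a table indexed by variable with columns ``hr`` (exp of the
    largest-magnitude coefficient for multi-level covariates), ``p_raw``,
    ``p_adj`` (BH across radiomic features only; equals ``p_raw`` for
    clinical covariates), ``p_use`` (the criteria p) and ``var_class``.
    Variables whose fit does not converge are dropped with a log entry.
    """
    config = config or SelectionConfig()
    sub = dataset.subset(arm=arm)
    time = sub.clinical["time"].to_numpy()
    event = sub.clinical["event"].to_numpy()
    if event.sum() < 10:
        logger.warning("arm %s has only %d events; screen will be noisy",
                       arm, int(event.sum()))
    rows = []
    clin_vars = [v for v in config.clinical_vars if v in sub.clinical.columns]
    for var in list(sub.features.columns) + clin_vars:
        if var in sub.features.columns:
            X = sub.features[[var]].to_numpy()
            names = [var]
            var_class = "radiomic"
        else:
            spec = build_encoder(sub.clinical, [var])
            X = encode(sub.clinical, spec).to_numpy()
            names = spec.columns
            var_class = "clinical"
        try:
            fit = cox_fit(X, time, event, names=names, ties=config.ties)
        except (ConvergenceError, ValueError) as err:
            logger.warning("screen: variable %r skipped in arm %s (%s)", var, arm, err)
            continue
        if len(fit.beta) == 1:
            p = float(fit.p[0])
            hr = float(fit.hr[0])
        else:
            p = cox_lrt_p(fit, X, time, event)
            hr = float(np.exp(fit.beta[np.argmax(np.abs(fit.beta))]))
        rows.append({"variable": var, "arm": arm, "var_class": var_class,
                     "hr": hr, "p_raw": max(p, P_FLOOR)})
    table = pd.DataFrame(rows).set_index("variable")
    table["p_adj"] = table["p_raw"]
    rad = table["var_class"] == "radiomic"
    if rad.any():
        table.loc[rad, "p_adj"] = bh_adjust(table.loc[rad, "p_raw"].to_numpy())
    table["p_adj"] = table["p_adj"].clip(lower=P_FLOOR)
    table["p_use"] = np.where(rad, table["p_adj"], table["p_raw"])
    return table


def apply_criteria(
    table_target: pd.DataFrame,
    table_other: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> list[str]:
    """Variables differentially prognostic for the *target* arm under
    scenario (i) or (ii); see module docstring."""
    config = config or SelectionConfig()
    common = table_target.index.intersection(table_other.index)
    out = []
    for var in common:
        pt = table_target.loc[var, "p_use"]
        po = table_other.loc[var, "p_use"]
        ht = table_target.loc[var, "hr"]
        ho = table_other.loc[var, "hr"]
        crit_i = pt < config.alpha_significant and po > config.alpha_no_association
        crit_ii = (
            pt < config.alpha_potential
            and po < config.alpha_potential
            and (ht - 1.0) * (ho - 1.0) < 0
        )
        if crit_i or crit_ii:
            out.append(var)
    return out


def _pair_correlation_p(dataset: TrialDataset, a: str, b: str) -> float:
    """Association p-value for one candidate pair: Pearson for
    continuous-continuous, chi-square for categorical-categorical,
    one-way ANOVA for mixed pairs."""
    def get(var):
        if var in dataset.features.columns:
            return dataset.features[var], True
        col = dataset.clinical[var]
        return col, col.dtype != object

    xa, num_a = get(a)
    xb, num_b = get(b)
    if num_a and num_b:
        return pearson(xa.to_numpy(float), xb.to_numpy(float))[1]
    if not num_a and not num_b:
        table = pd.crosstab(xa, xb).to_numpy()
        return chisq_independence(table, continuity_correction=False)
    cont, cat = (xa, xb) if num_a else (xb, xa)
    groups = [cont[cat == lev].to_numpy(float) for lev in pd.unique(cat)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return 1.0
    return float(sps.f_oneway(*groups).pvalue)


def prune_correlated(
    candidates: list[str],
    dataset: TrialDataset,
    screen_target: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> tuple[list[str], list[list[str]]]:
    """Collapse significantly correlated candidates to one representative.

    Correlation groups are connected components of the graph with an edge
    for every pair with association p < alpha_correlation (computed on
    the full supplied cohort).  Within a group the member with the lowest
    target-arm criteria p survives; ties fall back to the pre-correction
    p, then to lexicographic order (logged).
    """
    config = config or SelectionConfig()
    g = nx.Graph()
    g.add_nodes_from(candidates)
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            if _pair_correlation_p(dataset, a, b) < config.alpha_correlation:
                g.add_edge(a, b)
    groups = [sorted(c) for c in nx.connected_components(g)]
    groups.sort()
    reps = []
    for grp in groups:
        key = lambda v: (
            screen_target.loc[v, "p_use"],
            screen_target.loc[v, "p_raw"],
            v,
        )
        best = min(grp, key=key)
        if len(grp) > 1:
            ties = [v for v in grp if key(v)[:2] == key(best)[:2] and v != best]
            if ties:
                logger.info("correlation group %s: residual tie broken "
                            "lexicographically (%s kept)", grp, best)
        reps.append(best)
    return sorted(reps), groups


def rank_by_p_ratio(
    representatives: list[str],
    table_target: pd.DataFrame,
    table_other: pd.DataFrame,
) -> pd.DataFrame:
    """Rank representatives by min(pA, pB) / max(pA, pB), ascending."""
    rows = []
    for var in representatives:
        pa = max(float(table_target.loc[var, "p_use"]), P_FLOOR)
        pb = max(float(table_other.loc[var, "p_use"]), P_FLOOR)
        rows.append({
            "variable": var,
            "p_target": pa,
            "p_other": pb,
            "p_ratio": min(pa, pb) / max(pa, pb),
            "var_class": table_target.loc[var, "var_class"],
        })
    cols = ["variable", "p_target", "p_other", "p_ratio", "var_class"]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.sort_values(["p_ratio", "variable"]).reset_index(drop=True)
    return out


@dataclass
class SelectionResult:
    target_arm: str
    screen_target: pd.DataFrame
    screen_other: pd.DataFrame
    candidates: list[str]
    groups: list[list[str]]
    representatives: list[str]
    ranking: pd.DataFrame
    selected: list[str]

    def to_dict(self) -> dict:
        return {
            "target_arm": self.target_arm,
            "candidates": self.candidates,
            "groups": self.groups,
            "representatives": self.representatives,
            "ranking": self.ranking.to_dict(orient="records"),
            "selected": self.selected,
        }


def select_variables(
    dataset: TrialDataset,
    target_arm: str = "DOX",
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Full differential-selection pass for one target arm.

    The final variable set is every retained *clinical* representative
    plus the top ``n_radiomic_selected`` radiomic representatives by
    p-ratio (default one, matching a parsimonious clinical + single
    radiomic feature risk model).
    """
    config = config or SelectionConfig()
    arms = list(pd.unique(dataset.clinical["arm"]))
    if target_arm not in arms or len(arms) != 2:
        raise ValueError(f"target arm {target_arm!r} not one of two arms {arms}")
    other_arm = next(a for a in arms if a != target_arm)
    screen_t = per_arm_screen(dataset, target_arm, config)
    screen_o = per_arm_screen(dataset, other_arm, config)
    candidates = apply_criteria(screen_t, screen_o, config)
    reps, groups = prune_correlated(candidates, dataset, screen_t, config)
    ranking = rank_by_p_ratio(reps, screen_t, screen_o)
    selected = []
    if len(ranking):
        clin = ranking[ranking["var_class"] == "clinical"]["variable"].tolist()
        rad = ranking[ranking["var_class"] == "radiomic"]["variable"].tolist()
        selected = clin + rad[: config.n_radiomic_selected]
    return SelectionResult(
        target_arm=target_arm,
        screen_target=screen_t,
        screen_other=screen_o,
        candidates=candidates,
        groups=groups,
        representatives=reps,
        ranking=ranking,
        selected=selected,
    )
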
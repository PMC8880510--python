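"""Risk-score enrichment: single-arm multivariable Cox model, inclusion
threshold sweep on training data, frozen-threshold application to test.

The risk model is trained on the *control* (target) arm only; its linear
predictor is a log relative risk of death under control therapy.
Patients scoring high are predicted to do poorly on control therapy and
are therefore the ones to include in a trial of the experimental
combination.  The inclusion threshold is swept over the 1st..97th
percentiles of the pooled training-cohort scores; among thresholds with
a significant (p < alpha) log-rank difference *in the benefit direction*
(arm hazard ratio < 1), the one including the largest patient fraction
is chosen, then applied verbatim to the held-out test cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncoderSpec, build_encoder, encode
from .simulate import TrialDataset
from .stats import ConvergenceError, CoxFit, cox_fit, km_estimate, logrank, ph_check

logger = logging.getLogger(__name__)

EXPERIMENTAL_ARM = "DOX_EVO"


@dataclass
class RiskModel:
    """Multivariable Cox model fitted on the target arm.

    ``score`` is the linear predictor centred at the training covariate
    means, so an all-reference-level patient with mean continuous values
    scores ~0.
    """

    fit: CoxFit
    encoder: EncoderSpec
    target_arm: str
    direction: str  # include-above | include-below
    ph: dict = field(default_factory=dict)

    def scores(self, dataset: TrialDataset) -> pd.Series:
        joint = dataset.clinical.join(dataset.features)
        X = encode(joint, self.encoder)
        missing = [c for c in self.encoder.columns if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        lp = (X.to_numpy(dtype=float) - self.fit.x_center) @ self.fit.beta
        return pd.Series(lp, index=dataset.clinical.index, name="risk_score")


def fit_risk_model(
    train: TrialDataset,
    target_arm: str = "DOX",
    variables: list[str] | None = None,
    direction: str = "include-above",
    ties: str = "efron",
) -> RiskModel:
    """Fit the enrichment risk model on target-arm training patients only."""
    if not variables:
        raise ValueError("no variables selected for the risk model")
    arm_data = train.subset(arm=target_arm)
    if arm_data.clinical["event"].sum() < 10:
        logger.warning(
            "risk model trained on %d events only", int(arm_data.clinical["event"].sum())
        )
    joint = arm_data.clinical.join(arm_data.features)
    spec = build_encoder(joint, variables)
    X = encode(joint, spec)
    time = arm_data.clinical["time"].to_numpy()
    event = arm_data.clinical["event"].to_numpy()
    try:
        fit = cox_fit(X.to_numpy(dtype=float), time, event,
                      names=spec.columns, ties=ties)
    except ConvergenceError as err:
        raise ConvergenceError(
            f"risk model failed to converge on {len(time)} patients "
            f"({int(event.sum())} events, variables {variables}): {err}"
        ) from err
    ph = ph_check(fit, time, event, X.to_numpy(dtype=float))
    return RiskModel(fit=fit, encoder=spec, target_arm=target_arm,
                     direction=direction, ph=ph)


def _arm_comparison(clinical: pd.DataFrame) -> dict:
    """Log-rank p, arm HR (experimental vs control) with CI, and KM
    medians per arm on one patient subset."""
    arms = pd.unique(clinical["arm"])
    out: dict = {"n": int(len(clinical)), "evaluable": len(arms) == 2}
    if not out["evaluable"]:
        return out
    time = clinical["time"].to_numpy()
    event = clinical["event"].to_numpy()
    is_exp = (clinical["arm"] == EXPERIMENTAL_ARM).astype(float).to_numpy()
    chi2, p = logrank(time, event, is_exp)
    out["logrank_p"] = p
    try:
        fit = cox_fit(is_exp, time, event, names=["arm"])
        out["hr"] = float(fit.hr[0])
        out["hr_ci"] = [float(fit.ci_low[0]), float(fit.ci_high[0])]
    except (ConvergenceError, ValueError) as err:
        logger.warning("arm HR not estimable: %s", err)
        out["hr"] = None
        out["hr_ci"] = None
    out["km"] = {}
    for arm in sorted(arms):
        sel = clinical["arm"] == arm
        out["km"][arm] = km_estimate(
            clinical.loc[sel, "time"], clinical.loc[sel, "event"]
        ).to_dict()
    return out


def threshold_sweep(
    scores: pd.Series,
    clinical: pd.DataFrame,
    direction: str = "include-above",
    percentiles=range(1, 98),
) -> pd.DataFrame:
    """Survival contrast between arms at every percentile threshold.

    Thresholds are linear-interpolation percentiles of the pooled cohort
    scores.  Rows where an arm empties (or the arm effect is inestimable)
    are flagged with NaN statistics rather than dropped.
    """
    rows = []
    svals = scores.to_numpy(dtype=float)
    for k in percentiles:
        thr = float(np.percentile(svals, k))
        inc = scores >= thr if direction == "include-above" else scores <= thr
        sub = clinical.loc[inc[inc].index]
        row = {
            "percentile": int(k),
            "threshold": thr,
            "n_included": int(len(sub)),
            "fraction": len(sub) / len(clinical),
            "logrank_p": np.nan,
            "hr": np.nan,
            "hr_lo": np.nan,
            "hr_hi": np.nan,
        }
        if len(pd.unique(sub["arm"])) == 2:
            time = sub["time"].to_numpy()
            event = sub["event"].to_numpy()
            is_exp = (sub["arm"] == EXPERIMENTAL_ARM).astype(float).to_numpy()
            _, row["logrank_p"] = logrank(time, event, is_exp)
            try:
                fit = cox_fit(is_exp, time, event, names=["arm"])
                row["hr"] = float(fit.hr[0])
                row["hr_lo"] = float(fit.ci_low[0])
                row["hr_hi"] = float(fit.ci_high[0])
            except (ConvergenceError, ValueError):
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def select_threshold(sweep: pd.DataFrame, alpha: float = 0.05) -> dict | None:
    """Pick the qualifying sweep point (p < alpha, HR < 1) with the
    largest inclusion fraction; None when no threshold qualifies."""
    ok = sweep[(sweep["logrank_p"] < alpha) & (sweep["hr"] < 1.0)]
    if ok.empty:
        return None
    best = ok.sort_values(["fraction", "percentile"],
                          ascending=[False, True]).iloc[0]
    return {
        "percentile": int(best["percentile"]),
        "threshold": float(best["threshold"]),
        "fraction": float(best["fraction"]),
        "logrank_p": float(best["logrank_p"]),
        "hr": float(best["hr"]),
    }


@dataclass
class EnrichmentReport:
    threshold: float
    direction: str
    cohort: str
    included: dict
    excluded: dict
    n_total: int
    n_included: int

    @property
    def fraction_included(self) -> float:
        return self.n_included / self.n_total

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "direction": self.direction,
            "cohort": self.cohort,
            "n_total": self.n_total,
            "n_included": self.n_included,
            "fraction_included": self.fraction_included,
            "included": self.included,
            "excluded": self.excluded,
        }


def apply_enrichment(
    dataset: TrialDataset,
    model: RiskModel,
    threshold: float,
    cohort_label: str = "test",
) -> EnrichmentReport:
    """Partition a cohort at a frozen threshold and compare arms in the
    included and excluded subsets.  The threshold is used verbatim; no
    statistic of this cohort influences it."""
    scores = model.scores(dataset)
    inc = (
        scores >= threshold
        if model.direction == "include-above"
        else scores <= threshold
    )
    clin = dataset.clinical
    included = _arm_comparison(clin.loc[inc]) if inc.any() else {"n": 0, "evaluable": False}
    excluded = (
        _arm_comparison(clin.loc[~inc]) if (~inc).any() else {"n": 0, "evaluable": False}
    )
    if not included.get("evaluable", False):
        logger.warning("included subset not evaluable (an arm is empty)")
    return EnrichmentReport(
        threshold=float(threshold),
        direction=model.direction,
        cohort=cohort_label,
        included=included,
        excluded=excluded,
        n_total=int(len(clin)),
        n_included=int(inc.sum()),
    )


def enrich(
    train: TrialDataset,
    test: TrialDataset,
    variables: list[str],
    target_arm: str = "DOX",
    alpha: float = 0.05,
    direction: str = "include-above",
) -> dict:
    """End-to-end enrichment: fit model on train target arm, sweep on the
    pooled training cohort, freeze the chosen threshold, apply to test."""
    model = fit_risk_model(train, target_arm, variables, direction)
    train_scores = model.scores(train)
    sweep = threshold_sweep(train_scores, train.clinical, direction)
    chosen = select_threshold(sweep, alpha=alpha)
    out = {
        "model": model,
        "sweep": sweep,
        "chosen": chosen,
        "train_report": None,
        "test_report": None,
    }
    if chosen is None:
        logger.info("no enrichment threshold found (no sweep point with "
                    "p < %.3g and HR < 1)", alpha)
        return out
    out["train_report"] = apply_enrichment(train, model, chosen["threshold"], "train")
    out["test_report"] = apply_enrichment(test, model, chosen["threshold"], "test")
    return out
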
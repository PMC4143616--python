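"""Statistical analysis of response datasets.

The pipeline mirrors standard practice for two-alternative forced-choice
group data: responses are pooled within participant for each condition
cell (mass ratio x restitution x occlusion), participant-level proportions
feed one-sample t-tests and default JZS Bayes factors, the restitution
effect is the within-participant difference in motor-object choice
proportions between the high and low restitution levels, and models are
compared by the Bernoulli negative log likelihood of the observed binary
responses under their per-trial choice probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = [
    "ConditionSummary",
    "ModelComparison",
    "summarize",
    "e_difference",
    "one_sample_t",
    "jzs_bayes_factor",
    "model_nll",
    "chance_nll",
    "compare_models",
]

#: Probabilities are clipped to this range before taking logs, keeping the
#: NLL finite under deterministic predictions while penalizing them heavily.
NLL_CLIP = 1e-6

CELL_KEYS = ["mass_ratio_r", "e", "occlusion"]


@dataclass
class ConditionSummary:
    """Per-cell group summary plus the per-participant table behind it.

    ``cells`` has one row per (mass_ratio_r, e, occlusion) with the
    across-participant mean of the within-participant motor-choice
    proportion and accuracy; ``per_participant`` retains the underlying
    participant x cell proportions for the inferential tests.
    """

    cells: pd.DataFrame
    per_participant: pd.DataFrame


def _test_trials(dataset: pd.DataFrame, include_practice: bool) -> pd.DataFrame:
    data = dataset if include_practice else dataset[~dataset["is_practice"]]
    if len(data) == 0:
        raise ValueError("no test trials to analyze")
    return data


def summarize(dataset: pd.DataFrame, include_practice: bool = False) -> ConditionSummary:
    """Condition proportions, pooled within participant then averaged.

    Practice trials are excluded by default.  A participant contributes to
    a cell mean only if they have trials in that cell; unbalanced cells
    trigger a warning.
    """
    data = _test_trials(dataset, include_practice).copy()
    data["chose_motor"] = (data["response"] == "motor").astype(float)
    data["correct"] = data["correct"].astype(float)
    per = (
        data.groupby(["participant_id"] + CELL_KEYS, sort=True)
        .agg(
            p_motor=("chose_motor", "mean"),
            accuracy=("correct", "mean"),
            n_trials=("chose_motor", "size"),
        )
        .reset_index()
    )
    counts = per.groupby(CELL_KEYS)["participant_id"].nunique()
    if counts.nunique() > 1:
        warnings.warn(
            "some participants have no trials in some cells; they are "
            "excluded from those cell means",
            RuntimeWarning,
            stacklevel=2,
        )
    cells = (
        per.groupby(CELL_KEYS, sort=True)
        .agg(
            p_motor_chosen=("p_motor", "mean"),
            accuracy=("accuracy", "mean"),
            n_trials=("n_trials", "sum"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    return ConditionSummary(cells=cells, per_participant=per)


def e_difference(summary: ConditionSummary, occlusion: str) -> pd.Series:
    """Per-participant restitution effect for one occlusion condition.

    For each participant: the mean over mass ratios of
    ``p_motor(e=e_high) - p_motor(e=e_low)``, where e_high/e_low are the
    largest and smallest restitution levels present.  Both levels must be
    present for every (participant, mass ratio).
    """
    per = summary.per_participant
    per = per[per["occlusion"] == occlusion].copy()
    if len(per) == 0:
        raise ValueError(f"no trials with occlusion {occlusion!r}")
    levels = np.sort(per["e"].unique())
    if len(levels) < 2:
        raise ValueError(
            f"need both restitution levels for occlusion {occlusion!r}, found {levels}"
        )
    e_lo, e_hi = levels[0], levels[-1]
    # Pool the two signed sides of each heavier/lighter ratio: the design
    # balances condition cells, not which side carries the heavier object.
    per["ratio"] = np.maximum(per["mass_ratio_r"], 1.0 / per["mass_ratio_r"])
    per["_pn"] = per["p_motor"] * per["n_trials"]
    pooled = per.groupby(["participant_id", "ratio", "e"]).agg(
        _pn=("_pn", "sum"), n=("n_trials", "sum")
    )
    pooled = (pooled["_pn"] / pooled["n"]).rename("p_motor").reset_index()
    wide = pooled.pivot_table(
        index=["participant_id", "ratio"], columns="e", values="p_motor"
    )
    if e_lo not in wide.columns or e_hi not in wide.columns or wide[[e_lo, e_hi]].isna().any().any():
        raise ValueError("a participant is missing one restitution level in a cell")
    diff = (wide[e_hi] - wide[e_lo]).groupby("participant_id").mean()
    diff.name = "e_difference"
    return diff


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample two-sided t-test of the mean against ``mu0``.

    Returns ``(t, df, p_two_sided)``.  Requires n >= 2 and nonzero sample
    variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("t-test requires at least two values")
    if np.var(x, ddof=1) == 0.0:
        raise ValueError("t-test undefined for zero-variance sample")
    res = sps.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def jzs_bayes_factor(t: float, n: int, scale_r: float = 1.0) -> float:
    """Default (JZS) Bayes factor BF10 for a one-sample t statistic.

    The alternative places a Cauchy(0, ``scale_r``) prior on the
    standardized effect size d; BF10 is the ratio of the marginal
    likelihood of ``t`` under the alternative (noncentral t with
    noncentrality ``sqrt(n) * d``, integrated over the prior by adaptive
    quadrature) to its likelihood under the null (central t).  Values
    above 1 favour the alternative.
    """
    if n < 2:
        raise ValueError("Bayes factor requires n >= 2")
    if not scale_r > 0:
        raise ValueError("Cauchy prior scale must be positive")
    nu = n - 1
    root_n = np.sqrt(n)

    def integrand(d: float) -> float:
        return sps.nct.pdf(t, nu, root_n * d) * sps.cauchy.pdf(d, 0.0, scale_r)

    marginal, abserr = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-10, limit=400
    )
    null = sps.t.pdf(t, nu)
    if marginal <= 0 or null <= 0 or abserr > max(1e-10, 1e-6 * marginal):
        raise ArithmeticError(
            f"JZS integration failed: marginal={marginal!r}, null={null!r}, "
            f"abserr={abserr!r} (t={t}, n={n}, scale_r={scale_r})"
        )
    return float(marginal / null)


@dataclass
class ModelComparison:
    """Total Bernoulli negative log likelihood of a model's predictions."""

    model: str
    nll: float
    n_responses: int


def model_nll(
    dataset: pd.DataFrame,
    model=None,
    predictions=None,
    model_name: str = "model",
    include_practice: bool = False,
) -> ModelComparison:
    """Bernoulli NLL (nats) of the observed responses under a model.

    Provide either ``model`` (callable observation -> probability, or an
    object with ``.predict``) or ``predictions`` (an array with one
    probability of choosing the motor object per analyzed trial, in row
    order).  Probabilities are clipped to ``[NLL_CLIP, 1 - NLL_CLIP]``
    before taking logs.
    """
    from .physics import VisibleObservation
    from .simulate import _as_predictor

    data = _test_trials(dataset, include_practice)
    if predictions is None:
        if model is None:
            raise ValueError("provide a model or an array of predictions")
        predictor = _as_predictor(model)
        cache: dict[tuple, float] = {}
        p_list = []
        for row in data.itertuples(index=False):
            va = None if row.occlusion == "motor" else row.v_a
            vb = None if row.occlusion == "projectile" else row.v_b
            key = (row.u_a, va, vb)
            if key not in cache:
                cache[key] = float(
                    predictor(VisibleObservation(u_obs=row.u_a, va_obs=va, vb_obs=vb))
                )
            p_list.append(cache[key])
        p = np.asarray(p_list)
    else:
        p = np.asarray(predictions, dtype=float)
        if p.shape != (len(data),):
            raise ValueError(
                f"need one prediction per analyzed trial: got {p.shape}, "
                f"expected ({len(data)},)"
            )
    if np.isnan(p).any():
        raise ValueError("missing (NaN) prediction for at least one trial")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("model predictions must lie in [0, 1]")
    p = np.clip(p, NLL_CLIP, 1.0 - NLL_CLIP)
    chose_motor = (data["response"] == "motor").to_numpy()
    nll = -np.sum(np.where(chose_motor, np.log(p), np.log1p(-p)))
    return ModelComparison(model=model_name, nll=float(nll), n_responses=int(len(data)))


def chance_nll(n_responses: int) -> float:
    """NLL of the chance model: exactly ``n * ln 2``."""
    return float(n_responses) * float(np.log(2.0))


def compare_models(
    dataset: pd.DataFrame, models: dict, include_practice: bool = False
) -> pd.DataFrame:
    """NLL comparison table over named models (lower NLL is better)."""
    entries = [
        model_nll(dataset, model=m, model_name=name, include_practice=include_practice)
        for name, m in models.items()
    ]
    return pd.DataFrame(
        [{"model": e.model, "nll": e.nll, "n_responses": e.n_responses} for e in entries]
    )
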
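"""Statistical surface of the reward-complexity study.

Given per-subject empirical (complexity, reward) points and the optimal
frontier per set size, this module computes: quadratic empirical trade-off
curves (per group or pooled), a BIC comparison of group-specific versus
shared curves, the *bias* of each point (vertical gap to the optimal
frontier at the point's complexity), bias-complexity correlations,
a regression of per-subject mean bias on actor-critic parameters, learning
curves by stimulus-presentation index, and a two-way group x set-size
ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .rate_distortion import (
    TradeoffCurve,
    default_beta_grid,
    deterministic_value_table,
    optimal_reward_at,
    tradeoff_curve,
)

__all__ = [
    "CurveFit",
    "optimal_curves",
    "fit_empirical_curve",
    "compare_joint_independent",
    "compute_bias",
    "bias_complexity_correlation",
    "param_bias_regression",
    "learning_curves",
    "learned_beta_by_set_size",
    "group_anova",
    "qualitative_report",
]


@dataclass(frozen=True)
class CurveFit:
    """2nd-order polynomial fit of reward on complexity."""

    scope: str  # "joint" or a group label
    set_size: int | None
    coef: np.ndarray  # highest order first, length 3
    rss: float
    n: int


def optimal_curves(
    set_sizes=(2, 3, 4, 5, 6),
    n_actions: int = 3,
    beta_grid=None,
) -> dict[int, TradeoffCurve]:
    """Optimal reward-complexity frontier per set size for the
    deterministic one-rewarded-action task."""
    if beta_grid is None:
        beta_grid = default_beta_grid()
    return {
        n: tradeoff_curve(deterministic_value_table(n, n_actions), beta_grid)
        for n in set_sizes
    }


def fit_empirical_curve(
    points: pd.DataFrame, scope: str = "joint", set_size: int | None = None
) -> CurveFit:
    """Least-squares quadratic of reward on complexity.

    ``points`` is the tidy empirical-point table; ``set_size=None`` pools
    set sizes, ``scope`` other than "joint" restricts to that group.
    """
    df = points
    if set_size is not None:
        df = df[df["set_size"] == set_size]
    if scope != "joint":
        df = df[df["group"] == scope]
    x = df["complexity_nats"].to_numpy(dtype=float)
    y = df["reward"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("all complexities equal: quadratic is rank-deficient")
    coef = np.polyfit(x, y, 2)
    rss = float(np.sum((np.polyval(coef, x) - y) ** 2))
    return CurveFit(scope=scope, set_size=set_size, coef=coef, rss=rss, n=len(x))


def compare_joint_independent(points: pd.DataFrame, set_size: int) -> float:
    """BIC(independent per-group quadratics) - BIC(shared quadratic).

    Gaussian residual likelihood; the independent model spends 6 mean
    parameters, the joint 3.  Positive values favor the joint (shared
    curve) model.
    """
    df = points[points["set_size"] == set_size]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    joint = fit_empirical_curve(df, "joint")
    rss_indep = 0.0
    for grp in groups:
        sub = df[df["group"] == grp]
        if len(sub) < 3:
            raise ValueError(f"group {grp} has fewer than 3 points")
        rss_indep += fit_empirical_curve(df, grp).rss
    n = joint.n
    bic_joint = n * np.log(joint.rss / n) + 3 * np.log(n)
    bic_indep = n * np.log(rss_indep / n) + 6 * np.log(n)
    return float(bic_indep - bic_joint)


def compute_bias(
    points: pd.DataFrame, curves: dict[int, TradeoffCurve]
) -> pd.DataFrame:
    """Bias per (subject, set size): optimal reward at the point's
    complexity minus its empirical reward.

    Complexities beyond a curve's maximum are clamped to the terminal
    reward.  Bias can be negative for points estimated above the frontier.
    """
    rows = []
    for rec in points.itertuples(index=False):
        n = int(rec.set_size)
        if n not in curves:
            raise KeyError(f"no optimal curve for set size {n}")
        opt = optimal_reward_at(curves[n], float(rec.complexity_nats))
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "set_size": n,
                "complexity_nats": float(rec.complexity_nats),
                "reward": float(rec.reward),
                "bias": float(opt - rec.reward),
            }
        )
    return pd.DataFrame(rows)


def bias_complexity_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with Fisher-z 95% CI) and Spearman rho of bias against
    complexity, per group."""
    rows = []
    for grp, sub in records.groupby("group", sort=True):
        if len(sub) < 4:
            raise ValueError(f"group {grp} has fewer than 4 records")
        x = sub["complexity_nats"].to_numpy()
        y = sub["bias"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance in group {grp}")
        r = stats.pearsonr(x, y)
        rho = stats.spearmanr(x, y)
        z = np.arctanh(np.clip(r.statistic, -1 + 1e-15, 1 - 1e-15))
        half = 1.959963984540054 / np.sqrt(len(sub) - 3)
        rows.append(
            {
                "group": grp,
                "n": len(sub),
                "pearson_r": float(r.statistic),
                "pearson_p": float(r.pvalue),
                "r_ci_low": float(np.tanh(z - half)),
                "r_ci_high": float(np.tanh(z + half)),
                "spearman_rho": float(rho.statistic),
                "spearman_p": float(rho.pvalue),
            }
        )
    return pd.DataFrame(rows)


def param_bias_regression(
    params: pd.DataFrame, mean_bias: pd.DataFrame
) -> pd.DataFrame:
    """OLS of per-subject mean bias on the fixed-model parameters.

    ``params`` carries subject_id plus beta, alpha_theta, alpha_V, alpha_P;
    ``mean_bias`` carries subject_id and bias.  Returns the coefficient
    table with t and p values.
    """
    merged = params.merge(mean_bias, on="subject_id", validate="1:1")
    if len(merged) < 10:
        raise ValueError("need at least 10 subjects")
    names = ["beta", "alpha_theta", "alpha_V", "alpha_P"]
    X = sm.add_constant(merged[names].to_numpy(dtype=float))
    res = sm.OLS(merged["bias"].to_numpy(dtype=float), X).fit()
    cond = np.linalg.cond(X)
    if cond > 1e8:
        import warnings

        warnings.warn(f"design matrix is near-collinear (cond={cond:.2e})")
    return pd.DataFrame(
        {
            "term": ["const"] + names,
            "coef": res.params,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )


def learning_curves(subjects) -> pd.DataFrame:
    """Mean P(correct) by within-block presentation index of each stimulus,
    per (group, set size)."""
    df = pd.concat([s.trials for s in subjects], ignore_index=True)
    df = df.copy()
    df["presentation"] = (
        df.groupby(["subject_id", "block", "stimulus_id"]).cumcount() + 1
    )
    out = (
        df.groupby(["group", "set_size", "presentation"])["reward"]
        .agg(p_correct="mean", n="size")
        .reset_index()
    )
    return out


def learned_beta_by_set_size(
    subjects,
    set_sizes: tuple[int, ...] = (2, 6),
    restarts: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Learned inverse temperature of the adaptive model per set size.

    Fits the adaptive model to each subject by MLE, replays the fitted
    model on that subject's trial sequence, and averages the evolving
    beta_t over the trials of each requested set size.  Returns one row per
    subject with a ``beta_ss<n>`` column per set size.  Because beta
    re-adapts to each block, longer high-set-size blocks accumulate more
    adaptation; fitted to capacity-limited behavior this reproduces a
    slightly smaller learned beta at set size 6 than at set size 2.
    """
    from .agents import action_probs, adaptive_beta_step, init_block_state, step
    from .fitting import fit_subject

    rng = np.random.default_rng(seed)
    rows = []
    for data in subjects:
        fit = fit_subject(
            data, "adaptive", restarts=restarts,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        p = fit.params
        state, action, reward, block_ptr, n_states = data.to_arrays()
        block_sizes = data.trials.groupby("block")["set_size"].first().to_numpy()
        traces: dict[int, list[float]] = {n: [] for n in set_sizes}
        P_a = None
        for b in range(len(n_states)):
            st = init_block_state(int(n_states[b]), 3, p, P_a=P_a)
            for j in range(block_ptr[b], block_ptr[b + 1]):
                pi = action_probs(int(state[j]), st)
                step(int(state[j]), int(action[j]), float(reward[j]), p, st, pi=pi)
                adaptive_beta_step(int(state[j]), int(action[j]), p, st, pi=pi)
                if int(block_sizes[b]) in traces:
                    traces[int(block_sizes[b])].append(st.beta_t)
            P_a = st.P_a
        row = {"subject_id": data.subject_id, "group": data.group}
        for n in set_sizes:
            row[f"beta_ss{n}"] = float(np.mean(traces[n])) if traces[n] else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def group_anova(values: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of ``value`` on group (between subjects) and set size.

    ``values`` is a tidy (subject_id, group, set_size, value) table, one
    observation per subject and set size.  Returns F and p for group, set
    size, and their interaction (type-II sums of squares).
    """
    df = values.copy()
    counts = df.groupby(["group", "set_size"]).size().unstack()
    if counts.isna().any().any():
        raise ValueError("missing (group, set size) cells")
    model = smf.ols("value ~ C(group) * C(set_size)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key = {"C(group)": "group", "C(set_size)": "set_size",
           "C(group):C(set_size)": "interaction"}
    rows = []
    for raw, name in key.items():
        rows.append(
            {
                "effect": name,
                "F": float(table.loc[raw, "F"]),
                "p": float(table.loc[raw, "PR(>F)"]),
                "df": float(table.loc[raw, "df"]),
            }
        )
    return pd.DataFrame(rows)


def qualitative_report(
    points: pd.DataFrame,
    bias_records: pd.DataFrame,
    patient_group: str = "SZ",
    control_group: str = "HC",
) -> dict:
    """The study's four directional signatures on a two-cohort dataset.

    Returns booleans: the patient-like cohort has lower mean complexity and
    higher mean bias, bias correlates negatively with complexity in both
    groups, and the shared (joint) empirical curve is favored by BIC on
    average across set sizes.
    """
    mean_complexity = points.groupby("group")["complexity_nats"].mean()
    mean_bias = bias_records.groupby("group")["bias"].mean()
    corr = bias_complexity_correlation(bias_records)
    dbics = {
        int(n): compare_joint_independent(points, int(n))
        for n in sorted(points["set_size"].unique())
    }
    return {
        "complexity_gap": bool(
            mean_complexity[patient_group] < mean_complexity[control_group]
        ),
        "bias_gap": bool(mean_bias[patient_group] > mean_bias[control_group]),
        "negative_bias_complexity_correlation": bool(
            (corr["pearson_r"] < 0).all()
        ),
        "joint_curve_favored": bool(np.mean(list(dbics.values())) > 0),
        "mean_complexity": {k: float(v) for k, v in mean_complexity.items()},
        "mean_bias": {k: float(v) for k, v in mean_bias.items()},
        "delta_bic_by_set_size": dbics,
    }
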
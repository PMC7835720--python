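"""Analysis of percent-correct grasp-quality judgments.

The dependent measure throughout is the percentage of trials on which the
model-optimal grasp of a pair was judged "better", aggregated per
participant and session; chance is 50%.  The module provides

* one-sample and paired t-tests of percent correct against chance or
  between sessions, plus an unpaired (pooled or Welch) sibling;
* seeded percentile-bootstrap confidence intervals of the mean;
* effect sizes (mean − chance)/σ and mean(a − b)/σ(a − b);
* Bayesian estimation of group means with a Student-t likelihood (broad
  normal prior on the mean, uniform-on-log prior on the scale, shifted
  exponential on the normality parameter ν), sampled with random-walk
  Metropolis over 4 chains, reporting the 95% highest density interval
  and the posterior effect-size mass in a region of practical equivalence
  (ROPE, default ±0.4);
* the replication-subset rule (objects at chance under vision but above
  chance when grasping) and a within-session learning-trend check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "DegenerateTestError",
    "ConvergenceError",
    "GroupSummary",
    "TestResult",
    "BayesResult",
    "percent_correct",
    "summarize_group",
    "one_sample_t",
    "paired_t",
    "unpaired_t",
    "bootstrap_ci",
    "effect_size",
    "effect_size_paired",
    "hdi",
    "rope_fraction",
    "bayes_estimate",
    "bayes_estimate_paired",
    "select_replication_subset",
    "learning_trend",
    "plot_session_means",
]

CHANCE = 50.0
DEFAULT_ROPE = (-0.4, 0.4)


class DegenerateTestError(ValueError):
    """Raised for tests on degenerate data (n < 2 or zero variance)."""


class ConvergenceError(RuntimeError):
    """Raised when MCMC chains fail the R-hat convergence gate."""


@dataclass
class GroupSummary:
    """Per-participant percent-correct values with mean and bootstrap CI."""

    values: np.ndarray
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class TestResult:
    """Frequentist test output, optionally augmented with Bayesian summaries."""

    t: float
    df: int
    p: float
    mean_diff: float
    ci: tuple[float, float] | None = None
    hdi95: tuple[float, float] | None = None
    effect_size: float | None = None
    rope_fraction: float | None = None


@dataclass
class BayesResult:
    """Posterior draws and summaries from the robust Bayesian estimate."""

    mu: np.ndarray
    sigma: np.ndarray
    nu: np.ndarray
    effect: np.ndarray
    hdi95: tuple[float, float]
    rope_fraction: float
    rhat: dict[str, float]


# --- percent correct ------------------------------------------------------


def percent_correct(
    frame: pd.DataFrame,
    by: Sequence[str] = ("participant", "session"),
) -> pd.DataFrame:
    """Percent correct per grouping cell of the trial table.

    ``frame`` uses the interchange schema (columns ``participant``,
    ``session``, ``object``, ``chose_near_optimal``).  Cells absent from
    the table simply do not appear; rows with missing responses are
    dropped with a ``n_dropped`` attribute on the result.
    """
    if frame.empty:
        raise DegenerateTestError("empty trial table")
    work = frame.dropna(subset=["chose_near_optimal"])
    out = (
        work.groupby(list(by), observed=True)["chose_near_optimal"]
        .agg(n_correct="sum", n_trials="count")
        .reset_index()
    )
    out["percent_correct"] = 100.0 * out["n_correct"] / out["n_trials"]
    out.attrs["n_dropped"] = int(len(frame) - len(work))
    return out


def session_values(pc: pd.DataFrame, session: str) -> np.ndarray:
    """Per-participant percent-correct vector for one session, participant order."""
    sel = pc[pc["session"] == session].sort_values("participant")
    return sel["percent_correct"].to_numpy(dtype=float)


def summarize_group(
    values: Sequence[float], reps: int = 10000, seed: int = 0
) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    lo, hi = bootstrap_ci(v, reps=reps, seed=seed)
    return GroupSummary(values=v, mean=float(v.mean()), ci_low=lo, ci_high=hi)


# --- frequentist tests ----------------------------------------------------


def _check_values(values: np.ndarray, what: str = "values") -> None:
    if values.size < 2:
        raise DegenerateTestError(f"{what}: need at least 2 observations")
    if np.std(values, ddof=1) == 0:
        raise DegenerateTestError(f"{what}: zero variance")


def one_sample_t(values: Sequence[float], chance: float = CHANCE) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``chance``.

    Zero-variance data are degenerate: the test is undefined (error) unless
    the constant equals ``chance`` exactly, where t = 0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size >= 2 and np.std(v, ddof=1) == 0 and v.mean() == chance:
        return TestResult(t=0.0, df=int(v.size - 1), p=1.0, mean_diff=0.0)
    _check_values(v)
    res = sps.ttest_1samp(v, popmean=chance)
    return TestResult(
        t=float(res.statistic),
        df=int(v.size - 1),
        p=float(res.pvalue),
        mean_diff=float(v.mean() - chance),
        effect_size=effect_size(v, chance),
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Paired t-test (one-sample t on the within-participant differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateTestError("paired samples must have equal length")
    d = a - b
    if d.size >= 2 and np.std(d, ddof=1) == 0 and d.mean() == 0:
        return TestResult(t=0.0, df=int(d.size - 1), p=1.0, mean_diff=0.0)
    _check_values(d, "paired differences")
    res = sps.ttest_1samp(d, popmean=0.0)
    return TestResult(
        t=float(res.statistic),
        df=int(d.size - 1),
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
        effect_size=float(d.mean() / np.std(d, ddof=1)),
    )


def unpaired_t(
    a: Sequence[float], b: Sequence[float], welch: bool = True
) -> TestResult:
    """Two-sample t-test between independent groups (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_values(a, "group a")
    _check_values(b, "group b")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    return TestResult(
        t=float(res.statistic),
        df=int(round(df)),
        p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        effect_size=float((a.mean() - b.mean()) / pooled),
    )


def bootstrap_ci(
    values: Sequence[float],
    reps: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateTestError("need at least 2 observations to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(reps, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def effect_size(values: Sequence[float], chance: float = CHANCE) -> float:
    """Standardized deviation from chance: (mean − chance) / sd."""
    v = np.asarray(values, dtype=float)
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero standard deviation")
    return float((v.mean() - chance) / sd)


def effect_size_paired(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized paired difference: mean(a − b) / sd(a − b)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero standard deviation of differences")
    return float(d.mean() / sd)


# --- Bayesian estimation --------------------------------------------------


def hdi(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("no samples")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m:] - s[: n - m]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m])


def rope_fraction(
    samples: Sequence[float], bounds: tuple[float, float] = DEFAULT_ROPE
) -> float:
    """Share of posterior samples inside the region of practical equivalence."""
    lo, hi = bounds
    if lo > hi:
        raise ValueError("ROPE bounds must be ordered")
    s = np.asarray(samples, dtype=float)
    return float(np.mean((s >= lo) & (s <= hi)))


def _t_loglike(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Student-t log likelihood summed over data, vectorized over chains."""
    z = (y[None, :] - mu[:, None]) / sigma[:, None]
    n = y.size
    return (
        n * (gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi) - np.log(sigma))
        - (nu + 1) / 2 * np.log1p(z**2 / nu[:, None]).sum(axis=1)
    )


def _rhat(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction over (n_chains, n_draws)."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    b = n * means.var(ddof=1)
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _sample_best_one_group(
    y: np.ndarray,
    seed: int,
    n_chains: int = 4,
    n_iter: int = 10000,
    burn_in: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Random-walk Metropolis for the one-group robust model.

    Parameters sampled as (mu, log sigma, log(nu − 1)); priors: broad normal
    on mu, uniform on log sigma within wide bounds, exponential (mean 29)
    on nu − 1.  Proposal scale is adapted during burn-in toward ~30%
    acceptance and frozen afterwards.
    """
    n = y.size
    ybar, ysd = y.mean(), y.std(ddof=1)
    if ysd == 0:
        raise DegenerateTestError("zero variance data: posterior is degenerate")
    mu_prior_sd = 1000.0 * ysd
    log_sigma_lo, log_sigma_hi = np.log(ysd / 1000.0), np.log(ysd * 1000.0)

    rng = np.random.default_rng(seed)
    # Over-dispersed chain initialization.
    mu = ybar + ysd * rng.standard_normal(n_chains)
    log_sigma = np.log(ysd) + 0.3 * rng.standard_normal(n_chains)
    log_nu1 = np.log(29.0) + 0.3 * rng.standard_normal(n_chains)

    base_steps = np.array([ysd / np.sqrt(n), 0.7 / np.sqrt(n), 0.7])
    scale = 1.0

    def log_post(mu_, log_sigma_, log_nu1_):
        sigma_ = np.exp(log_sigma_)
        nu_ = 1.0 + np.exp(log_nu1_)
        lp = _t_loglike(y, mu_, sigma_, nu_)
        lp = lp - 0.5 * ((mu_ - ybar) / mu_prior_sd) ** 2
        lp = np.where(
            (log_sigma_ >= log_sigma_lo) & (log_sigma_ <= log_sigma_hi), lp, -np.inf
        )
        # exponential prior on nu-1 with Jacobian of the log transform
        lp = lp - (nu_ - 1.0) / 29.0 + log_nu1_
        return lp

    lp = log_post(mu, log_sigma, log_nu1)
    keep = n_iter - burn_in
    out = np.empty((3, n_chains, keep))
    for it in range(n_iter):
        prop_mu = mu + scale * base_steps[0] * rng.standard_normal(n_chains)
        prop_ls = log_sigma + scale * base_steps[1] * rng.standard_normal(n_chains)
        prop_ln = log_nu1 + scale * base_steps[2] * rng.standard_normal(n_chains)
        lp_prop = log_post(prop_mu, prop_ls, prop_ln)
        accept = np.log(rng.random(n_chains)) < lp_prop - lp
        mu = np.where(accept, prop_mu, mu)
        log_sigma = np.where(accept, prop_ls, log_sigma)
        log_nu1 = np.where(accept, prop_ln, log_nu1)
        lp = np.where(accept, lp_prop, lp)
        if it < burn_in:
            rate = accept.mean()
            scale *= np.exp(0.05 * (rate - 0.3))
        else:
            j = it - burn_in
            out[0, :, j] = mu
            out[1, :, j] = np.exp(log_sigma)
            out[2, :, j] = 1.0 + np.exp(log_nu1)
    rhats = {
        "mu": _rhat(out[0]),
        "sigma": _rhat(out[1]),
        "nu": _rhat(out[2]),
    }
    if max(rhats.values()) > 1.1:
        raise ConvergenceError(
            f"chains did not converge: R-hat {rhats}; "
            f"chain means mu={out[0].mean(axis=1)}"
        )
    return out[0].ravel(), out[1].ravel(), out[2].ravel(), rhats


def bayes_estimate(
    values: Sequence[float],
    chance: float = CHANCE,
    rope: tuple[float, float] = DEFAULT_ROPE,
    seed: int = 0,
    n_iter: int = 10000,
    burn_in: int = 2000,
) -> BayesResult:
    """Robust Bayesian estimate of a group mean's deviation from chance.

    Returns posterior draws of (mu, sigma, nu), the 95% HDI of mu − chance
    and the effect-size ((mu − chance)/sigma) posterior mass in the ROPE.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise DegenerateTestError("need at least 2 observations")
    mu, sigma, nu, rhats = _sample_best_one_group(
        y, seed=seed, n_iter=n_iter, burn_in=burn_in
    )
    effect = (mu - chance) / sigma
    return BayesResult(
        mu=mu,
        sigma=sigma,
        nu=nu,
        effect=effect,
        hdi95=hdi(mu - chance, 0.95),
        rope_fraction=rope_fraction(effect, rope),
        rhat=rhats,
    )


def bayes_estimate_paired(
    a: Sequence[float],
    b: Sequence[float],
    rope: tuple[float, float] = DEFAULT_ROPE,
    seed: int = 0,
    n_iter: int = 10000,
    burn_in: int = 2000,
) -> BayesResult:
    """Bayesian estimate of a paired difference (one-group model on a − b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateTestError("paired samples must have equal length")
    return bayes_estimate(a - b, chance=0.0, rope=rope, seed=seed, n_iter=n_iter, burn_in=burn_in)


# --- study-specific procedures -------------------------------------------


def select_replication_subset(
    frame: pd.DataFrame,
    vision_session: str = "vision",
    grasping_session: str = "grasping",
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
) -> list[str]:
    """Objects at chance under vision but reliably above chance when grasping.

    An object qualifies when the bootstrap 95% CI of its vision-session
    mean percent correct contains 50 AND its grasping-session one-sample
    t-test against 50 is significant (two-sided p < alpha) with a positive
    mean difference.
    """
    pc = percent_correct(frame, by=("object", "participant", "session"))
    selected = []
    for obj, grp in pc.groupby("object"):
        vis = grp[grp["session"] == vision_session]["percent_correct"].to_numpy()
        gra = grp[grp["session"] == grasping_session]["percent_correct"].to_numpy()
        if vis.size < 2 or gra.size < 2:
            continue
        lo, hi = bootstrap_ci(vis, reps=reps, seed=seed)
        if not (lo <= CHANCE <= hi):
            continue
        try:
            res = one_sample_t(gra, CHANCE)
        except DegenerateTestError:
            # all-identical grasping scores: above chance iff mean > 50
            if gra.mean() > CHANCE:
                selected.append(str(obj))
            continue
        if res.p < alpha and res.mean_diff > 0:
            selected.append(str(obj))
    return selected


def learning_trend(frame: pd.DataFrame) -> dict[str, TestResult]:
    """Within-session learning check: slope of correctness on trial index.

    Fits a least-squares slope per participant and session, then tests the
    session's slopes against zero with a one-sample t-test.  A stationary
    observer yields mean slopes near 0 and a non-significant test.
    """
    out: dict[str, TestResult] = {}
    for session, grp in frame.groupby("session"):
        slopes = []
        for _, sub in grp.groupby("participant"):
            x = sub["trial"].to_numpy(dtype=float)
            y = sub["chose_near_optimal"].to_numpy(dtype=float)
            if np.unique(x).size < 2:
                raise DegenerateTestError(
                    f"session {session!r}: need >= 2 trial indices per participant"
                )
            slopes.append(float(np.polyfit(x, y, 1)[0]))
        slopes_arr = np.asarray(slopes)
        if slopes_arr.size < 2:
            # a single participant: report the slope, no group test
            out[str(session)] = TestResult(
                t=float("nan"), df=0, p=float("nan"), mean_diff=float(slopes_arr.mean())
            )
        elif np.std(slopes_arr, ddof=1) == 0:
            out[str(session)] = TestResult(
                t=0.0, df=len(slopes) - 1, p=1.0, mean_diff=float(slopes_arr.mean())
            )
        else:
            res = sps.ttest_1samp(slopes_arr, 0.0)
            out[str(session)] = TestResult(
                t=float(res.statistic),
                df=len(slopes) - 1,
                p=float(res.pvalue),
                mean_diff=float(slopes_arr.mean()),
            )
    return out


# --- figures --------------------------------------------------------------


def plot_session_means(
    frame: pd.DataFrame,
    path: str | None = None,
    sessions: Sequence[str] | None = None,
    reps: int = 10000,
    seed: int = 0,
):
    """Bar plot of session means with bootstrap error bars and the chance line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pc = percent_correct(frame)
    if sessions is None:
        sessions = [s for s in ("vision", "video", "grasping") if s in set(pc["session"])]
    means, err_lo, err_hi = [], [], []
    for s in sessions:
        v = session_values(pc, s)
        summ = summarize_group(v, reps=reps, seed=seed)
        means.append(summ.mean)
        err_lo.append(summ.mean - summ.ci_low)
        err_hi.append(summ.ci_high - summ.mean)
    fig, ax = plt.subplots(figsize=(4, 4))
    x = np.arange(len(sessions))
    ax.bar(x, means, color="0.7", edgecolor="k")
    ax.errorbar(x, means, yerr=[err_lo, err_hi], fmt="none", ecolor="k", capsize=4)
    ax.axhline(CHANCE, ls=":", color="0.4", label="chance")
    ax.set_xticks(x, sessions)
    ax.set_ylabel("Percent correct grasp optimality judgments")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
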
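"""Within-embryo expression-variability analysis.

Per-nucleus fluorescence tables (columns: embryo, nucleus, ap_percent,
fluorescence, line) are first adjusted for between-embryo differences by a
per-embryo multiplicative scale factor, fitted to minimise the sum of
squared pairwise differences between embryos in 1% AP bins subject to the
scale factors summing to the number of embryos.  The scaled, pooled nuclei
then support:

* an ordinary least-squares regression of per-bin standard deviation on
  per-bin mean (the mean-SD slope distinguishes noisy from quiet reporters
  at matched means);
* mean-normalisation (values divided by their 1% bin mean inside an AP
  window, default 60-80% embryo length) to compare distribution shapes
  independent of the mean;
* comparison with the steady-state mRNA distribution of the two-state
  (telegraph) promoter model, in which the transcript count and the ON/OFF
  promoter state are coupled random variables.  The model is parameterised
  by the ON-state transcription strength N (synthesis rate in units of the
  mRNA degradation rate), the probability p of the ON state, and a
  switching-rate parameter b (default 4), mapped to rate constants as
  k_on = b*p, k_off = b*(1-p).  The mean mRNA count is mu = N*p; at fixed
  mean, variance falls as p rises, which is the proposed mechanism for the
  quieter expression driven by chromatin-opening activators.
* a Fligner-Killeen variance-homogeneity test, computed from its
  definition: median-centred absolute deviations, normal-score ranks, and a
  chi-square statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NUCLEUS_COLUMNS",
    "EmbryoScaling",
    "TelegraphParams",
    "TelegraphDistribution",
    "fit_embryo_scales",
    "apply_embryo_scales",
    "mean_sd_regression",
    "mean_normalize",
    "telegraph_pmf",
    "variance_homogeneity_test",
]

NUCLEUS_COLUMNS = ("embryo", "nucleus", "ap_percent", "fluorescence", "line")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in NUCLEUS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus table is missing columns {missing}")
    if ((table["ap_percent"] < 0) | (table["ap_percent"] > 100)).any():
        raise ValueError("ap_percent must lie in [0, 100]")
    if (table["fluorescence"] < 0).any():
        raise ValueError("fluorescence must be >= 0")
    return table


def _ap_bin(ap: pd.Series, width: float = 1.0) -> pd.Series:
    # half-open bins [k*width, (k+1)*width)
    return np.floor(ap / width).astype(int)


@dataclass(frozen=True)
class EmbryoScaling:
    scales: dict[str, float]
    objective: float

    def __post_init__(self) -> None:
        total = sum(self.scales.values())
        if abs(total - len(self.scales)) > 1e-9:
            raise ValueError("scale factors must sum to the number of embryos")


def fit_embryo_scales(table: pd.DataFrame, bin_width: float = 1.0) -> EmbryoScaling:
    """Fit one multiplicative scale per embryo (see module docstring).

    The constrained quadratic is solved exactly via its KKT linear system.
    """
    table = _check_table(table)
    embryos = sorted(table["embryo"].unique())
    n = len(embryos)
    if n < 2:
        raise ValueError("need at least 2 embryos to fit scale factors")
    idx = {e: i for i, e in enumerate(embryos)}

    binned = table.assign(_bin=_ap_bin(table["ap_percent"], bin_width))
    means = binned.groupby(["_bin", "embryo"])["fluorescence"].mean()
    per_embryo_bins = means.groupby("embryo").size()
    for e in embryos:
        if per_embryo_bins.get(e, 0) == 0:
            raise ValueError(f"embryo {e!r} has no populated AP bins")

    q = np.zeros((n, n))
    shared = False
    for _bin, grp in means.groupby(level="_bin"):
        present = grp.index.get_level_values("embryo")
        m = grp.to_numpy()
        if len(present) < 2:
            continue
        shared = True
        ii = [idx[e] for e in present]
        for a in range(len(ii)):
            q[ii[a], ii[a]] += (len(ii) - 1) * m[a] ** 2
            for b in range(a + 1, len(ii)):
                q[ii[a], ii[b]] -= m[a] * m[b]
                q[ii[b], ii[a]] -= m[a] * m[b]
    if not shared:
        raise ValueError("no AP bin is shared by two or more embryos")

    # minimise s' Q s subject to sum(s) = n  (KKT system)
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * q
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[n] = float(n)
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    s = sol[:n]
    s = s * (n / s.sum())  # enforce the constraint exactly
    if np.any(s <= 0):
        warnings.warn("fitted scale factor(s) are nonpositive; data are degenerate",
                      stacklevel=2)
    return EmbryoScaling({e: float(s[idx[e]]) for e in embryos},
                         float(s @ q @ s))


def apply_embryo_scales(table: pd.DataFrame, scaling: EmbryoScaling) -> pd.DataFrame:
    """Return a copy with fluorescence multiplied by each embryo's scale."""
    table = _check_table(table)
    out = table.copy()
    out["fluorescence"] = out["fluorescence"] * out["embryo"].map(scaling.scales)
    return out


def mean_sd_regression(
    table: pd.DataFrame, bin_width: float = 1.0, ddof: int = 0
) -> tuple[float, float, pd.DataFrame]:
    """OLS of per-bin SD on per-bin mean over pooled (scaled) nuclei.

    Population SD (ddof=0) by default.  Returns (slope, intercept, per-bin
    frame with columns bin, mean, sd, n).
    """
    table = _check_table(table)
    binned = table.assign(_bin=_ap_bin(table["ap_percent"], bin_width))
    stats_df = (
        binned.groupby("_bin")["fluorescence"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=ddof), n="count")
        .reset_index()
        .rename(columns={"_bin": "bin"})
    )
    stats_df = stats_df[stats_df["n"] >= 1].dropna()
    if len(stats_df) < 3:
        raise ValueError("need at least 3 populated AP bins for the regression")
    slope, intercept = np.polyfit(stats_df["mean"], stats_df["sd"], deg=1)
    return float(slope), float(intercept), stats_df


def mean_normalize(
    table: pd.DataFrame,
    window: tuple[float, float] = (60.0, 80.0),
    bin_width: float = 1.0,
) -> np.ndarray:
    """Fluorescence divided by its 1% bin mean, within an AP window.

    Every bin in the window must be populated; the output has per-bin mean 1.
    """
    table = _check_table(table)
    lo, hi = window
    sub = table[(table["ap_percent"] >= lo) & (table["ap_percent"] < hi)].copy()
    sub["_bin"] = _ap_bin(sub["ap_percent"], bin_width)
    expected = set(range(int(np.floor(lo / bin_width)), int(np.floor(hi / bin_width))))
    populated = set(sub["_bin"].unique())
    empty = sorted(expected - populated)
    if empty:
        raise ValueError(f"AP bins {empty} in the window are empty")
    bin_means = sub.groupby("_bin")["fluorescence"].transform("mean")
    if (bin_means <= 0).any():
        raise ValueError("a window bin has zero mean fluorescence")
    return (sub["fluorescence"] / bin_means).to_numpy()


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state promoter parameters: strength N, ON-probability p, switching b."""

    N: float
    p: float
    b: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if self.N <= 0 or self.b <= 0:
            raise ValueError("N and b must be positive")

    @property
    def mean(self) -> float:
        return self.N * self.p


@dataclass(frozen=True)
class TelegraphDistribution:
    params: TelegraphParams
    alpha: np.ndarray = field(repr=False)  # P(OFF, n)
    beta: np.ndarray = field(repr=False)   # P(ON, n)

    @property
    def phi(self) -> np.ndarray:
        return self.alpha + self.beta

    @property
    def n(self) -> np.ndarray:
        return np.arange(self.alpha.size)

    @property
    def mean(self) -> float:
        return float(self.n @ self.phi)

    @property
    def variance(self) -> float:
        mu = self.mean
        return float((self.n**2) @ self.phi - mu**2)


def telegraph_pmf(params: TelegraphParams, n_max: int) -> TelegraphDistribution:
    """Steady-state mRNA distribution of the coupled ON-OFF promoter model.

    Solved numerically as the stationary distribution of the truncated
    master-equation generator over states (promoter in {OFF, ON}, n mRNA),
    with rates: synthesis N while ON, degradation n, switching k_on = b*p
    (OFF->ON) and k_off = b*(1-p) (ON->OFF).  Degradation units: time is
    measured in mRNA lifetimes.
    """
    if n_max < 5 * params.N:
        raise ValueError(f"n_max must be at least 5*N = {5 * params.N:.0f}")
    k_on = params.b * params.p
    k_off = params.b * (1.0 - params.p)
    size = 2 * (n_max + 1)  # state index: 2*n + g, g=0 OFF, g=1 ON

    gen = np.zeros((size, size))

    def st(n: int, g: int) -> int:
        return 2 * n + g

    for n in range(n_max + 1):
        # promoter switching
        gen[st(n, 1), st(n, 0)] += k_on
        gen[st(n, 0), st(n, 0)] -= k_on
        gen[st(n, 0), st(n, 1)] += k_off
        gen[st(n, 1), st(n, 1)] -= k_off
        # synthesis while ON
        if n < n_max:
            gen[st(n + 1, 1), st(n, 1)] += params.N
            gen[st(n, 1), st(n, 1)] -= params.N
        # degradation
        if n > 0:
            gen[st(n - 1, 0), st(n, 0)] += n
            gen[st(n, 0), st(n, 0)] -= n
            gen[st(n - 1, 1), st(n, 1)] += n
            gen[st(n, 1), st(n, 1)] -= n

    a = np.vstack([gen, np.ones(size)])
    rhs = np.zeros(size + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    alpha = pi[0::2]
    beta = pi[1::2]

    tail = float(alpha[-1] + beta[-1])
    if tail > 1e-6:
        raise ValueError(
            f"probability mass {tail:.2e} at the truncation boundary; raise n_max"
        )
    return TelegraphDistribution(params, alpha, beta)


def variance_homogeneity_test(x, y) -> tuple[float, float]:
    """Fligner-Killeen test of equal variances for two samples.

    Median-centred absolute deviations are ranked jointly; ranks are mapped
    to one-sided normal scores a_i = Phi^-1(1/2 + r_i / (2(n+1))); the
    statistic sum_g n_g (abar_g - abar)^2 / V is chi-square with one degree
    of freedom (two groups).  Returns (statistic, p_value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both samples are degenerate (all values equal)")
    centred = np.concatenate([np.abs(x - np.median(x)), np.abs(y - np.median(y))])
    n = centred.size
    ranks = stats.rankdata(centred)  # average ranks for ties
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (n + 1)))
    grand = scores.mean()
    v = np.sum((scores - grand) ** 2) / (n - 1)
    if v == 0:
        raise ValueError("degenerate samples: zero score variance")
    stat = 0.0
    for g in (scores[: x.size], scores[x.size :]):
        stat += g.size * (g.mean() - grand) ** 2
    stat /= v
    return float(stat), float(stats.chi2.sf(stat, df=1))
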
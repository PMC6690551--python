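"""Inferential statistics for genotype comparisons of song metrics.

Implements the battery used to compare song phenotypes across genotypes:
Fisher's exact test on monocyclic/polycyclic counts, the Mann-Whitney U test,
one-way ANOVA with Bonferroni-corrected pairwise t tests, and Kruskal-Wallis
followed by either Dwass-Steel-Critchlow-Fligner (DSCF) all-pairs or Steel
many-to-one nonparametric multiple comparisons.

Significance is annotated with the conventional stars: ``*`` p < 0.05,
``**`` p < 0.01, ``***`` p < 0.001, ``NS`` otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats as sps

ALPHA_LEVELS = (0.05, 0.01, 0.001)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class ContingencyTable2x2:
    """Counts with rows = genotypes and columns = monocyclic/polycyclic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class PairwiseComparison:
    label: str
    statistic: float
    p_raw: float
    p_adjusted: float

    @property
    def stars(self) -> str:
        return stars(self.p_adjusted)


@dataclass
class TestReport:
    """A test's omnibus statistic plus any pairwise comparisons."""

    test_name: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    notes: str = ""

    @property
    def stars(self) -> str:
        return stars(self.p_value)

    def to_rows(self) -> list[dict]:
        rows = [dict(comparison="omnibus", test=self.test_name,
                     statistic=self.statistic, p_raw=self.p_value,
                     p_adj=self.p_value, stars=self.stars)]
        for c in self.pairwise:
            rows.append(dict(comparison=c.label, test=self.test_name,
                             statistic=c.statistic, p_raw=c.p_raw,
                             p_adj=c.p_adjusted, stars=c.stars))
        return rows


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_exact(table: ContingencyTable2x2, sidedness: str = "two-sided") -> TestReport:
    """Fisher's exact probability test on a 2x2 table.

    The two-sided p-value sums the hypergeometric probabilities of all tables
    (with the observed margins) no more probable than the observed one.  The
    computation is exact integer arithmetic: every table with the same
    margins shares the denominator C(N, a+c), so probabilities are compared
    and summed as integer numerators.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("empty row or column margin: Fisher test undefined")
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    denom = math.comb(n, c1)
    obs = nums[a - lo]
    if sidedness == "two-sided":
        p_num = sum(v for v in nums if v <= obs)
    elif sidedness == "greater":  # enrichment of cell a
        p_num = sum(nums[a - lo:])
    elif sidedness == "less":
        p_num = sum(nums[:a - lo + 1])
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = min(1.0, p_num / denom)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestReport(test_name="fisher_exact", statistic=odds, p_value=p,
                      notes=f"sidedness={sidedness}")


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney_u(
    x, y, exact_max_n: int = 8, use_continuity: bool = True
) -> TestReport:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact by enumeration of all group labelings when ``min(n) <=
    exact_max_n`` (valid under ties, using the permutation distribution of
    the rank sum); otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if min(n1, n2) <= exact_max_n:
        # permutation distribution of U1 (symmetric about mu even under ties)
        ranks_arr = ranks
        obs_dev = abs(u1 - mu)
        count = 0
        total = 0
        offset = n1 * (n1 + 1) / 2.0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks_arr[list(comb)].sum() - offset
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
        p = count / total
        notes = "exact enumeration"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            return TestReport(test_name="mann_whitney_u", statistic=u1,
                              p_value=1.0, notes="degenerate: all values tied")
        dev = abs(u1 - mu)
        if use_continuity:
            dev = max(0.0, dev - 0.5)
        z = dev / math.sqrt(var)
        p = 2.0 * sps.norm.sf(z)
        notes = "normal approximation with tie correction"
    return TestReport(test_name="mann_whitney_u", statistic=u1,
                      p_value=min(1.0, p), notes=notes)


# ---------------------------------------------------------------------------
# one-way ANOVA + Bonferroni

def anova_bonferroni(groups, labels=None) -> TestReport:
    """One-way ANOVA; all-pairs pooled t tests with Bonferroni adjustment."""
    data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2 or any(g.size < 2 for g in data):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    labels = labels or [f"group{i}" for i in range(len(data))]
    grand = np.concatenate(data)
    if np.ptp(grand) == 0:
        f_stat, p_omni = 0.0, 1.0
    else:
        f_stat, p_omni = sps.f_oneway(*data)
        f_stat, p_omni = float(f_stat), float(p_omni)
    m = len(data) * (len(data) - 1) // 2
    pairwise = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(data), 2):
        if np.ptp(gi) == 0 and np.ptp(gj) == 0:
            t, p = (math.inf if gi[0] != gj[0] else 0.0), (0.0 if gi[0] != gj[0] else 1.0)
        else:
            t, p = sps.ttest_ind(gi, gj, equal_var=True)
            t, p = float(t), float(p)
        pairwise.append(PairwiseComparison(
            label=f"{labels[i]} vs {labels[j]}", statistic=t,
            p_raw=p, p_adjusted=min(1.0, p * m),
        ))
    return TestReport(test_name="anova_bonferroni", statistic=f_stat,
                      p_value=p_omni, pairwise=pairwise)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + DSCF / Steel

def _pair_ranksum_z(gi: np.ndarray, gj: np.ndarray) -> float:
    """Standardized rank sum of gj within the re-ranked pair (tie-corrected)."""
    ni, nj = gi.size, gj.size
    n = ni + nj
    ranks = sps.rankdata(np.concatenate([gi, gj]))
    w = float(ranks[ni:].sum())
    mean = nj * (n + 1) / 2.0
    _, t = np.unique(np.concatenate([gi, gj]), return_counts=True)
    tie = float(np.sum(t ** 3 - t))
    var = ni * nj / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var == 0:
        return 0.0
    return (w - mean) / math.sqrt(var)


def kruskal_steel_dwass(groups, labels=None, method: str = "asymptotic") -> TestReport:
    """Kruskal-Wallis omnibus plus DSCF all-pairs comparisons.

    Each pair of groups is re-ranked on its own; the standardized Wilcoxon
    rank sum times sqrt(2) is referred to the studentized range distribution
    with k groups (infinite degrees of freedom).  ``method='exact'``
    (per-group n <= 6) replaces the asymptotic pairwise p with the exact
    permutation p of the pair's rank sum, Bonferroni-adjusted -- a
    conservative small-sample variant.
    """
    data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 3 or any(g.size < 2 for g in data):
        raise ValueError("need >= 3 groups with >= 2 observations each")
    labels = labels or [f"group{i}" for i in range(len(data))]
    k = len(data)
    if np.ptp(np.concatenate(data)) == 0:
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = sps.kruskal(*data)
        h_stat, p_omni = float(h_stat), float(p_omni)
    pairwise = []
    m = k * (k - 1) // 2
    for (i, gi), (j, gj) in itertools.combinations(enumerate(data), 2):
        z = _pair_ranksum_z(gi, gj)
        q = abs(z) * math.sqrt(2.0)
        p_asym = float(sps.studentized_range.sf(q, k, np.inf))
        if method == "asymptotic":
            p_raw = p_adj = p_asym
        elif method == "exact":
            if max(gi.size, gj.size) > 6:
                raise ValueError("exact DSCF offered only for per-group n <= 6")
            p_raw = _exact_pair_permutation_p(gi, gj)
            p_adj = min(1.0, p_raw * m)
        else:
            raise ValueError(f"unknown method {method!r}")
        pairwise.append(PairwiseComparison(
            label=f"{labels[i]} vs {labels[j]}", statistic=q,
            p_raw=p_raw, p_adjusted=p_adj,
        ))
    return TestReport(test_name="kruskal_steel_dwass", statistic=h_stat,
                      p_value=p_omni, pairwise=pairwise, notes=f"method={method}")


def _exact_pair_permutation_p(gi: np.ndarray, gj: np.ndarray) -> float:
    ni, nj = gi.size, gj.size
    pooled = np.concatenate([gi, gj])
    ranks = sps.rankdata(pooled)
    mean = nj * (ni + nj + 1) / 2.0
    obs = abs(float(ranks[ni:].sum()) - mean)
    count = total = 0
    for comb in itertools.combinations(range(ni + nj), nj):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= obs - 1e-9:
            count += 1
    return count / total


def _steel_joint_p(z_obs: float, lambdas: np.ndarray) -> float:
    """P(max_j |Z_j| >= z_obs) for one-factor correlated standard normals.

    The Steel comparisons share the control sample, inducing the one-factor
    structure Z_j = sqrt(lambda_j) T + sqrt(1 - lambda_j) E_j with
    lambda_j = n_j / (n_j + n_0); the joint tail is a single numerically
    integrated expectation over the shared factor.
    """
    z_obs = abs(z_obs)
    sl = np.sqrt(lambdas)
    su = np.sqrt(1.0 - lambdas)

    def inner(t):
        upper = (z_obs - sl * t) / su
        lower = (-z_obs - sl * t) / su
        return sps.norm.pdf(t) * np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower))

    prob_inside, _ = integrate.quad(inner, -8.5, 8.5, limit=200)
    return float(min(1.0, max(0.0, 1.0 - prob_inside)))


def kruskal_steel(groups, control_index: int = 0, labels=None) -> TestReport:
    """Kruskal-Wallis omnibus plus Steel many-to-one comparisons vs a control.

    Each treatment is re-ranked jointly with the control; the standardized
    rank sum is referred to the maximum of jointly correlated normals
    (correlation induced by the shared control), evaluated by numerical
    integration over the shared factor.
    """
    data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 3 or any(g.size < 2 for g in data):
        raise ValueError("need a control plus >= 2 treatments, n >= 2 each")
    if not 0 <= control_index < len(data):
        raise ValueError(f"control_index {control_index} out of range")
    labels = labels or [f"group{i}" for i in range(len(data))]
    if np.ptp(np.concatenate(data)) == 0:
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = sps.kruskal(*data)
    control = data[control_index]
    n0 = control.size
    treat = [(i, g) for i, g in enumerate(data) if i != control_index]
    lambdas = np.array([g.size / (g.size + n0) for _, g in treat])
    pairwise = []
    for (i, g), lam in zip(treat, lambdas):
        z = _pair_ranksum_z(control, g)
        p = _steel_joint_p(z, lambdas)
        pairwise.append(PairwiseComparison(
            label=f"{labels[i]} vs {labels[control_index]} (control)",
            statistic=z, p_raw=p, p_adjusted=p,
        ))
    return TestReport(test_name="kruskal_steel", statistic=float(h_stat),
                      p_value=float(p_omni), pairwise=pairwise)


def fisher_from_summaries(summary_a: dict, summary_b: dict) -> TestReport:
    """Fisher's exact test on polycyclic incidence from two analysis summaries."""
    def counts(s):
        n, npoly = int(s["n_pulses"]), int(s["n_polycyclic"])
        return n - npoly, npoly
    a, b = counts(summary_a)
    c, d = counts(summary_b)
    return fisher_exact(ContingencyTable2x2(a, b, c, d))
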
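"""Repeated-measures statistical battery.

For each measure the protocol runs a one-way within-subjects ANOVA over the
three epochs with sphericity handling (Mauchly's test; Greenhouse-Geisser and
Huynh-Feldt epsilon corrections chosen by the 0.75 rule), Bonferroni-adjusted
pairwise comparisons, polynomial (linear/quadratic) a priori contrasts, the
partial-eta-squared -> Cohen's f conversion, and noncentral-F power /
sample-size analysis for the within-factor design.

All of it is implemented directly on the sums-of-squares decomposition and
scipy's central/noncentral F distributions, so every reported quantity (F,
df, epsilon, exact p, effect size) is available for complete reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import EPOCH_LABELS

EPOCH_ORDER = EPOCH_LABELS  # (relax, happiness, stress)

ALL_PAIRS = (("relax", "happiness"), ("happiness", "stress"), ("relax", "stress"))

#: orthonormal polynomial contrast coefficients for 3 ordered levels
LINEAR_COEF = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
QUADRATIC_COEF = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)

#: Greenhouse-Geisser threshold above which the Huynh-Feldt correction is
#: preferred (Girden's rule)
GIRDEN_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float          # mean(first) - mean(second)
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "mean_diff": self.mean_diff,
                "t": self.t, "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted, "significant": self.significant}


@dataclass
class ContrastResult:
    linear_estimate: float
    quadratic_estimate: float
    linear_F: float
    quadratic_F: float
    linear_p: float
    quadratic_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class RmBattery:
    """Complete within-subjects battery for one measure."""

    measure: str
    n_subjects: int
    epoch_means: dict[str, float]
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_W: float
    mauchly_p: float
    epsilon_gg: float
    epsilon_hf: float
    correction_used: str        # none | GG | HF
    df1_corrected: float
    df2_corrected: float
    p_corrected: float
    partial_eta_sq: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    contrasts: Optional[ContrastResult] = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("pairwise", "contrasts")}
        d["pairwise"] = [p.to_dict() for p in self.pairwise]
        d["contrasts"] = self.contrasts.to_dict() if self.contrasts else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RmBattery":
        d = dict(d)
        pw = [PairwiseResult(pair=tuple(p["pair"]),
                             mean_diff=p["mean_diff"], t=p["t"],
                             p_raw=p["p_raw"], p_adjusted=p["p_adjusted"],
                             significant=p["significant"])
              for p in d.pop("pairwise", [])]
        co = d.pop("contrasts", None)
        return cls(**d, pairwise=pw,
                   contrasts=ContrastResult(**co) if co else None)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _wide_matrix(table: pd.DataFrame, measure: str,
                 order: Sequence[str] = EPOCH_ORDER) -> np.ndarray:
    """Pivot the long index table to an (n subjects) x (k epochs) matrix."""
    if measure not in table.columns:
        raise KeyError(f"measure {measure!r} not in table")
    wide = table.pivot(index="subject", columns="epoch", values=measure)
    missing = set(order) - set(wide.columns)
    if missing:
        raise ValueError(f"missing epoch level(s): {sorted(missing)}")
    wide = wide[list(order)]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing cells for subjects {bad}")
    return wide.to_numpy(dtype=float)


def _orthonormal_basis(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast basis (normalized Helmert rows)."""
    m = np.zeros((k - 1, k))
    for i in range(k - 1):
        m[i, :i + 1] = 1.0
        m[i, i + 1] = -(i + 1)
        m[i] /= np.linalg.norm(m[i])
    return m


def sphericity_epsilons(Y: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilon estimates from the sample
    covariance of the k condition columns.  HF is floored at GG and capped
    at 1."""
    n, k = Y.shape
    S = np.cov(Y, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    Sd = C @ S @ C
    num = np.trace(Sd) ** 2
    den = (k - 1) * np.sum(Sd * Sd)
    eps_gg = 1.0 if den <= 0 else float(num / den)
    eps_gg = min(1.0, max(1.0 / (k - 1), eps_gg))
    hf_den = (k - 1) * (n - 1 - (k - 1) * eps_gg)
    if hf_den <= 0:
        eps_hf = 1.0
    else:
        eps_hf = (n * (k - 1) * eps_gg - 2.0) / hf_den
    eps_hf = min(1.0, max(eps_gg, float(eps_hf)))
    return eps_gg, eps_hf


def mauchly_test(Y: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square approximation p-value."""
    n, k = Y.shape
    S = np.cov(Y, rowvar=False)
    M = _orthonormal_basis(k)
    A = M @ S @ M.T
    tr = np.trace(A)
    if tr <= 0:
        return 1.0, 1.0
    det = np.linalg.det(A)
    W = float(det / (tr / (k - 1)) ** (k - 1))
    W = min(max(W, 0.0), 1.0)
    df = k * (k - 1) // 2 - 1
    if df <= 0:        # k = 2: sphericity holds trivially
        return W, 1.0
    if W <= 0:
        return W, 0.0
    corr = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * (n - 1))
    chi2 = -(n - 1) * corr * math.log(W)
    return W, float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# rmANOVA
# ---------------------------------------------------------------------------

def rm_anova(table: pd.DataFrame, measure: str, alpha: float = 0.05,
             order: Sequence[str] = EPOCH_ORDER,
             pairs: Sequence[tuple[str, str]] = ALL_PAIRS[:2]) -> RmBattery:
    """One-way within-subjects ANOVA with sphericity handling, plus the
    pairwise comparisons and polynomial contrasts of the protocol.

    The GG/HF correction is applied only when Mauchly's test is significant
    at ``alpha``; Girden's rule (GG epsilon > 0.75 -> use HF) then selects
    which correction.  Both raw and corrected p are always reported.
    """
    Y = _wide_matrix(table, measure, order)
    n, k = Y.shape
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")

    grand = Y.mean()
    cond_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_tot = float(np.sum((Y - grand) ** 2))
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1 = float(k - 1)
    df2 = float((n - 1) * (k - 1))

    degenerate = ss_err <= 1e-300
    if degenerate and ss_cond <= 1e-300:
        F = 0.0
        p_unc = 1.0
    elif degenerate:
        F = math.inf
        p_unc = 0.0
    else:
        F = (ss_cond / df1) / (ss_err / df2)
        p_unc = float(sps.f.sf(F, df1, df2))
    eta_p = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0

    eps_gg, eps_hf = sphericity_epsilons(Y)
    W, mauchly_p = mauchly_test(Y)

    if mauchly_p >= alpha:
        correction, eps = "none", 1.0
    elif eps_gg > GIRDEN_THRESHOLD:
        correction, eps = "HF", eps_hf
    else:
        correction, eps = "GG", eps_gg
    df1_c, df2_c = eps * df1, eps * df2
    if correction == "none":
        p_corr = p_unc
    elif math.isinf(F):
        p_corr = 0.0
    else:
        p_corr = float(sps.f.sf(F, df1_c, df2_c))

    battery = RmBattery(
        measure=measure, n_subjects=n,
        epoch_means={lab: float(m) for lab, m in zip(order, cond_means)},
        F=float(F), df1=df1, df2=df2, p_uncorrected=p_unc,
        mauchly_W=W, mauchly_p=mauchly_p,
        epsilon_gg=eps_gg, epsilon_hf=eps_hf,
        correction_used=correction, df1_corrected=df1_c, df2_corrected=df2_c,
        p_corrected=p_corr, partial_eta_sq=float(eta_p),
        degenerate=degenerate,
    )
    usable = tuple(p for p in pairs if set(p) <= set(order))
    battery.pairwise = pairwise_bonferroni(table, measure, pairs=usable,
                                           alpha=alpha, order=order)
    if k >= 3:
        battery.contrasts = polynomial_contrasts(table, measure, order=order)
    return battery


def pairwise_bonferroni(table: pd.DataFrame, measure: str,
                        pairs: Sequence[tuple[str, str]] = ALL_PAIRS[:2],
                        alpha: float = 0.05,
                        order: Sequence[str] = EPOCH_ORDER) -> list[PairwiseResult]:
    """Paired-difference t tests on subject-matched epochs with Bonferroni
    adjustment: p_adjusted = min(1, m * p_raw), m = number of comparisons."""
    Y = _wide_matrix(table, measure, order)
    idx = {lab: i for i, lab in enumerate(order)}
    m = len(pairs)
    out = []
    for pair in pairs:
        a, b = pair
        if a not in idx or b not in idx:
            raise ValueError(f"unknown pair label in {pair!r}")
        d = Y[:, idx[a]] - Y[:, idx[b]]
        n = len(d)
        sd = float(np.std(d, ddof=1))
        if sd == 0:
            t = 0.0 if np.mean(d) == 0 else math.inf * np.sign(np.mean(d))
            p = 1.0 if t == 0 else 0.0
        else:
            t = float(np.mean(d) / (sd / math.sqrt(n)))
            p = float(2 * sps.t.sf(abs(t), n - 1))
        p_adj = min(1.0, m * p)
        out.append(PairwiseResult(pair=tuple(pair), mean_diff=float(np.mean(d)),
                                  t=t, p_raw=p, p_adjusted=p_adj,
                                  significant=p_adj < alpha))
    return out


def polynomial_contrasts(table: pd.DataFrame, measure: str,
                         order: Sequence[str] = EPOCH_ORDER) -> ContrastResult:
    """Linear and quadratic trend contrasts over the ordered epochs.

    Normalized coefficients are applied per subject; a one-sample test of the
    contrast scores against zero gives F (= t^2) and p per contrast.  Testing
    the per-subject scores uses each contrast's own error term, which is
    robust to sphericity violation.
    """
    Y = _wide_matrix(table, measure, order)
    n = Y.shape[0]
    res = {}
    for name, coef in (("linear", LINEAR_COEF), ("quadratic", QUADRATIC_COEF)):
        scores = Y @ coef
        est = float(np.mean(scores))
        sd = float(np.std(scores, ddof=1))
        if sd == 0:
            F = 0.0 if est == 0 else math.inf
            p = 1.0 if est == 0 else 0.0
        else:
            t = est / (sd / math.sqrt(n))
            F = float(t ** 2)
            p = float(sps.f.sf(F, 1, n - 1))
        res[name] = (est, F, p)
    return ContrastResult(linear_estimate=res["linear"][0],
                          quadratic_estimate=res["quadratic"][0],
                          linear_F=res["linear"][1],
                          quadratic_F=res["quadratic"][1],
                          linear_p=res["linear"][2],
                          quadratic_p=res["quadratic"][2])


def run_battery(table: pd.DataFrame, measures: Sequence[str],
                alpha: float = 0.05) -> dict[str, RmBattery]:
    """Run the full battery for every requested measure."""
    return {m: rm_anova(table, m, alpha=alpha) for m in measures}


# ---------------------------------------------------------------------------
# Effect size and power
# ---------------------------------------------------------------------------

def cohens_f_from_eta(partial_eta_sq: float) -> float:
    """Cohen's f = sqrt(eta^2 / (1 - eta^2))."""
    if not (0.0 <= partial_eta_sq < 1.0):
        raise ValueError(f"partial eta squared must be in [0, 1), "
                         f"got {partial_eta_sq}")
    return math.sqrt(partial_eta_sq / (1.0 - partial_eta_sq))


@dataclass
class PowerSpec:
    """Inputs of the a priori repeated-measures power analysis."""

    f: float = 0.25             # Cohen's effect size
    alpha: float = 0.05
    target_power: float = 0.8
    n_groups: int = 1
    k_measurements: int = 3
    rho: float = 0.5            # correlation among repeated measures
    epsilon: float = 1.0        # nonsphericity correction
    lambda_uses_epsilon: bool = False  # optional ε-scaled λ convention

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("effect size f must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target_power must be in (0, 1)")
        if self.k_measurements < 2:
            raise ValueError("need k >= 2 repeated measurements")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


@dataclass
class PowerResult:
    N: int
    lam: float
    F_crit: float
    df1: float
    df2: float
    achieved_power: float

    def to_dict(self) -> dict:
        return {"N": self.N, "lambda": self.lam, "F_crit": self.F_crit,
                "df1": self.df1, "df2": self.df2,
                "achieved_power": self.achieved_power}


def _power_at(spec: PowerSpec, N: int) -> PowerResult:
    k, g, eps = spec.k_measurements, spec.n_groups, spec.epsilon
    df1 = (k - 1) * eps
    df2 = (N - g) * (k - 1) * eps
    if df2 <= 0:
        raise ValueError(f"nonpositive denominator df at N={N}")
    lam = spec.f ** 2 * N * k / (1.0 - spec.rho)
    if spec.lambda_uses_epsilon:
        lam *= eps
    F_crit = float(sps.f.isf(spec.alpha, df1, df2))
    power = float(sps.ncf.sf(F_crit, df1, df2, lam))
    return PowerResult(N=N, lam=lam, F_crit=F_crit, df1=df1, df2=df2,
                       achieved_power=power)


def achieved_power(spec: PowerSpec, N: int) -> PowerResult:
    """Post hoc power of the within-factor F test at fixed total N."""
    return _power_at(spec, N)


def apriori_sample_size(spec: PowerSpec, n_max: int = 10 ** 6) -> PowerResult:
    """Smallest total N whose noncentral-F power reaches the target.

    The noncentrality is the within-factor convention lambda =
    f^2 * N * k / (1 - rho), with numerator df (k-1)*epsilon and denominator
    df (N - groups) * (k-1) * epsilon.
    """
    N = spec.n_groups + 1
    while (N - spec.n_groups) * (spec.k_measurements - 1) * spec.epsilon <= 0:
        N += 1
    while N <= n_max:
        res = _power_at(spec, N)
        if res.achieved_power >= spec.target_power:
            return res
        N += 1
    raise ValueError(f"target power {spec.target_power} unreachable at N <= {n_max}")
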
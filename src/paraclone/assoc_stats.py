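"""Association statistics for allele-count tables.

Implements, from the standard formulas, the statistics used to test rare
pathogenic alleles against population controls and to pool independent case
series:

* two-sided Fisher's exact test by direct enumeration of the conditional
  hypergeometric distribution (point-probability rule, the behaviour of the
  usual statistical software);
* Mantel–Haenszel common-effects pooled odds ratio with the
  Robins–Breslow–Greenland variance estimator, Wald 95% CI and z test;
* Cochran's Q, I² and the DerSimonian–Laird between-study variance τ²,
  computed on inverse-variance-weighted log odds ratios;
* normal-approximation two-proportion sample size, with and without
  continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, hypergeom, norm

_Z975 = 1.959964


class TableError(ValueError):
    pass


@dataclass(frozen=True)
class TwoByTwoTable:
    """Allele-count table: a/b case alt/ref, c/d control alt/ref."""

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise TableError("negative cell count")
        if self.a + self.b == 0 or self.c + self.d == 0 \
                or self.a + self.c == 0 and self.b + self.d == 0:
            raise TableError("empty margin")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def case_af(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_af(self) -> float:
        return self.c / (self.c + self.d)

    @property
    def crude_or(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    def haldane(self) -> "TwoByTwoTable":
        """Add 0.5 to every cell if (and only if) the table has a zero cell."""
        if min(self.a, self.b, self.c, self.d) > 0:
            return self
        return _ContinuityTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5,
                                self.label)


@dataclass(frozen=True)
class _ContinuityTable:
    a: float
    b: float
    c: float
    d: float
    label: str = ""

    crude_or = TwoByTwoTable.crude_or
    n = TwoByTwoTable.n


def build_table_from_counts(
    alt_cases: int, n_case_alleles: int,
    alt_controls: int, n_control_alleles: int,
    label: str = "",
) -> TwoByTwoTable:
    """Build the 2x2 table from alt-allele counts and total allele counts."""
    b = n_case_alleles - alt_cases
    d = n_control_alleles - alt_controls
    if b < 0 or d < 0:
        raise TableError("alt count exceeds total allele count")
    return TwoByTwoTable(alt_cases, b, alt_controls, d, label)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float


def fisher_exact_two_sided(table: TwoByTwoTable) -> FisherResult:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed one (with a 1+1e-7
    relative slack); computed in log space so large counts are exact to
    double precision.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        # only one attainable table given these margins
        return FisherResult(1.0)
    N, K, n = table.n, a + b, a + c
    lo, hi = max(0, n - (c + d)), min(K, n)
    xs = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(xs, N, K, n)
    logp_obs = hypergeom.logpmf(a, N, K, n)
    keep = logp <= logp_obs + math.log1p(1e-7)
    p = float(np.exp(logp[keep] - logp_obs).sum() * np.exp(logp_obs))
    return FisherResult(min(p, 1.0))


@dataclass(frozen=True)
class StudyEffect:
    label: str
    or_crude: float
    log_or: float
    var_log_or: float

    @property
    def iv_weight(self) -> float:
        return 1.0 / self.var_log_or

    @property
    def ci(self) -> tuple[float, float]:
        se = math.sqrt(self.var_log_or)
        return (math.exp(self.log_or - _Z975 * se), math.exp(self.log_or + _Z975 * se))


@dataclass(frozen=True)
class MetaResult:
    or_mh: float
    log_or_se: float
    ci_low: float
    ci_high: float
    p_z: float
    studies: tuple[StudyEffect, ...]
    q: float | None = None
    df: int | None = None
    p_q: float | None = None
    i2_pct: float | None = None
    tau2_dl: float | None = None


def _study_effects(tables: list[TwoByTwoTable]) -> tuple[StudyEffect, ...]:
    out = []
    for t in tables:
        h = t.haldane()
        log_or = math.log((h.a * h.d) / (h.b * h.c))
        var = 1 / h.a + 1 / h.b + 1 / h.c + 1 / h.d
        out.append(StudyEffect(t.label, t.crude_or, log_or, var))
    return tuple(out)


def mh_common_or(tables: list[TwoByTwoTable]) -> MetaResult:
    """Mantel–Haenszel common-effects pooled OR with RBG variance.

    ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the variance of the
    log pooled OR uses the Robins–Breslow–Greenland estimator; the 95% CI is
    Wald on the log scale and ``p_z`` is the two-sided z test of log OR = 0.
    Heterogeneity fields are filled when two or more tables are given.
    """
    if not tables:
        raise TableError("at least one table is required")
    R = [t.a * t.d / t.n for t in tables]
    S = [t.b * t.c / t.n for t in tables]
    sR, sS = sum(R), sum(S)
    if sS == 0:
        raise TableError("pooled OR undefined: sum(b_i c_i / n_i) is zero")
    or_mh = sR / sS
    P = [(t.a + t.d) / t.n for t in tables]
    Q_ = [(t.b + t.c) / t.n for t in tables]
    var = (
        sum(p * r for p, r in zip(P, R)) / (2 * sR * sR)
        + sum(p * s + q * r for p, q, r, s in zip(P, Q_, R, S)) / (2 * sR * sS)
        + sum(q * s for q, s in zip(Q_, S)) / (2 * sS * sS)
    )
    se = math.sqrt(var)
    log_or = math.log(or_mh)
    ci = (math.exp(log_or - _Z975 * se), math.exp(log_or + _Z975 * se))
    p_z = 2.0 * float(norm.sf(abs(log_or / se)))
    het = heterogeneity(tables) if len(tables) >= 2 else None
    return MetaResult(
        or_mh=or_mh, log_or_se=se, ci_low=ci[0], ci_high=ci[1], p_z=p_z,
        studies=_study_effects(tables),
        q=het[0] if het else None, df=het[1] if het else None,
        p_q=het[2] if het else None, i2_pct=het[3] if het else None,
        tau2_dl=het[4] if het else None,
    )


def heterogeneity(tables: list[TwoByTwoTable]) -> tuple[float, int, float, float, float]:
    """(Q, df, p_Q, I² %, τ²_DL) on inverse-variance log odds ratios.

    Haldane's +0.5 is applied per study, only to studies with a zero cell.
    I² = max(0, (Q - df)/Q)·100; τ² is DerSimonian–Laird, floored at zero.
    """
    if len(tables) < 2:
        raise TableError("heterogeneity needs at least two tables")
    eff = _study_effects(tables)
    w = np.array([e.iv_weight for e in eff])
    y = np.array([e.log_or for e in eff])
    mu = float((w * y).sum() / w.sum())
    q = float((w * (y - mu) ** 2).sum())
    df = len(tables) - 1
    p_q = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, df, p_q, i2, tau2


def inverse_variance_or(tables: list[TwoByTwoTable]) -> tuple[float, tuple[float, float]]:
    """Inverse-variance pooled OR (exposed as an option; not the default)."""
    eff = _study_effects(tables)
    w = np.array([e.iv_weight for e in eff])
    y = np.array([e.log_or for e in eff])
    mu = float((w * y).sum() / w.sum())
    se = math.sqrt(1.0 / w.sum())
    return math.exp(mu), (math.exp(mu - _Z975 * se), math.exp(mu + _Z975 * se))


def forest_table(meta: MetaResult) -> "pd.DataFrame":
    """Per-study OR, 95% CI and IV weight plus the pooled row — the data
    behind a forest plot."""
    import pandas as pd

    rows = []
    wsum = sum(e.iv_weight for e in meta.studies)
    for e in meta.studies:
        lo, hi = e.ci
        rows.append({
            "study": e.label or f"study{len(rows) + 1}",
            "or": e.or_crude, "ci_low": lo, "ci_high": hi,
            "weight_pct": 100.0 * e.iv_weight / wsum,
        })
    rows.append({
        "study": "pooled (MH common effects)",
        "or": meta.or_mh, "ci_low": meta.ci_low, "ci_high": meta.ci_high,
        "weight_pct": 100.0,
    })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PowerSpec:
    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.8
    correction: str = "none"       # "none" | "continuity"

    def __post_init__(self) -> None:
        if not (0.0 < self.p2 < self.p1 < 1.0):
            raise TableError("require 0 < p2 < p1 < 1")
        if self.correction not in ("none", "continuity"):
            raise TableError("correction must be 'none' or 'continuity'")


def sample_size_two_proportions(spec: PowerSpec) -> int:
    """Per-group sample size for detecting p1 vs p2 (normal approximation).

    Uncorrected: ``n = (z_{1-a/2} sqrt(2 p̄ q̄) + z_{1-b} sqrt(p1 q1 + p2 q2))²
    / (p1 - p2)²``; the continuity-corrected size is
    ``n' = (n/4) (1 + sqrt(1 + 4/(n |p1-p2|)))²``. Both are rounded up.
    """
    za = float(norm.ppf(1.0 - spec.alpha / 2.0))
    zb = float(norm.ppf(spec.power))
    p1, p2 = spec.p1, spec.p2
    pbar = (p1 + p2) / 2.0
    delta = p1 - p2
    n = (za * math.sqrt(2 * pbar * (1 - pbar))
         + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2 / delta ** 2
    if spec.correction == "continuity":
        n = (n / 4.0) * (1.0 + math.sqrt(1.0 + 4.0 / (n * abs(delta)))) ** 2
    return math.ceil(n)


# ---------------------------------------------------------------------------
# the published allele-count tables this package re-analyses

def published_tables() -> dict[str, TwoByTwoTable]:
    """Allele-count tables printed by the study: three Gaucher-pathogenic
    variants in the current MSA series vs population controls, plus the
    previous series for the p.L483P analogue."""
    return {
        "p.S310G": build_table_from_counts(1, 998, 3, 17554, "p.S310G"),
        "c.del1447_1466insTG": build_table_from_counts(1, 998, 0, 17554, "c.del1447_1466insTG"),
        "p.L483P_current": build_table_from_counts(3, 998, 20, 17554, "current study"),
        "p.L483P_previous": build_table_from_counts(4, 1148, 2, 1800, "previous study"),
    }


def replicate_association_analysis() -> dict:
    """Recompute every published association number from the printed counts:
    the four Fisher p-values, the two-study meta-analysis and the two-sided
    two-proportion sample sizes for the observed allele frequencies."""
    t = published_tables()
    meta = mh_common_or([t["p.L483P_current"], t["p.L483P_previous"]])
    return {
        "fisher_p": {k: fisher_exact_two_sided(v).p_two_sided for k, v in t.items()},
        "meta": meta,
        "n_uncorrected": sample_size_two_proportions(PowerSpec(0.0030, 0.0011)),
        "n_continuity": sample_size_two_proportions(
            PowerSpec(0.0030, 0.0011, correction="continuity")
        ),
    }
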
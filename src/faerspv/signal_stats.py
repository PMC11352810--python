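"""Disproportionality statistics on drug-by-event 2x2 tables.

For a drug D and an event query Q over a corpus of N reports::

                Q       not Q
    D           a       b
    not D       c       d

PRR = (a/(a+b)) / (c/(c+d)); ROR = ad/bc; the chi-square statistic is
Pearson's without continuity correction. The information component (IC) is
available in three variants:

``log2_oe``
    log2 of the observed/expected ratio a*N/((a+b)(a+c)); undefined at
    a = 0. The 95% interval uses a delta-method normal approximation with
    Var(ln O/E) ~= 1/a.
``log2_oe_shrunk``
    log2((a+0.5)/(E+0.5)) with E = (a+b)(a+c)/N; finite at a = 0.
``bcpnn_bate1998``
    The Bayesian confidence-propagation closed form with standard priors
    (Beta(1,1) margins, prior IC expectation 0). The point IC is the
    published posterior-expectation formula; IC025 is a Cornish-Fisher
    quantile built from the exact posterior log-moments (digamma /
    polygamma), which tracks the Monte-Carlo posterior quantile closely
    even for small cell counts.

A pair is a potential signal when n >= 3, PRR >= 2, ROR >= 2, chi-square
>= 4 and IC025 >= 0; any undefined metric vetoes the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import polygamma, psi

IC_METHODS = ("bcpnn_bate1998", "log2_oe", "log2_oe_shrunk")

_LN2 = math.log(2.0)
_Z975 = 1.959963984540054


class ConsistencyError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConsistencyError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(
    drug_subset: set[str], flagged_overall: set[str], corpus_size: int
) -> ContingencyTable:
    """Build the 2x2 table for one drug-query pair from report-id sets.

    ``flagged_overall`` must be computed on the full cleaned corpus, whose
    size is the table total.
    """
    a = len(drug_subset & flagged_overall)
    b = len(drug_subset) - a
    c = len(flagged_overall) - a
    d = corpus_size - a - b - c
    if d < 0:
        raise ConsistencyError(
            f"corpus_size {corpus_size} smaller than |drug|+|query|-overlap"
        )
    return ContingencyTable(a, b, c, d)


def prr(table: ContingencyTable) -> float | None:
    """Proportional reporting ratio; None when undefined (empty drug row or
    no comparator events)."""
    if table.a + table.b == 0 or table.c == 0:
        return None
    return (table.a / (table.a + table.b)) / (table.c / (table.c + table.d))


def ror(table: ContingencyTable) -> float | None:
    """Reporting odds ratio ad/bc; None when b or c is zero."""
    if table.b == 0 or table.c == 0:
        return None
    return (table.a * table.d) / (table.b * table.c)


def chi_square(table: ContingencyTable) -> float | None:
    """Pearson chi-square without continuity correction; None when a margin
    is zero. Well-defined (and possibly large) even when a = 0."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return None
    stat = 0.0
    for obs, r, col in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        exp = r * col / n
        stat += (obs - exp) ** 2 / exp
    return stat


def _bcpnn_posteriors(table: ContingencyTable):
    """Posterior Beta parameters of (p11, p_drug, p_event) under the
    standard priors: margins Beta(1,1); joint-cell prior Beta(g11, g-g11)
    with g11 = 1 and g set so the prior IC expectation is zero."""
    a = table.a
    n = table.n
    cx = table.a + table.b
    cy = table.a + table.c
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((cx + alpha1) * (cy + beta1))
    p11 = (a + gamma11, n - a + gamma - gamma11)
    px = (cx + alpha1, n - cx + alpha - alpha1)
    py = (cy + beta1, n - cy + beta - beta1)
    return p11, px, py


def _beta_log_cumulants(u: float, v: float) -> tuple[float, float, float]:
    """First three cumulants of ln X for X ~ Beta(u, v)."""
    k1 = psi(u) - psi(u + v)
    k2 = polygamma(1, u) - polygamma(1, u + v)
    k3 = polygamma(2, u) - polygamma(2, u + v)
    return float(k1), float(k2), float(k3)


def ic(table: ContingencyTable, method: str = "bcpnn_bate1998") -> float | None:
    """Information component (log2 observed/expected measure)."""
    if method not in IC_METHODS:
        raise ConfigurationError(f"unknown IC method {method!r}")
    a = table.a
    n = table.n
    cx = table.a + table.b
    cy = table.a + table.c
    if method == "log2_oe":
        if a == 0 or cx == 0 or cy == 0:
            return None
        return math.log2(a * n / (cx * cy))
    if method == "log2_oe_shrunk":
        if n == 0:
            return None
        expected = cx * cy / n
        return math.log2((a + 0.5) / (expected + 0.5))
    (a11, b11), (ax, bx), (ay, by) = _bcpnn_posteriors(table)
    return math.log2(
        (a11 / (a11 + b11)) / ((ax / (ax + bx)) * (ay / (ay + by)))
    )


def ic025(table: ContingencyTable, method: str = "bcpnn_bate1998") -> float | None:
    """Lower bound of the 95% interval of the information component."""
    if method not in IC_METHODS:
        raise ConfigurationError(f"unknown IC method {method!r}")
    point = ic(table, method)
    if point is None:
        return None
    if method == "log2_oe":
        sd = math.sqrt(1.0 / table.a) / _LN2
        return point - _Z975 * sd
    if method == "log2_oe_shrunk":
        sd = math.sqrt(1.0 / (table.a + 0.5)) / _LN2
        return point - _Z975 * sd
    # bcpnn: IC = (ln p11 - ln px - ln py) / ln 2 with independent Beta
    # posteriors; use exact cumulants and a Cornish-Fisher 2.5% quantile.
    p11, px, py = _bcpnn_posteriors(table)
    k1 = k2 = k3 = 0.0
    for (u, v), sign in ((p11, 1.0), (px, -1.0), (py, -1.0)):
        c1, c2, c3 = _beta_log_cumulants(u, v)
        k1 += sign * c1
        k2 += c2
        k3 += sign * c3
    skew = k3 / k2**1.5
    z = -_Z975
    w = z + skew * (z * z - 1.0) / 6.0
    return (k1 + math.sqrt(k2) * w) / _LN2


@dataclass
class SignalResult:
    """All disproportionality metrics for one drug-query pair. ``None``
    metric values correspond to the "-" cells of printed signal tables."""

    drug_id: str
    query: str
    n: int
    prr: float | None
    ror: float | None
    chi2: float | None
    ic: float | None
    ic025: float | None
    signal: bool
    ic_method: str


def evaluate_signal(
    n: int,
    prr_value: float | None,
    ror_value: float | None,
    chi2_value: float | None,
    ic025_value: float | None,
) -> bool:
    """Signal decision: n >= 3, PRR >= 2, ROR >= 2, chi-square >= 4 and
    IC025 >= 0; an undefined metric makes the decision False."""
    if None in (prr_value, ror_value, chi2_value, ic025_value):
        return False
    return (
        n >= 3
        and prr_value >= 2
        and ror_value >= 2
        and chi2_value >= 4
        and ic025_value >= 0
    )


def compute_signal(
    drug_id: str, query: str, table: ContingencyTable, ic_method: str = "bcpnn_bate1998"
) -> SignalResult:
    prr_v = prr(table)
    ror_v = ror(table)
    chi2_v = chi_square(table)
    ic_v = ic(table, ic_method)
    ic025_v = ic025(table, ic_method)
    return SignalResult(
        drug_id=drug_id,
        query=query,
        n=table.a,
        prr=prr_v,
        ror=ror_v,
        chi2=chi2_v,
        ic=ic_v,
        ic025=ic025_v,
        signal=evaluate_signal(table.a, prr_v, ror_v, chi2_v, ic025_v),
        ic_method=ic_method,
    )


def solve_comparator_count(
    a: int, drug_total: int, corpus_total: int, target_prr: float
) -> int:
    """Reconstruct the comparator event count c of a 2x2 table from printed
    marginals: the integer c >= 1 minimizing |PRR(a,b,c,d) - target_prr|
    with b = drug_total - a and d closing the table to corpus_total."""
    b = drug_total - a
    rest = corpus_total - drug_total
    # PRR = (a/drug_total) / (c/rest)  =>  c ~= a*rest/(drug_total*target)
    c0 = a * rest / (drug_total * target_prr)
    best_c, best_err = None, math.inf
    for c in range(max(1, int(c0) - 2), int(c0) + 3):
        value = (a / drug_total) / (c / rest)
        err = abs(value - target_prr)
        if err < best_err:
            best_c, best_err = c, err
    return best_c


def reconstruct_table(
    a: int, drug_total: int, corpus_total: int, target_prr: float
) -> ContingencyTable:
    """2x2 table recovered from printed marginals (see
    :func:`solve_comparator_count`)."""
    c = solve_comparator_count(a, drug_total, corpus_total, target_prr)
    b = drug_total - a
    d = corpus_total - drug_total - c
    return ContingencyTable(a, b, c, d)
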
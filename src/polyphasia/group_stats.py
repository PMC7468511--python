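"""Between-group statistics for the polyphasia tables.

Implemented from first principles (not wrappers) so that small-sample
behaviour is testable against independent oracles:

* Fisher's exact test on r×2 tables by full enumeration of the conditional
  (multivariate hypergeometric) distribution given the margins;
* Pearson chi-square with optional Yates correction;
* Wilcoxon rank-sum, exact by enumeration for small untied samples,
  otherwise normal approximation with tie-corrected variance and
  continuity correction;
* Kruskal–Wallis H with tie correction.

All tests are two-sided and no multiple-testing correction is applied,
matching how the polyphasia comparisons are conventionally reported.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .mep_phase import SubjectSummary

logger = logging.getLogger(__name__)

FISHER_ENUMERATION_MAX_N = 200


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least a 2×2 table")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def build_contingency(summaries: list[SubjectSummary],
                      row_factor: str = "group",
                      col_factor: str = "subject_polyphasic",
                      row_order: tuple[str, ...] | None = None,
                      col_order: tuple[str, ...] | None = None
                      ) -> ContingencyTable:
    """Tabulate subject summaries into a contingency table.

    The default factors reproduce the "participants displaying polyphasia by
    group" table: rows = group, columns = polyphasic yes/no.
    """
    if not summaries:
        raise ValueError("no subject summaries to tabulate")

    def value(s: SubjectSummary, factor: str) -> str:
        v = getattr(s, factor)
        if isinstance(v, bool):
            return "polyphasic" if v else "non_polyphasic"
        return str(v)

    rows = row_order or tuple(dict.fromkeys(value(s, row_factor) for s in summaries))
    cols = col_order or tuple(dict.fromkeys(value(s, col_factor) for s in summaries))
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for s in summaries:
        r, c = value(s, row_factor), value(s, col_factor)
        if r not in rows or c not in cols:
            raise ValueError(f"summary value ({r!r}, {c!r}) outside the configured order")
        counts[rows.index(r), cols.index(c)] += 1
    return ContingencyTable(row_labels=rows, col_labels=cols, counts=counts)


# ---------------------------------------------------------------------------
# Fisher's exact test, r×2, by full enumeration
# ---------------------------------------------------------------------------

def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Exact conditional test on an r×2 table.

    Enumerates every table with the observed margins; the two-sided p-value
    sums the (multivariate hypergeometric) probabilities of all tables no
    more probable than the observed one. For 2×2 this is the classical
    two-sided Fisher test.
    """
    counts = table.counts
    if counts.shape[1] != 2:
        raise ValueError("fisher_exact implemented for r×2 tables")
    n = int(counts.sum())
    if n > FISHER_ENUMERATION_MAX_N:
        raise ValueError(
            f"N={n} exceeds the enumeration bound {FISHER_ENUMERATION_MAX_N}; "
            "use chi_square instead")
    row_sums = counts.sum(axis=1)
    c1 = int(counts[:, 0].sum())

    def log_prob(a: tuple[int, ...]) -> float:
        # P(table | margins) = Π C(r_i, a_i) / C(N, c1)
        return sum(_log_binom(int(r), ai) for r, ai in zip(row_sums, a)) \
            - _log_binom(n, c1)

    observed = tuple(int(x) for x in counts[:, 0])
    lp_obs = log_prob(observed)

    ranges = [range(0, int(r) + 1) for r in row_sums]
    p = 0.0
    # tolerance guards against float round-off deciding "more probable"
    for a in itertools.product(*ranges):
        if sum(a) != c1:
            continue
        lp = log_prob(a)
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return TestResult(p_value=min(p, 1.0))


def chi_square(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r×c table."""
    counts = table.counts.astype(float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    n = counts.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column: expected counts undefined")
    expected = row @ col / n
    diff = np.abs(counts - expected)
    if yates:
        if counts.shape != (2, 2):
            raise ValueError("Yates correction applies to 2×2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    return TestResult(p_value=max(p, np.nextafter(0, 1)), statistic=statistic, df=df)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon (Mann–Whitney) rank-sum test.

    Exact by full enumeration of rank assignments when both samples have at
    most ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("all values identical in both samples; p = 1")
        return TestResult(p_value=1.0, statistic=0.0)

    nx, ny = x.size, y.size
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())  # rank sum of x

    has_ties = np.unique(pooled).size < pooled.size
    if nx <= exact_max_n and ny <= exact_max_n and not has_ties:
        # exact null: every subset of size nx of ranks 1..N is equally likely
        all_ranks = np.arange(1, nx + ny + 1)
        mean_w = nx * (nx + ny + 1) / 2.0
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(all_ranks, nx):
            total += 1
            if abs(sum(combo) - mean_w) >= dev - 1e-9:
                count += 1
        return TestResult(p_value=count / total, statistic=w)

    mean_w = nx * (nx + ny + 1) / 2.0
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return TestResult(p_value=1.0, statistic=w)
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = 2.0 * float(sps.norm.sf(z))
    return TestResult(p_value=min(max(p, np.nextafter(0, 1)), 1.0), statistic=w)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal–Wallis H test with tie correction; chi-square tail p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need ≥ 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts ** 3 - tie_counts)) / (n ** 3 - n)
    if correction <= 0:  # every value identical
        return TestResult(p_value=1.0, statistic=0.0, df=len(groups) - 1)
    h /= correction
    h = max(h, 0.0)
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(p_value=min(max(p, np.nextafter(0, 1)), 1.0),
                      statistic=h, df=df)


def percentage(count: int, total: int, decimals: int = 0) -> float:
    """``100·count/total`` rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def group_comparison_report(summaries: list[SubjectSummary]) -> list[dict]:
    """All between-group comparisons of the polyphasia pipeline outputs.

    Mirrors the study layout: the polyphasia-by-group table (Fisher +
    chi-square), then for mean crossings and polyphasia ratio the omnibus
    Kruskal–Wallis and all pairwise Wilcoxon rank-sum tests.
    """
    rows: list[dict] = []
    order = tuple(g for g in ("patient", "relative", "control")
                  if any(s.group == g for s in summaries))
    table = build_contingency(summaries, row_order=order,
                              col_order=("polyphasic", "non_polyphasic"))
    fisher = fisher_exact(table)
    rows.append({"comparison": "polyphasia_by_group_fisher", "statistic": None,
                 "df": None, "p_value": fisher.p_value})
    try:
        chi = chi_square(table)
        rows.append({"comparison": "polyphasia_by_group_chi_square",
                     "statistic": chi.statistic, "df": chi.df,
                     "p_value": chi.p_value})
    except ValueError:  # zero margin: expected counts undefined
        rows.append({"comparison": "polyphasia_by_group_chi_square",
                     "statistic": None, "df": None, "p_value": None})
    for g, line in zip(order, table.counts):
        rows.append({"comparison": f"polyphasia_pct_{g}",
                     "statistic": percentage(int(line[0]), int(line.sum())),
                     "df": None, "p_value": None})

    for metric in ("mean_crossings", "polyphasia_ratio"):
        by_group = {g: [getattr(s, metric) for s in summaries if s.group == g]
                    for g in order}
        kw = kruskal_wallis([by_group[g] for g in order])
        rows.append({"comparison": f"{metric}_kruskal_wallis",
                     "statistic": kw.statistic, "df": kw.df, "p_value": kw.p_value})
        for ga, gb in itertools.combinations(order, 2):
            res = wilcoxon_rank_sum(by_group[ga], by_group[gb])
            rows.append({"comparison": f"{metric}_wilcoxon_{ga}_vs_{gb}",
                         "statistic": res.statistic, "df": None,
                         "p_value": res.p_value})
    return rows
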
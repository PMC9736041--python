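"""Paired nonparametric tests with exact small-sample distributions.

Both tests are computed from their exact permutation null distributions
where feasible, because plan-comparison cohorts are small (n = 15) and the
chi-square / normal approximations are poor there:

* Wilcoxon signed-rank: the null distribution of W+ is built by dynamic
  programming over the (doubled, so tied average ranks stay integral) rank
  values — exact for any tie pattern.  Above ``exact_limit`` pairs a normal
  approximation with tie and continuity corrections is used.
* Friedman (k = 3 matched groups): under the null each block's within-block
  ranking is an independent uniform draw from the 3! orderings; the joint
  distribution of the column rank sums is built by convolution over blocks,
  which is exact for any n when blocks have no internal ties.  Blocks with
  internal ties fall back to the tie-corrected chi-square approximation.

Zero differences in the signed-rank test are dropped before ranking
(classic Wilcoxon); all-zero input is reported as degenerate with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = ["WilcoxonResult", "FriedmanResult", "wilcoxon_signed_rank", "friedman_test"]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    pvalue: float  # two-sided
    n_used: int  # pairs after dropping zero differences
    method: str  # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float  # Friedman chi-square Q
    pvalue: float
    n: int  # blocks (patients)
    k: int  # groups (modalities)
    mean_ranks: tuple[float, ...]
    method: str  # "exact" | "chisq"


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact counts of the doubled statistic 2·W+ over all sign assignments."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x, y=None, *, exact_limit: int = 25, method: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Exact for ``n <= exact_limit`` non-zero differences (including tied
    ranks); otherwise a normal approximation with tie and continuity
    corrections.  ``method`` may force ``"exact"`` or ``"normal"``.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, method="degenerate")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    use_exact = method == "exact" or (method == "auto" and n <= exact_limit)
    if use_exact:
        r2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(r2)
        total = counts.sum()  # 2^n, exact in float for n <= ~50
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_plus, pvalue=p, n_used=n, method="exact")

    mu = n * (n + 1) / 4.0
    tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_sizes**3 - tie_sizes).sum() / 48.0
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, pvalue=p, n_used=n, method="normal")


def _friedman_exact_pvalue(rank_matrix: np.ndarray) -> float:
    """P(S >= s_obs) where S = Σ_j R_j², by convolution over blocks (k = 3)."""
    n = rank_matrix.shape[0]
    s_obs = float((rank_matrix.sum(axis=0) ** 2).sum())
    size = 3 * n + 1
    # joint counts of (R1, R2); R3 = 6n − R1 − R2
    joint = np.zeros((size, size))
    joint[0, 0] = 1.0
    perms = [(1, 2, 3), (1, 3, 2), (2, 1, 3), (2, 3, 1), (3, 1, 2), (3, 2, 1)]
    for _ in range(n):
        new = np.zeros_like(joint)
        for a, b, _c in perms:
            new[a:, b:] += joint[: size - a, : size - b]
        joint = new
    r1, r2 = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    r3 = 6 * n - r1 - r2
    s = r1**2 + r2**2 + r3**2
    total = joint.sum()  # 6^n
    return float(joint[s >= s_obs - 1e-9].sum() / total)


def friedman_test(values: np.ndarray, *, method: str = "auto") -> FriedmanResult:
    """Friedman test for n blocks × 3 matched groups.

    ``values`` is an (n, 3) array (rows = patients, columns = modalities).
    The exact permutation p-value is used whenever no block has internal
    ties; blocks with ties use the tie-corrected chi-square approximation.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of paired values")
    n, k = values.shape
    if n < 2:
        raise ValueError("need at least 2 complete blocks")

    ranks = np.apply_along_axis(rankdata, 1, values)
    mean_ranks = tuple(float(m) for m in ranks.mean(axis=0))
    col_sums = ranks.sum(axis=0)
    has_ties = any(np.unique(row).size < k for row in values)

    # tie-corrected Friedman chi-square
    s = float((col_sums**2).sum())
    q = 12.0 * s / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    if has_ties:
        tie_term = sum(
            (np.unique(row, return_counts=True)[1] ** 3 - np.unique(row, return_counts=True)[1]).sum()
            for row in values
        )
        correction = 1.0 - tie_term / (n * k * (k**2 - 1))
        q = q / correction if correction > 0 else 0.0

    if method == "chisq" or (method == "auto" and has_ties):
        p = float(chi2.sf(q, df=k - 1)) if q > 0 else 1.0
        return FriedmanResult(q, p, n, k, mean_ranks, method="chisq")
    p = _friedman_exact_pvalue(ranks)
    return FriedmanResult(q, p, n, k, mean_ranks, method="exact")
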
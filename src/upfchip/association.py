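"""Occupancy-expression correlation, ratio-group classification and
gene-set overlap statistics.

The overlap between two gene sets is evaluated twice: by random sampling
(each repetition draws same-sized sets from the two universes and records
the intersection size) and by the one-sided hypergeometric (Fisher's exact)
upper tail.  The permutation P uses the add-one estimator ``(r+1)/(reps+1)``
so that zero is never reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "OverlapResult",
    "mean_log_fpkm",
    "spearman_correlation",
    "classify_ratio_groups",
    "overlap_permutation_test",
    "hypergeometric_overlap_test",
]


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm_reps: tuple[float, ...]
    mean_fpkm: float
    log_fpkm: float  # natural log(mean_fpkm + 1)


@dataclass(frozen=True)
class OverlapResult:
    k: int  # observed overlap
    K: int  # |set A|
    n: int  # |set B|
    N_A: int  # universe A size
    N_B: int  # universe B size
    p_permutation: float
    p_hypergeometric: float
    reps: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def mean_log_fpkm(fpkm_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate FPKM per gene and transform via natural log(FPKM + 1).

    *fpkm_table* has a ``gene_id`` column and one column per replicate.
    """
    reps = [c for c in fpkm_table.columns if c != "gene_id"]
    if not reps:
        raise ValueError("no replicate columns")
    vals = fpkm_table[reps].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative FPKM")
    mean = vals.mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": fpkm_table["gene_id"],
            "mean_fpkm": mean,
            "log_fpkm": np.log(mean + 1.0),
        }
    )


def spearman_correlation(
    x: pd.Series,
    y: pd.Series,
    top_expressed_fraction: float | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation of two per-gene series (paired by gene id).

    With ``top_expressed_fraction=f``, genes whose *y* value lies below the
    ``1 - f`` quantile of *y* are removed before ranking, mirroring a
    "top f expressed genes" filter on the expression variable only.
    Returns (rho, two-sided P from the t approximation).
    """
    paired = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    if top_expressed_fraction is not None:
        if not 0 < top_expressed_fraction <= 1:
            raise ValueError("top_expressed_fraction must be in (0, 1]")
        cut = paired["y"].quantile(1.0 - top_expressed_fraction)
        paired = paired[paired["y"] >= cut]
    if len(paired) < 3:
        raise ValueError("fewer than 3 paired genes after filtering")
    if paired["x"].nunique() == 1 or paired["y"].nunique() == 1:
        raise ValueError("constant vector after filtering")
    res = stats.spearmanr(paired["x"], paired["y"])
    return float(res.statistic), float(res.pvalue)


def classify_ratio_groups(
    upf1_signal: pd.Series,
    polii_signal: pd.Series,
    theta_low: float = -1.0,
    theta_high: float = 1.0,
    min_signal: float = 0.0,
) -> pd.Series:
    """Label genes by log2(Upf1 / Pol II) signal ratio.

    Genes with both signals below *min_signal* are ``unclassified``; genes
    with a non-positive signal are likewise excluded.  Otherwise
    ``d = log2(upf1) - log2(polII)`` maps to ``high_ratio`` (d >= theta_high),
    ``low_ratio`` (d <= theta_low) or ``similar``.
    """
    if theta_low >= theta_high:
        raise ValueError("theta_low must be below theta_high")
    df = pd.concat(
        [upf1_signal.rename("u"), polii_signal.rename("p")], axis=1, join="inner"
    )
    labels = pd.Series("unclassified", index=df.index, name="group_label")
    weak = (df["u"] < min_signal) & (df["p"] < min_signal)
    nonpos = (df["u"] <= 0) | (df["p"] <= 0)
    ok = ~(weak | nonpos)
    d = np.log2(df.loc[ok, "u"]) - np.log2(df.loc[ok, "p"])
    labels.loc[ok] = np.where(
        d >= theta_high, "high_ratio", np.where(d <= theta_low, "low_ratio", "similar")
    )
    return labels


def hypergeometric_overlap_test(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function evaluated in log space for numerical stability
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def overlap_permutation_test(
    set_a: set[str] | list[str],
    universe_a: list[str],
    set_b: set[str] | list[str],
    universe_b: list[str],
    reps: int = 1000,
    seed: int = 0,
    hypergeom_universe: str = "A",
) -> OverlapResult:
    """Random-sampling overlap test between two gene sets.

    Each repetition draws ``|set_a|`` genes uniformly without replacement
    from *universe_a* and ``|set_b|`` from *universe_b* and records the
    intersection size of the draws (matched by gene id); the permutation P
    is ``(r + 1) / (reps + 1)`` with r the number of repetitions whose
    overlap is at least the observed one.  The hypergeometric P is computed
    on the same counts with the universe chosen by *hypergeom_universe*.
    """
    set_a, set_b = set(set_a), set(set_b)
    ua, ub = list(dict.fromkeys(universe_a)), list(dict.fromkeys(universe_b))
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not set_a <= set(ua):
        raise ValueError("set A not contained in universe A")
    if not set_b <= set(ub):
        raise ValueError("set B not contained in universe B")
    k_obs = len(set_a & set_b)
    K, n = len(set_a), len(set_b)

    union = list(dict.fromkeys(ua + ub))
    idx = {g: i for i, g in enumerate(union)}
    ia = np.array([idx[g] for g in ua])
    ib = np.array([idx[g] for g in ub])
    rng = np.random.default_rng(seed)
    r = 0
    member_a = np.zeros(len(union), dtype=bool)
    for _ in range(reps):
        draw_a = ia[rng.permutation(len(ia))[:K]]
        draw_b = ib[rng.permutation(len(ib))[:n]]
        member_a[draw_a] = True
        overlap = int(member_a[draw_b].sum())
        member_a[draw_a] = False
        if overlap >= k_obs:
            r += 1
    p_perm = (r + 1) / (reps + 1)
    N_hyp = len(ua) if hypergeom_universe == "A" else len(ub)
    p_hyp = hypergeometric_overlap_test(k_obs, K, n, N_hyp)
    return OverlapResult(
        k=k_obs,
        K=K,
        n=n,
        N_A=len(ua),
        N_B=len(ub),
        p_permutation=p_perm,
        p_hypergeometric=p_hyp,
        reps=reps,
        seed=seed,
    )
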
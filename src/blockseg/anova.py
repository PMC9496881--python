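"""One-way and two-way fixed-effects ANOVA, and the block fitness built on it.

Both models are computed from first principles on balanced layouts.  The
two-way model decomposes the total sum of squares of observations
``y[i, j, k]`` (factor A level *i*, factor B level *j*, replicate *k*) into

    SST = SSA + SSB + SSAB + SSE

with mean squares ``MS = SS / df`` and F ratios against the residual mean
square.  The block fitness used by the swarm search is

    fitness = MSA / MSE + MSB / MSE

computed on a layout where factor A is the image source (candidate block
from the diseased image vs the co-located block of the disease-free
reference) and factor B is the column index within the block, with the rows
of each column as replicates.  A large image-factor mean square then means
the candidate block differs systematically from healthy tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "OneWayAnovaTable",
    "TwoWayAnovaTable",
    "oneway_anova",
    "twoway_anova",
    "anova_fitness",
    "f_pvalue",
]

#: Guard added to MSE in the fitness ratio so constant blocks stay finite.
FITNESS_EPS = 1e-12


def f_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the Fisher-Snedecor distribution.

    Computed through the regularized incomplete beta function:
    ``P(X >= F) = I_x(df2/2, df1/2)`` with ``x = df2 / (df2 + df1 * F)``.

    Parameters
    ----------
    F : float
        Observed F statistic, ``>= 0`` (``inf`` allowed, giving ``p = 0``).
    df1, df2 : int
        Numerator and denominator degrees of freedom, both ``>= 1``.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if not F >= 0:
        raise ValueError(f"F statistic must be non-negative, got {F}")
    if np.isinf(F):
        return 0.0
    x = df2 / (df2 + df1 * F)
    return float(special.betainc(df2 / 2.0, df1 / 2.0, x))


def _f(ss_num: float, df_num: int, mse: float, df2: int) -> tuple[float, float]:
    """F statistic and p-value of ``(ss_num/df_num) / mse`` with guards.

    A zero numerator with zero MSE is reported as ``F = 0, p = 1`` (no
    evidence either way); a positive numerator over zero MSE is ``F = inf``.
    """
    ms = ss_num / df_num
    if mse == 0.0:
        if ms == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms / mse
    return F, f_pvalue(F, df_num, df2)


@dataclass(frozen=True)
class OneWayAnovaTable:
    """All quantities of a one-way fixed-effects ANOVA."""

    k: int
    N: int
    n_i: tuple[int, ...]
    group_means: tuple[float, ...]
    grand_mean: float
    SSF: float
    SSE: float
    SST: float
    df_factor: int
    df_residual: int
    MS_factor: float
    MS_residual: float
    F: float
    p: float

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["n_i"] = list(self.n_i)
        d["group_means"] = list(self.group_means)
        return d

    def __str__(self) -> str:
        rows = [
            ("Factor", self.SSF, self.df_factor, self.MS_factor, self.F, self.p),
            ("Residues", self.SSE, self.df_residual, self.MS_residual, "", ""),
            ("Total", self.SST, self.N - 1, "", "", ""),
        ]
        return _format_table(rows)


@dataclass(frozen=True)
class TwoWayAnovaTable:
    """All quantities of a balanced two-way fixed-effects ANOVA."""

    a: int
    b: int
    n: int
    N: int
    cell_means: np.ndarray = field(repr=False)
    marginal_means_A: tuple[float, ...]
    marginal_means_B: tuple[float, ...]
    grand_mean: float
    marginal_counts_A: tuple[int, ...]
    marginal_counts_B: tuple[int, ...]
    SSA: float
    SSB: float
    SSAB: float
    SSE: float
    SST: float
    df_A: int
    df_B: int
    df_AB: int
    df_residual: int
    MSA: float
    MSB: float
    MSAB: float
    MSE: float
    F_A: float
    F_B: float
    F_AB: float
    p_A: float
    p_B: float
    p_AB: float

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["cell_means"] = self.cell_means.tolist()
        for key in ("marginal_means_A", "marginal_means_B",
                    "marginal_counts_A", "marginal_counts_B"):
            d[key] = list(d[key])
        return d

    def __str__(self) -> str:
        rows = [
            ("Factor A", self.SSA, self.df_A, self.MSA, self.F_A, self.p_A),
            ("Factor B", self.SSB, self.df_B, self.MSB, self.F_B, self.p_B),
            ("Interaction AB", self.SSAB, self.df_AB, self.MSAB, self.F_AB, self.p_AB),
            ("Residues", self.SSE, self.df_residual, self.MSE, "", ""),
            ("Total", self.SST, self.N - 1, "", "", ""),
        ]
        return _format_table(rows)


def _format_table(rows) -> str:
    header = ("Source", "SS", "df", "MS", "F", "p")
    fmt = lambda v: f"{v:.6g}" if isinstance(v, float) else str(v)
    table = [header] + [tuple(fmt(v) for v in r) for r in rows]
    widths = [max(len(r[i]) for r in table) for i in range(6)]
    return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in table)


def oneway_anova(groups) -> OneWayAnovaTable:
    """One-way fixed-effects ANOVA of ``k`` groups of observations.

    Parameters
    ----------
    groups : sequence of sequences of float
        At least two groups, each non-empty, ``N >= k + 1`` observations in
        total.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError(f"one-way ANOVA needs at least 2 groups, got {k}")
    if any(a.size == 0 for a in arrays):
        raise ValueError("one-way ANOVA groups must all be non-empty")
    n_i = tuple(int(a.size) for a in arrays)
    N = sum(n_i)
    if N < k + 1:
        raise ValueError(f"one-way ANOVA needs N >= k+1 observations, got N={N}, k={k}")

    pooled = np.concatenate(arrays)
    grand = float(pooled.mean())
    means = tuple(float(a.mean()) for a in arrays)
    SSF = float(sum(n * (m - grand) ** 2 for n, m in zip(n_i, means)))
    SSE = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    SST = float(((pooled - grand) ** 2).sum())

    df_f, df_r = k - 1, N - k
    MSF, MSR = SSF / df_f, SSE / df_r
    F, p = _f(SSF, df_f, MSR, df_r)
    return OneWayAnovaTable(
        k=k, N=N, n_i=n_i, group_means=means, grand_mean=grand,
        SSF=SSF, SSE=SSE, SST=SST,
        df_factor=df_f, df_residual=df_r, MS_factor=MSF, MS_residual=MSR,
        F=F, p=p,
    )


def _as_balanced_array(cells) -> np.ndarray:
    """Coerce an a x b grid of n-replicate sequences to a float array."""
    try:
        Y = np.asarray(cells, dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(
            "two-way ANOVA requires a balanced design: every cell must hold "
            "the same number of replicates"
        ) from exc
    if Y.ndim != 3:
        raise ValueError(
            f"two-way ANOVA input must be an a x b grid of replicate "
            f"sequences (3-d), got {Y.ndim} dimension(s)"
        )
    return Y


def _balanced_ss(Y: np.ndarray):
    """Sums of squares of a balanced (a, b, n) layout.

    Returns ``(SSA, SSB, SSAB, SSE, SST)``.  SSAB comes from the cell sum of
    squares minus the main effects (clipped at zero against round-off); SSE
    is the full per-cell deviation sum.
    """
    a, b, n = Y.shape
    grand = Y.mean()
    cell = Y.mean(axis=2)                 # (a, b)
    mA = cell.mean(axis=1)                # (a,)
    mB = cell.mean(axis=0)                # (b,)
    SSA = b * n * float(((mA - grand) ** 2).sum())
    SSB = a * n * float(((mB - grand) ** 2).sum())
    SScells = n * float(((cell - grand) ** 2).sum())
    SSAB = SScells - SSA - SSB
    if -1e-12 < SSAB < 0.0:
        SSAB = 0.0
    SSE = float(((Y - cell[:, :, None]) ** 2).sum())
    SST = float(((Y - grand) ** 2).sum())
    return SSA, SSB, SSAB, SSE, SST, cell, mA, mB, float(grand)


def twoway_anova(cells) -> TwoWayAnovaTable:
    """Balanced two-way fixed-effects ANOVA.

    Parameters
    ----------
    cells : array-like, shape (a, b, n)
        Crossed design with ``a >= 2`` levels of factor A, ``b >= 2`` levels
        of factor B and exactly ``n >= 2`` replicates per cell.  Unbalanced
        grids are rejected rather than approximated.
    """
    Y = _as_balanced_array(cells)
    a, b, n = Y.shape
    if a < 2 or b < 2:
        raise ValueError(f"two-way ANOVA needs a >= 2 and b >= 2 levels, got a={a}, b={b}")
    if n < 2:
        raise ValueError(
            "two-way ANOVA needs n >= 2 replicates per cell "
            "(with n = 1 the interaction is inseparable from error)"
        )
    N = a * b * n
    SSA, SSB, SSAB, SSE, SST, cell, mA, mB, grand = _balanced_ss(Y)

    df_A, df_B = a - 1, b - 1
    df_AB = df_A * df_B
    df_E = N - a * b
    MSA, MSB, MSAB, MSE = SSA / df_A, SSB / df_B, SSAB / df_AB, SSE / df_E
    F_A, p_A = _f(SSA, df_A, MSE, df_E)
    F_B, p_B = _f(SSB, df_B, MSE, df_E)
    F_AB, p_AB = _f(SSAB, df_AB, MSE, df_E)

    return TwoWayAnovaTable(
        a=a, b=b, n=n, N=N,
        cell_means=cell,
        marginal_means_A=tuple(float(m) for m in mA),
        marginal_means_B=tuple(float(m) for m in mB),
        grand_mean=grand,
        marginal_counts_A=tuple([b * n] * a),
        marginal_counts_B=tuple([a * n] * b),
        SSA=SSA, SSB=SSB, SSAB=SSAB, SSE=SSE, SST=SST,
        df_A=df_A, df_B=df_B, df_AB=df_AB, df_residual=df_E,
        MSA=MSA, MSB=MSB, MSAB=MSAB, MSE=MSE,
        F_A=F_A, F_B=F_B, F_AB=F_AB, p_A=p_A, p_B=p_B, p_AB=p_AB,
    )


def anova_fitness(candidate, reference, *, factor_layout: str = "columns-as-B",
                  eps: float = FITNESS_EPS) -> float:
    """Block fitness ``MSA/MSE + MSB/MSE`` of a candidate/reference pair.

    Factor A is the image source (2 levels).  With the default
    ``columns-as-B`` layout, factor B is the column index within the block
    and the rows of each column are the replicates; ``rows-as-B`` swaps the
    roles for sensitivity checks.  Returns 0 for a totally constant pair
    (no variance, hence no lesion evidence); ``eps`` keeps the ratio finite
    when only the residual vanishes.
    """
    C = np.asarray(candidate, dtype=float)
    R = np.asarray(reference, dtype=float)
    if C.shape != R.shape:
        raise ValueError(f"candidate and reference differ in shape: {C.shape} vs {R.shape}")
    if C.ndim != 2 or C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError(f"blocks must be 2-d with height, width >= 2, got shape {C.shape}")
    if factor_layout == "columns-as-B":
        Y = np.stack([C.T, R.T])          # (2, w, h): image, column, row-replicate
    elif factor_layout == "rows-as-B":
        Y = np.stack([C, R])              # (2, h, w): image, row, col-replicate
    else:
        raise ValueError(f"unknown factor_layout {factor_layout!r}")

    SSA, SSB, _, SSE, SST, *_ = _balanced_ss(Y)
    if SST == 0.0:
        return 0.0
    a, b, n = Y.shape
    MSA = SSA / (a - 1)
    MSB = SSB / (b - 1)
    MSE = SSE / (a * b * n - a * b)
    return float((MSA + MSB) / (MSE + eps))
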
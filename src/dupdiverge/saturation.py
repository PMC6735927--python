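"""Origin-constrained saturation curves of divergence versus Ks.

Divergence between duplicates (sequence, expression or interaction) is
modeled as a Michaelis-Menten-type saturation curve of Ks,

    y(x) = a * x / (b + x),

which passes through the origin — duplicates are assumed functionally
redundant at the moment of duplication, so divergence starts at zero — rises
monotonically, and saturates at the asymptote ``a`` with half-saturation
constant ``b`` (the Ks at which divergence reaches a/2).  The curve absorbs
the synonymous-site saturation that makes linear models misbehave for old
duplicates.

Partitions (tandem vs block, with vs without PPI) are compared by the
classical extra-sum-of-squares F-test: fit one curve per partition and one
curve to the pooled data; under the null that one curve suffices,

    F = ((SSE_comb - SSE_sep) / df_num) / (SSE_sep / df_den)

with df_num = 2*(k-1) and df_den = n_total - 2*k for k partitions of two
parameters each.  Confidence bands come from a case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "michaelis_menten",
    "SaturationFit",
    "fit_saturation",
    "ModelComparison",
    "compare_partitions",
    "ConfidenceBand",
    "confidence_band",
    "FigureSuiteResult",
    "run_figure_suite",
]

_B_MIN, _B_MAX = 1e-6, 100.0


def michaelis_menten(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Saturation curve a*x/(b+x); vectorized over x."""
    x = np.asarray(x, dtype=float)
    return a * x / (b + x)


@dataclass(frozen=True)
class SaturationFit:
    """Least-squares fit of y = a*x/(b+x).

    ``b_identified`` is False in the degenerate all-zero-response case where
    any b fits equally well (a = 0 is then reported with sse = 0).
    """

    a: float
    b: float
    sse: float
    n: int
    converged: bool = True
    b_identified: bool = True

    @property
    def dof(self) -> int:
        return self.n - 2

    def predict(self, x: np.ndarray) -> np.ndarray:
        return michaelis_menten(x, self.a, self.b)


def _sse(x: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    r = y - michaelis_menten(x, a, b)
    return float(r @ r)


def fit_saturation(
    x: np.ndarray,
    y: np.ndarray,
    a_max: float = 10.0,
    extra_starts: tuple[tuple[float, float], ...] = (),
) -> SaturationFit:
    """Fit (a, b) by bounded nonlinear least squares with multiple starts.

    Starts: a0 in {max(y), mean(y)}, b0 in {median(x), 1.0}, plus any
    ``extra_starts``; the best sum of squared errors wins, ties broken by the
    smaller b.  Bounds: a in [0, a_max] (pass 1 for measures bounded in
    [0, 1], the default 10 for sequence divergence), b in (1e-6, 100].

    Requires at least 3 points with x > 0.  If every y is 0 the asymptote is
    0 and b is unidentifiable; a = 0 is returned with ``b_identified=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("fit_saturation requires at least 3 points")
    if (x <= 0).any():
        raise ValueError("fit_saturation requires x > 0")
    if np.allclose(y, 0.0):
        return SaturationFit(a=0.0, b=1.0, sse=0.0, n=x.size, b_identified=False)

    starts = [
        (a0, b0)
        for a0 in (float(np.max(y)), float(np.mean(y)))
        for b0 in (float(np.median(x)), 1.0)
    ]
    starts += [tuple(map(float, s)) for s in extra_starts]

    def residuals(theta):
        return y - michaelis_menten(x, theta[0], theta[1])

    candidates: list[tuple[float, float, float]] = []  # (sse, b, a)
    any_success = False
    for a0, b0 in starts:
        a0 = float(np.clip(a0 if a0 > 0 else 0.5 * a_max, 0.0, a_max))
        b0 = float(np.clip(b0, _B_MIN, _B_MAX))
        try:
            res = optimize.least_squares(
                residuals,
                x0=[a0, b0],
                bounds=([0.0, _B_MIN], [a_max, _B_MAX]),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        any_success = any_success or bool(res.success)
        candidates.append((_sse(x, y, *res.x), float(res.x[1]), float(res.x[0])))
    if not candidates:
        raise RuntimeError("fit_saturation: no optimizer start converged")
    best_sse = min(c[0] for c in candidates)
    # Ties (within relative 1e-9) broken by the smaller half-saturation b.
    tol = 1e-9 * max(best_sse, 1e-300)
    sse, b, a = min(c for c in candidates if c[0] <= best_sse + tol)
    return SaturationFit(a=a, b=b, sse=sse, n=x.size, converged=any_success)


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares F-test of per-partition vs pooled curves."""

    labels: tuple[str, ...]
    fits: dict[str, SaturationFit] = field(repr=False)
    combined: SaturationFit = field(repr=False)
    f_stat: float = float("nan")
    df_num: int = 0
    df_den: int = 0
    p_value: float = float("nan")

    @property
    def sse_separate(self) -> float:
        return sum(f.sse for f in self.fits.values())


def compare_partitions(
    partitions: dict[str, tuple[np.ndarray, np.ndarray]],
    a_max: float = 10.0,
) -> ModelComparison:
    """Fit each partition and the pooled data; F-test the separate model.

    The pooled fit's parameters are injected as an additional start for every
    per-partition fit, which guarantees the nesting inequality
    SSE_combined >= sum(SSE_separate) structurally (each separate fit can do
    at least as well as the pooled parameters on its own points).
    """
    if len(partitions) < 2:
        raise ValueError("compare_partitions needs at least two partitions")
    xs = np.concatenate([np.asarray(x, float) for x, _ in partitions.values()])
    ys = np.concatenate([np.asarray(y, float) for _, y in partitions.values()])
    combined = fit_saturation(xs, ys, a_max=a_max)

    fits = {
        name: fit_saturation(x, y, a_max=a_max, extra_starts=((combined.a, combined.b),))
        for name, (x, y) in partitions.items()
    }
    k = len(partitions)
    n_total = int(xs.size)
    df_num = 2 * (k - 1)
    df_den = n_total - 2 * k
    if df_den <= 0:
        raise ValueError("compare_partitions: nonpositive denominator dof")
    sse_sep = sum(f.sse for f in fits.values())
    assert combined.sse >= sse_sep - 1e-9 * max(1.0, combined.sse), (
        "nesting violated: combined SSE below sum of separate SSEs"
    )
    if sse_sep <= 0:
        f_stat = float("inf") if combined.sse > sse_sep else 0.0
        p_value = 0.0 if f_stat > 0 else 1.0
    else:
        f_stat = ((combined.sse - sse_sep) / df_num) / (sse_sep / df_den)
        f_stat = max(f_stat, 0.0)
        p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return ModelComparison(
        labels=tuple(partitions),
        fits=fits,
        combined=combined,
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
    )


@dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise bootstrap percentile band around a fitted curve."""

    x_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_success: int


def confidence_band(
    x: np.ndarray,
    y: np.ndarray,
    fit: SaturationFit,
    level: float = 0.95,
    n_boot: int = 500,
    seed: int = 0,
    x_grid: np.ndarray | None = None,
    a_max: float = 10.0,
) -> ConfidenceBand:
    """Case-resampling bootstrap band for the fitted curve.

    Points are resampled with replacement and refit from a single start at
    the point estimate (the least-squares surface of this two-parameter
    curve is well behaved near the optimum, and the resample stays close to
    the original sample); the band is the pointwise percentile envelope at
    ``level``, widened where necessary to contain the point-estimate curve
    itself.  Raises if fewer than 50 bootstrap refits succeed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_grid is None:
        x_grid = np.linspace(x.min(), x.max(), 50)
    rng = np.random.default_rng(seed)
    start = [max(fit.a, 1e-6), float(np.clip(fit.b, _B_MIN, _B_MAX))]
    curves = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        xb, yb = x[idx], y[idx]
        if np.unique(xb).size < 3:
            continue
        try:
            res = optimize.least_squares(
                lambda th: yb - michaelis_menten(xb, th[0], th[1]),
                x0=start,
                bounds=([0.0, _B_MIN], [a_max, _B_MAX]),
                method="trf",
            )
        except Exception:
            continue
        curves.append(michaelis_menten(x_grid, *res.x))
    if len(curves) < 50:
        raise RuntimeError(
            f"confidence_band: only {len(curves)} successful bootstrap refits (< 50)"
        )
    arr = np.vstack(curves)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(arr, alpha, axis=0)
    upper = np.quantile(arr, 1.0 - alpha, axis=0)
    yhat = fit.predict(x_grid)
    return ConfidenceBand(
        x_grid=x_grid,
        lower=np.minimum(lower, yhat),
        upper=np.maximum(upper, yhat),
        level=level,
        n_success=len(curves),
    )


_A_MAX_BY_MEASURE = {"ed": 1.0, "id": 1.0, "sd": 10.0}


@dataclass(frozen=True)
class FigureSuiteResult:
    """Tidy outputs of a fit-and-compare run over one or more measures."""

    fits: pd.DataFrame          # measure, scheme, partition, a, b, sse, n
    comparisons: pd.DataFrame   # measure, scheme, group, f, df1, df2, p
    skipped: pd.DataFrame       # partitions below the minimum size
    bands: dict[tuple, ConfidenceBand] = field(default_factory=dict, repr=False)


def run_figure_suite(
    records: pd.DataFrame,
    measures: tuple[str, ...] = ("sd", "ed"),
    scheme: str = "mode",
    min_partition_size: int = 10,
    with_bands: bool = False,
    n_boot: int = 200,
    seed: int = 0,
) -> FigureSuiteResult:
    """Fit saturation curves per partition and run the nested F-tests.

    ``records`` must carry ``ks``, one column per requested measure (NaN
    allowed; rows are dropped per measure), and the partitioning columns:
    ``mode`` for scheme "mode", boolean ``with_ppi`` for "ppi_status", both
    for "mode_x_ppi".  Under "mode_x_ppi" the with/without-PPI curves are
    compared *within* tandem and within block separately.

    Partitions smaller than ``min_partition_size`` are skipped and reported.
    """
    from . import catalog as _catalog

    fit_rows, cmp_rows, skip_rows = [], [], []
    bands: dict[tuple, ConfidenceBand] = {}
    for measure in measures:
        a_max = _A_MAX_BY_MEASURE.get(measure, 10.0)
        sub = records.dropna(subset=["ks", measure])
        if scheme in ("mode", "ppi_status"):
            comparison_groups = {"all": _catalog.partition(sub, by=scheme)}
        elif scheme == "mode_x_ppi":
            crossed = _catalog.partition(sub, by="mode_x_ppi")
            comparison_groups = {
                m: {k: v for k, v in crossed.items() if k.startswith(m + "|")}
                for m in ("tandem", "block")
            }
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

        for group, parts in comparison_groups.items():
            usable = {}
            for name, df in parts.items():
                if len(df) < min_partition_size:
                    skip_rows.append(
                        dict(measure=measure, scheme=scheme, group=group,
                             partition=name, n=len(df))
                    )
                    continue
                usable[name] = (df["ks"].to_numpy(), df[measure].to_numpy())
            if not usable:
                continue
            if len(usable) >= 2:
                cmp_res = compare_partitions(usable, a_max=a_max)
                fits = cmp_res.fits
                cmp_rows.append(
                    dict(measure=measure, scheme=scheme, group=group,
                         f=cmp_res.f_stat, df1=cmp_res.df_num,
                         df2=cmp_res.df_den, p=cmp_res.p_value)
                )
            else:
                fits = {
                    name: fit_saturation(x, y, a_max=a_max)
                    for name, (x, y) in usable.items()
                }
            for name, f in fits.items():
                fit_rows.append(
                    dict(measure=measure, scheme=scheme, group=group,
                         partition=name, a=f.a, b=f.b, sse=f.sse, n=f.n)
                )
                if with_bands:
                    x, y = usable[name]
                    bands[(measure, group, name)] = confidence_band(
                        x, y, f, n_boot=n_boot, seed=seed, a_max=a_max
                    )
    return FigureSuiteResult(
        fits=pd.DataFrame(fit_rows, columns=["measure", "scheme", "group", "partition", "a", "b", "sse", "n"]),
        comparisons=pd.DataFrame(cmp_rows, columns=["measure", "scheme", "group", "f", "df1", "df2", "p"]),
        skipped=pd.DataFrame(skip_rows, columns=["measure", "scheme", "group", "partition", "n"]),
        bands=bands,
    )
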
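"""Multi-line nonlinear LD-decay model and equality-of-curves tests.

The expected decay of r^2 with inter-marker distance d (kb) in line k is
modelled by the hyperbolic kernel

    E[r2] = 1 / (1 + 4 * beta_k * d),

with iid Gaussian residuals.  Because lines enter through dummy variables,
the model with one beta per line and the model with a single shared beta
are nested nonlinear least-squares problems, compared by

    chi2 = N * ln(SSR_reduced / SSR_full),

referred to a chi-square with df = difference in parameter counts.  The
pairwise procedure applies that test to each unordered pair of lines
(refitting on the two lines' records only) with a Bonferroni-corrected
threshold alpha / number_of_pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, ConvergenceError, StructuralError

__all__ = [
    "DecayDataset",
    "DecayFit",
    "CurveEqualityResult",
    "predict_r2",
    "fit_sved",
    "equality_test",
    "pairwise_equality",
    "bin_summary",
]


@dataclass
class DecayDataset:
    """(distance_kb, r2, line) records pooled over lines.

    ``check_bounds=False`` skips the [0, 1] range check on r2 — data
    generated from the decay model with additive Gaussian residuals can
    legitimately fall outside the unit interval, and truncating it would
    bias the fit.
    """

    frame: pd.DataFrame  # columns: distance_kb, r2, line
    check_bounds: bool = True

    def __post_init__(self) -> None:
        required = {"distance_kb", "r2", "line"}
        if required - set(self.frame.columns):
            raise StructuralError("decay dataset needs columns distance_kb, r2, line")
        f = self.frame
        if (f["distance_kb"] <= 0).any():
            raise ConfigurationError("decay dataset: distances must be > 0")
        if self.check_bounds and ((f["r2"] < 0) | (f["r2"] > 1)).any():
            raise ConfigurationError("decay dataset: r2 must lie in [0, 1]")
        for line, sub in f.groupby("line"):
            if sub["distance_kb"].nunique() < 2:
                raise ConfigurationError(
                    f"decay dataset: line {line} has < 2 distinct distances"
                )

    @classmethod
    def from_pairs(cls, pair_tables: list[pd.DataFrame]) -> "DecayDataset":
        frames = [
            t[["distance_kb", "r2"]].assign(line=t["population"]) for t in pair_tables
        ]
        return cls(pd.concat(frames, ignore_index=True))

    @property
    def lines(self) -> list[str]:
        return sorted(self.frame["line"].unique())

    @property
    def n_records(self) -> int:
        return len(self.frame)


def predict_r2(beta: float, d) -> np.ndarray | float:
    """Expected r^2 at distance d (kb) under decay coefficient beta (1/kb)."""
    return 1.0 / (1.0 + 4.0 * np.asarray(beta, dtype=float) * np.asarray(d, dtype=float))


@dataclass
class DecayFit:
    """Per-group decay coefficients with asymptotic standard errors.

    `groups` is the fitted partition; `line_to_group` maps each line to its
    group index.  p-values test beta = 0 by the asymptotic t-test with
    N - p residual degrees of freedom.
    """

    groups: list[tuple[str, ...]]
    beta: np.ndarray
    std_error: np.ndarray
    p_value: np.ndarray
    ssr: float
    n_records: int
    line_to_group: dict[str, int] = field(repr=False)

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def beta_for(self, line: str) -> float:
        return float(self.beta[self.line_to_group[line]])

    def predict(self, line: str, d) -> np.ndarray | float:
        return predict_r2(self.beta_for(line), d)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for line, gi in sorted(self.line_to_group.items()):
            rows.append(
                {
                    "line": line,
                    "beta_per_kb": float(self.beta[gi]),
                    "std_error": float(self.std_error[gi]),
                    "p_value": float(self.p_value[gi]),
                }
            )
        return pd.DataFrame(rows)


def _normalise_partition(
    data: DecayDataset, shared: list[tuple[str, ...]] | None
) -> list[tuple[str, ...]]:
    lines = data.lines
    if shared is None:
        return [(line,) for line in lines]
    flat = [ln for grp in shared for ln in grp]
    if sorted(flat) != sorted(lines):
        raise ConfigurationError(
            "partition must cover every line exactly once; "
            f"got {sorted(flat)} for lines {lines}"
        )
    if any(len(grp) == 0 for grp in shared):
        raise ConfigurationError("partition contains an empty beta-group")
    return [tuple(grp) for grp in shared]


def _fit_group(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """1-D least squares for one beta-group; returns (beta, ssr, sum J^2)."""

    def residuals(b: np.ndarray) -> np.ndarray:
        return y - 1.0 / (1.0 + 4.0 * b[0] * d)

    def jac(b: np.ndarray) -> np.ndarray:
        # d residual / d beta
        return (4.0 * d / (1.0 + 4.0 * b[0] * d) ** 2)[:, None]

    sol = optimize.least_squares(
        residuals,
        x0=[1e-3],
        jac=jac,
        bounds=(1e-8, 1.0),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise ConvergenceError(
            f"decay fit failed: {sol.message} (status {sol.status}, nfev {sol.nfev})"
        )
    beta = float(sol.x[0])
    ssr = float(np.sum(sol.fun**2))
    jtj = float(np.sum(jac(sol.x) ** 2))
    return beta, ssr, jtj


def fit_sved(
    data: DecayDataset, shared: list[tuple[str, ...]] | None = None
) -> DecayFit:
    """Fit the multi-line decay model under a partition of lines.

    `shared` groups lines constrained to a common beta; the default (every
    line its own group) is the complete model, a single group containing
    all lines is the reduced single-curve model.  Groups share no
    parameters, so each is fitted by its own 1-D least squares; standard
    errors use the pooled residual variance SSR / (N - p).
    """
    groups = _normalise_partition(data, shared)
    frame = data.frame
    line_to_group = {ln: gi for gi, grp in enumerate(groups) for ln in grp}
    betas = np.empty(len(groups))
    jtjs = np.empty(len(groups))
    ssr = 0.0
    for gi, grp in enumerate(groups):
        sub = frame[frame["line"].isin(grp)]
        beta, group_ssr, jtj = _fit_group(
            sub["distance_kb"].to_numpy(dtype=float), sub["r2"].to_numpy(dtype=float)
        )
        betas[gi], jtjs[gi] = beta, jtj
        ssr += group_ssr
    n, p = data.n_records, len(groups)
    if n <= p:
        raise ConfigurationError("decay fit needs more records than parameters")
    sigma2 = ssr / (n - p)
    se = np.sqrt(sigma2 / jtjs)
    with np.errstate(divide="ignore"):
        pvals = 2.0 * stats.t.sf(np.abs(betas / se), df=n - p)
    return DecayFit(
        groups=groups,
        beta=betas,
        std_error=se,
        p_value=pvals,
        ssr=ssr,
        n_records=n,
        line_to_group=line_to_group,
    )


@dataclass
class CurveEqualityResult:
    """Nested-model comparison; chi2 = N * ln(ssr_reduced / ssr_full)."""

    chi2: float
    df: int
    p_value: float
    ssr_full: float
    ssr_reduced: float
    fit_full: DecayFit = field(repr=False)
    fit_reduced: DecayFit = field(repr=False)


def _is_coarsening(full: list[tuple[str, ...]], reduced: list[tuple[str, ...]]) -> bool:
    """True iff every full group lies wholly inside one reduced group."""
    reduced_sets = [set(g) for g in reduced]
    return all(any(set(f) <= r for r in reduced_sets) for f in full)


def equality_test(
    data: DecayDataset,
    full_partition: list[tuple[str, ...]] | None = None,
    reduced_partition: list[tuple[str, ...]] | None = None,
) -> CurveEqualityResult:
    """Test whether the coarser partition describes the data as well.

    Defaults compare the complete model (one beta per line) against the
    single-curve reduced model.  The statistic N * ln(SSR_reduced /
    SSR_full) is referred to chi-square with df equal to the parameter
    difference; an SSR_full of zero makes the statistic infinite.
    """
    full = _normalise_partition(data, full_partition)
    if reduced_partition is None:
        reduced_partition = [tuple(data.lines)]
    reduced = _normalise_partition(data, reduced_partition)
    if not _is_coarsening(full, reduced):
        raise ConfigurationError("reduced partition must coarsen the full partition")
    fit_full = fit_sved(data, full)
    fit_reduced = fit_sved(data, reduced)
    df = fit_full.n_params - fit_reduced.n_params
    if df < 1:
        raise ConfigurationError("reduced model must have fewer parameters")
    n = data.n_records
    if fit_full.ssr == 0.0:
        warnings.warn("SSR of the complete model is zero; statistic is infinite")
        chi2 = np.inf
    else:
        chi2 = max(0.0, n * np.log(fit_reduced.ssr / fit_full.ssr))
    return CurveEqualityResult(
        chi2=float(chi2),
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        ssr_full=fit_full.ssr,
        ssr_reduced=fit_reduced.ssr,
        fit_full=fit_full,
        fit_reduced=fit_reduced,
    )


def pairwise_equality(data: DecayDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Equality test for every unordered pair of lines, Bonferroni-corrected.

    Each comparison refits on the two lines' records only (complete: two
    betas; reduced: one).  The result frame carries `n_tests` and
    `alpha_star` (= alpha / n_tests) in ``attrs``.
    """
    lines = data.lines
    if len(lines) < 2:
        raise ConfigurationError("pairwise comparison needs at least 2 lines")
    pairs = list(itertools.combinations(lines, 2))
    alpha_star = alpha / len(pairs)
    rows = []
    for a, b in pairs:
        sub = DecayDataset(
            data.frame[data.frame["line"].isin((a, b))].reset_index(drop=True),
            check_bounds=data.check_bounds,
        )
        res = equality_test(sub, [(a,), (b,)], [(a, b)])
        rows.append(
            {
                "line_a": a,
                "line_b": b,
                "beta_a": res.fit_full.beta_for(a),
                "beta_b": res.fit_full.beta_for(b),
                "chi2": res.chi2,
                "df": res.df,
                "p_value": res.p_value,
                "significant": res.p_value < alpha_star,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(pairs)
    out.attrs["alpha"] = alpha
    out.attrs["alpha_star"] = alpha_star
    return out


def bin_summary(pairs: pd.DataFrame, bin_edges) -> pd.DataFrame:
    """Mean and SD of r^2 within half-open distance bins [lo, hi).

    `bin_edges` is a sequence of (lo_kb, hi_kb) tuples.  Empty bins are
    reported with count 0 and undefined statistics.
    """
    rows = []
    d = pairs["distance_kb"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    for lo, hi in bin_edges:
        sel = (d >= lo) & (d < hi)
        vals = r2[sel]
        rows.append(
            {
                "lo_kb": lo,
                "hi_kb": hi,
                "n_pairs": int(sel.sum()),
                "mean_r2": float(vals.mean()) if len(vals) else np.nan,
                "sd_r2": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
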
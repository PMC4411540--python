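"""Correlation machinery for comparing structural predictors with rates.

For one protein, each predictor x is scored by the squared Pearson
correlation R^2(K, x) with the empirical relative rates K, and by its squared
semipartial correlation rho^2(K, x | z) given a control predictor z — the
correlation between K and the residual of x after regressing z out of x
(control removed from the predictor only). The semipartial square equals the
increment in explained variance from the one-variable model K ~ z to the
two-variable model K ~ z + x, so it is the predictor's unique contribution.

Across proteins, expected values are plain means; dispersions and p-values
come from bootstrapping the set of proteins with replacement (the resampling
unit is the protein, not the site). p-values are one-sided: the fraction of
replicates in which the statistic of interest fails to be positive. Win
counts (protein-by-protein "A beats B") are computed on the original,
unresampled set, with exact ties counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    CollinearPredictorsError,
    InsufficientSitesError,
    NoProteinsError,
    ZeroVarianceError,
)
from .packing import PackingProfile
from .structures import AlignedRates, ProteinSites, RateProfile, align_rates_to_sites

CorrMethod = Literal["pearson", "spearman"]


def _as_values(x) -> np.ndarray:
    if isinstance(x, PackingProfile):
        x = x.values
    return np.asarray(x, dtype=float)


def _check_variance(v: np.ndarray, what: str) -> None:
    if np.ptp(v) == 0.0:
        raise ZeroVarianceError(f"zero variance: {what} is constant")


def r_squared(rates, predictor, method: CorrMethod = "pearson") -> float:
    """Squared correlation between per-site rates and a predictor.

    Symmetric and invariant to affine transforms (including sign flips) of
    either argument.
    """
    y, x = _as_values(rates), _as_values(predictor)
    if y.size != x.size:
        raise ValueError("rates and predictor must have equal length")
    if y.size < 3:
        raise InsufficientSitesError("insufficient sites: need at least 3 pairs")
    _check_variance(y, "rates")
    _check_variance(x, "predictor")
    if method == "spearman":
        r = sps.spearmanr(y, x).statistic
    else:
        r = np.corrcoef(y, x)[0, 1]
    return float(r * r)


def _residualize(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residual of x after OLS on z (with intercept)."""
    zc = z - z.mean()
    xc = x - x.mean()
    denom = zc @ zc
    if denom == 0.0:
        raise ZeroVarianceError("zero variance: control predictor is constant")
    return xc - (xc @ zc) / denom * zc


def semipartial_r_squared(rates, predictor_x, control_z,
                          method: CorrMethod = "pearson") -> float:
    """Squared semipartial correlation rho^2(K, x | z).

    The control is regressed out of the predictor only; the squared
    correlation of the rates with that residual equals the R^2 increment
    from K ~ z to K ~ z + x.
    """
    y, x, z = _as_values(rates), _as_values(predictor_x), _as_values(control_z)
    if not (y.size == x.size == z.size):
        raise ValueError("all vectors must have equal length")
    if y.size < 4:
        raise InsufficientSitesError("insufficient sites: need at least 4 pairs")
    _check_variance(y, "rates")
    _check_variance(x, "predictor")
    resid = _residualize(x, z)
    ss_resid = float(resid @ resid)
    ss_x = float(((x - x.mean()) ** 2).sum())
    if ss_resid <= 1e-12 * ss_x:
        raise CollinearPredictorsError(
            "collinear predictors: x is (numerically) an affine function of z"
        )
    if method == "spearman":
        r = sps.spearmanr(y, resid).statistic
    else:
        r = np.corrcoef(y, resid)[0, 1]
    return float(r * r)


def predicted_profile(rates, predictor) -> np.ndarray:
    """OLS affine fit of rates on a predictor, returned per site.

    This is the construction behind predicted-rate profiles and
    empirical-vs-predicted scatter comparisons: the fitted values share the
    rates' mean, and their R^2 with the rates equals r_squared(rates,
    predictor).
    """
    y, x = _as_values(rates), _as_values(predictor)
    if y.size < 3:
        raise InsufficientSitesError("insufficient sites: need at least 3 pairs")
    _check_variance(x, "predictor")
    slope, intercept = np.polyfit(x, y, 1)
    return intercept + slope * x


@dataclass
class ProteinComparison:
    """Per-protein predictive power of each structural predictor."""

    label: str
    n_sites: int
    control: str
    r2: dict[str, float]
    sp2: dict[str, float]  # squared semipartial given control; control absent


@dataclass
class PairwiseComparison:
    """Bootstrap comparison of two predictors' mean R^2."""

    predictor_a: str
    predictor_b: str
    delta_r2: float  # mean over proteins of R2_A, minus mean of R2_B
    sd: float
    p_value: float
    wins_a: int
    wins_b: int
    ties: int


@dataclass
class AggregateComparison:
    """Dataset-level summary over proteins with bootstrap dispersion."""

    predictors: list[str]
    control: str
    n_proteins: int
    n_boot: int
    mean_r2: dict[str, float]
    sd_r2: dict[str, float]
    mean_sp2: dict[str, float]
    sd_sp2: dict[str, float]
    p_sp2: dict[str, float]
    pairs: list[PairwiseComparison] = field(default_factory=list)


def compare_protein(
    sites: ProteinSites,
    rates: RateProfile | AlignedRates,
    predictors: Mapping[str, PackingProfile | np.ndarray],
    control: str = "WCN_rho_alpharho",
    align_mode: Literal["by_position", "by_order"] = "by_position",
    method: CorrMethod = "pearson",
) -> ProteinComparison:
    """Score every predictor against the empirical rates of one protein.

    Rates are aligned to structure sites first; R^2 and semipartial rho^2
    are computed on the matched subset only.
    """
    if control not in predictors:
        raise ValueError(f"control predictor {control!r} not among predictors")
    aligned = rates if isinstance(rates, AlignedRates) else align_rates_to_sites(
        sites, rates, mode=align_mode
    )
    idx = aligned.table["site_index"].to_numpy()
    if idx.size < 4:
        raise InsufficientSitesError(
            f"insufficient sites: only {idx.size} matched pairs"
        )
    y = aligned.table["relative_rate"].to_numpy()
    xs = {}
    for name, prof in predictors.items():
        v = _as_values(prof)
        if v.size != len(sites):
            raise ValueError(f"predictor {name!r} is not aligned to the sites")
        xs[name] = v[idx]
    r2 = {name: r_squared(y, x, method=method) for name, x in xs.items()}
    sp2 = {
        name: semipartial_r_squared(y, x, xs[control], method=method)
        for name, x in xs.items()
        if name != control
    }
    return ProteinComparison(label=sites.label, n_sites=int(idx.size),
                             control=control, r2=r2, sp2=sp2)


def aggregate(
    comparisons: Sequence[ProteinComparison],
    n_boot: int = 10_000,
    seed: int | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    sp2_threshold: float = 0.0,
) -> AggregateComparison:
    """Average per-protein comparisons with bootstrap dispersion.

    Resamples proteins with replacement ``n_boot`` times. For each pair
    (A, B) the p-value is the fraction of replicates whose mean
    R^2(A) - R^2(B) is <= 0 (one-sided); for each predictor's semipartial
    the p-value is the fraction of replicates whose mean rho^2 is
    <= ``sp2_threshold``. A p-value with zero qualifying replicates is
    reported as 1/n_boot (an upper bound, never 0). Win counts use the
    original set. Deterministic given seed.
    """
    if len(comparisons) == 0:
        raise NoProteinsError("no proteins: empty comparison list")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    predictors = list(comparisons[0].r2)
    control = comparisons[0].control
    for c in comparisons:
        if list(c.r2) != predictors or c.control != control:
            raise ValueError("comparisons have inconsistent predictor sets")
    if pairs is None:
        pairs = [(control, p) for p in predictors if p != control]

    P = len(comparisons)
    r2_mat = np.array([[c.r2[p] for p in predictors] for c in comparisons])
    sp_names = [p for p in predictors if p != control]
    sp2_mat = np.array([[c.sp2[p] for p in sp_names] for c in comparisons])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, P, size=(n_boot, P))
    boot_r2 = r2_mat[idx].mean(axis=1)      # (n_boot, n_pred)
    boot_sp2 = sp2_mat[idx].mean(axis=1)    # (n_boot, n_sp)

    def _pv(count: int) -> float:
        return count / n_boot if count > 0 else 1.0 / n_boot

    mean_r2 = {p: float(r2_mat[:, k].mean()) for k, p in enumerate(predictors)}
    sd_r2 = {p: float(boot_r2[:, k].std(ddof=0)) for k, p in enumerate(predictors)}
    mean_sp2 = {p: float(sp2_mat[:, k].mean()) for k, p in enumerate(sp_names)}
    sd_sp2 = {p: float(boot_sp2[:, k].std(ddof=0)) for k, p in enumerate(sp_names)}
    p_sp2 = {
        p: _pv(int((boot_sp2[:, k] <= sp2_threshold).sum()))
        for k, p in enumerate(sp_names)
    }

    pair_results = []
    col = {p: k for k, p in enumerate(predictors)}
    for a, b in pairs:
        da = r2_mat[:, col[a]] - r2_mat[:, col[b]]
        boot_d = boot_r2[:, col[a]] - boot_r2[:, col[b]]
        pair_results.append(PairwiseComparison(
            predictor_a=a,
            predictor_b=b,
            delta_r2=float(da.mean()),
            sd=float(boot_d.std(ddof=0)),
            p_value=_pv(int((boot_d <= 0.0).sum())),
            wins_a=int((da > 0).sum()),
            wins_b=int((da < 0).sum()),
            ties=int((da == 0).sum()),
        ))

    return AggregateComparison(
        predictors=predictors, control=control, n_proteins=P, n_boot=n_boot,
        mean_r2=mean_r2, sd_r2=sd_r2, mean_sp2=mean_sp2, sd_sp2=sd_sp2,
        p_sp2=p_sp2, pairs=pair_results,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def comparisons_to_frame(comparisons: Sequence[ProteinComparison]):
    """Per-protein comparison table (one row per protein)."""
    import pandas as pd

    rows = []
    for c in comparisons:
        row = {"protein": c.label, "n_sites": c.n_sites}
        for p, v in c.r2.items():
            row[f"R2_{p}"] = v
        for p, v in c.sp2.items():
            row[f"sp2_{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_to_frames(agg: AggregateComparison):
    """(summary, pairwise) DataFrames of an AggregateComparison."""
    import pandas as pd

    summary = pd.DataFrame([
        {
            "predictor": p,
            "mean_R2": agg.mean_r2[p],
            "sd_R2": agg.sd_r2[p],
            "mean_sp2": agg.mean_sp2.get(p, np.nan),
            "sd_sp2": agg.sd_sp2.get(p, np.nan),
            "p_value_sp2": agg.p_sp2.get(p, np.nan),
        }
        for p in agg.predictors
    ])
    pairwise = pd.DataFrame([
        {
            "pair": f"{pr.predictor_a} vs {pr.predictor_b}",
            "delta_R2": pr.delta_r2,
            "sd": pr.sd,
            "p_value": pr.p_value,
            "wins_A": pr.wins_a,
            "wins_B": pr.wins_b,
            "ties": pr.ties,
        }
        for pr in agg.pairs
    ])
    return summary, pairwise
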
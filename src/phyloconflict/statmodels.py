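"""Predictors of concordance and saturation diagnostics.

Aggregate binomial / quasibinomial logistic regression treats each gene
as one observation with x concordant nodes out of n evaluable nodes,
regressed on gene properties (alignment length, tree length,
root-to-tip variance).  Saturation is diagnosed per codon position by
comparing observed p-distances to F84-corrected distances: on the
diagonal the gene is unsaturated; a flattening slope indicates multiple
hits the correction can no longer recover.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alignments import Alignment

__all__ = [
    "RegressionFit",
    "fit_logistic",
    "influence",
    "refit_reduced",
    "f84_distance",
    "p_distance",
    "SaturationResult",
    "saturation_assess",
]

PREDICTORS = ("alignment_length", "tree_length", "root_to_tip_variance")


@dataclass
class RegressionFit:
    """Results of an aggregate binomial/quasibinomial logistic fit."""

    coefficients: pd.Series
    bse: pd.Series
    family: str
    dispersion: float
    deviance: float
    null_deviance: float
    df_resid: int
    fitted: pd.Series
    predictors: list[str]
    data: pd.DataFrame
    sm_result: object = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        z = self.coefficients / self.bse
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "std_error": self.bse,
                "z": z,
                "p_value": 2 * norm.sf(np.abs(z)),
            }
        )

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        q = norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "lower": self.coefficients - q * self.bse,
                "upper": self.coefficients + q * self.bse,
            }
        )


def _design(data: pd.DataFrame, predictors: Sequence[str]):
    for col in ("successes", "trials"):
        if col not in data:
            raise ValueError(f"data must have a {col!r} column")
    if (data["successes"] > data["trials"]).any() or (data["successes"] < 0).any():
        raise ValueError("successes must satisfy 0 <= x <= n")
    if (data["trials"] < 1).any():
        raise ValueError("every observation needs at least one trial")
    X = data[list(predictors)].astype(float)
    if (X.nunique() <= 1).any():
        bad = list(X.columns[X.nunique() <= 1])
        raise ValueError(f"constant predictors: {bad}")
    X = sm.add_constant(X, prepend=True)
    y = np.column_stack([data["successes"], data["trials"] - data["successes"]])
    return y, X


def fit_logistic(
    data: pd.DataFrame,
    predictors: Sequence[str],
    family: str = "binomial",
) -> RegressionFit:
    """Aggregate logistic regression of concordant nodes on gene properties.

    ``data`` needs ``successes`` and ``trials`` columns plus the named
    predictor columns (one row per gene).  ``family='quasibinomial'``
    keeps the binomial point estimates but scales standard errors by
    sqrt(phi) with phi = Pearson chi^2 / (N - p - 1).
    """
    if family not in ("binomial", "quasibinomial"):
        raise ValueError(f"unknown family {family!r}")
    if len(data) < len(predictors) + 1:
        raise ValueError("insufficient data: need more observations than parameters")
    y, X = _design(data, predictors)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:
            raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not res.converged:
        raise ValueError("IRLS did not converge")
    warned = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    fitted_extreme = bool(
        (res.fittedvalues < 1e-8).any() or (res.fittedvalues > 1 - 1e-8).any()
    )
    # a saturated fit to interior proportions also triggers the statsmodels
    # warning; genuine separation drives fitted probabilities to 0/1
    if np.abs(res.params).max() > 1e3 or (warned and fitted_extreme):
        raise ValueError("perfect separation: diverging coefficients")
    # phi as R reports it for quasibinomial: Pearson chi^2 / (N - p - 1);
    # statsmodels' scale='X2' drops the aggregate weights, so compute it here
    phi = float(res.pearson_chi2) / res.df_resid if family == "quasibinomial" else 1.0
    fitted = pd.Series(res.fittedvalues, index=data.index, name="fitted_probability")
    return RegressionFit(
        coefficients=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse * math.sqrt(phi), index=X.columns),
        family=family,
        dispersion=phi,
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        df_resid=int(res.df_resid),
        fitted=fitted,
        predictors=list(predictors),
        data=data,
        sm_result=res,
    )


def influence(fit: RegressionFit) -> pd.DataFrame:
    """Studentized residuals, leverages and Cook's distances per gene.

    Flags use the conventional thresholds |r| > 2, h > 2p/N, D > 4/N.
    """
    infl = fit.sm_result.get_influence(observed=False)
    hat = infl.hat_matrix_diag
    cooks = infl.cooks_distance[0]
    student = infl.resid_studentized
    n = len(hat)
    p = len(fit.coefficients)
    df = pd.DataFrame(
        {
            "studentized_residual": student,
            "leverage": hat,
            "cooks_distance": cooks,
        },
        index=fit.data.index,
    )
    df["flag_residual"] = np.abs(df["studentized_residual"]) > 2
    df["flag_leverage"] = df["leverage"] > 2 * p / n
    df["flag_cooks"] = df["cooks_distance"] > 4 / n
    return df


def refit_reduced(
    data: pd.DataFrame,
    exclude: Iterable[str],
    predictors: Sequence[str],
    family: str = "binomial",
) -> RegressionFit:
    """Refit after excluding named genes (influence-driven sensitivity)."""
    exclude = list(exclude)
    unknown = [g for g in exclude if g not in data.index]
    if unknown:
        raise ValueError(f"unknown genes to exclude: {unknown}")
    kept = data.drop(index=exclude)
    if len(kept) < len(predictors) + 1:
        raise ValueError("insufficient data after exclusions")
    return fit_logistic(kept, predictors, family)


# ----------------------------------------------------------------------
# distances and saturation


def _pair_sites(s1: str, s2: str) -> tuple[str, str]:
    keep = [
        (a, b)
        for a, b in zip(s1.upper(), s2.upper())
        if a in "ACGT" and b in "ACGT"
    ]
    if not keep:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    return "".join(a for a, _ in keep), "".join(b for _, b in keep)


def p_distance(s1: str, s2: str) -> float:
    """Uncorrected proportion of differing sites (gapped sites excluded)."""
    a, b = _pair_sites(s1, s2)
    return sum(x != y for x, y in zip(a, b)) / len(a)


_PURINES = frozenset("AG")


def f84_distance(s1: str, s2: str) -> float:
    """Maximum-likelihood F84 distance between two aligned rows.

    Uses the closed form with base frequencies averaged over the pair
    and the observed transition (P) and transversion (Q) proportions;
    sites with a gap or ambiguity in either row are excluded.  Returns
    ``inf`` when a log argument is non-positive (divergence beyond what
    the correction can recover).
    """
    a, b = _pair_sites(s1, s2)
    n = len(a)
    both = a + b
    freqs = {c: both.count(c) / (2 * n) for c in "ACGT"}
    P = Q = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            P += 1
        else:
            Q += 1
    P /= n
    Q /= n
    piA, piC, piG, piT = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    piR, piY = piA + piG, piC + piT
    if piR <= 0 or piY <= 0:
        return math.inf if P + Q > 0 else 0.0
    A = piA * piG / piR + piC * piT / piY
    B = piA * piG + piC * piT
    C = piR * piY
    if A <= 0:  # one class of bases absent: transitions impossible
        arg2 = 1 - Q / (2 * C)
        return math.inf if arg2 <= 0 else -2 * (B + C - A) * math.log(arg2)
    arg1 = 1 - P / (2 * A) - (A - B) * Q / (2 * A * C)
    arg2 = 1 - Q / (2 * C)
    if arg1 <= 0 or arg2 <= 0:
        return math.inf
    return -2 * A * math.log(arg1) + 2 * (A - B - C) * math.log(arg2)


@dataclass
class SaturationResult:
    """Observed vs F84-corrected distances per codon position.

    ``pairs`` holds one row per taxon pair and position ("1", "2", "3",
    "all"); ``slopes`` holds the per-position slope of observed on
    corrected distance through the origin (NaN when undefined, e.g. all
    distances zero).  Saturated pairs (infinite correction) are flagged,
    not dropped from the table.
    """

    pairs: pd.DataFrame
    slopes: dict[str, float]

    @property
    def n_flagged(self) -> int:
        return int(self.pairs["flagged"].sum())


def _codon_position(aln: Alignment, pos: Optional[int]) -> Alignment:
    if pos is None:
        return aln
    idx = list(range(pos - 1, aln.length, 3))
    return aln.columns(idx)


def saturation_assess(codon_aln: Alignment) -> SaturationResult:
    """All-pairs observed and F84-corrected distances per codon position.

    The alignment length must be divisible by 3 (a codon alignment from
    the protein-guided expansion).  The summary slope regresses the
    observed distance on the corrected distance through the origin over
    finite pairs; a value near 1 means essentially no saturation.
    """
    if codon_aln.length % 3:
        raise ValueError("codon alignment length must be divisible by 3")
    rows = []
    slopes: dict[str, float] = {}
    for name, pos in (("1", 1), ("2", 2), ("3", 3), ("all", None)):
        sub = _codon_position(codon_aln, pos)
        obs_list, corr_list = [], []
        for t1, t2 in itertools.combinations(sub.taxa, 2):
            s1, s2 = sub.sequences[t1], sub.sequences[t2]
            try:
                obs = p_distance(s1, s2)
                corr = f84_distance(s1, s2)
                flagged = not math.isfinite(corr)
            except ValueError:
                obs, corr, flagged = math.nan, math.nan, True
            rows.append(
                {
                    "position": name,
                    "taxon_1": t1,
                    "taxon_2": t2,
                    "p_distance": obs,
                    "f84_distance": corr,
                    "flagged": flagged,
                }
            )
            if not flagged:
                obs_list.append(obs)
                corr_list.append(corr)
        x = np.asarray(corr_list)
        y = np.asarray(obs_list)
        denom = float(np.sum(x * x))
        slopes[name] = float(np.sum(x * y) / denom) if denom > 0 else math.nan
    return SaturationResult(pairs=pd.DataFrame(rows), slopes=slopes)
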
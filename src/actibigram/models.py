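"""Swap-style OLS models relating activity features to a continuous outcome.

Within a day there is a fixed budget of epochs (nd = 1440 minutes) and of
epoch pairs (nd - 1), so an increase in one state's minutes, or one
bigram's frequency, must be paid for by a decrease elsewhere. The swap
models express this: one feature is the *baseline* (left out of the model),
another the *comparison* (in the model), and the pooled remainder is
adjusted for. For a transfer of time between activity states, e.g. baseline
S and comparison M,

    outcome = b1 * Md + b2 * r + e,   r = nd - (Md + Sd)

so b1 is the outcome difference per minute/day moved from S to M with the
other states' total held fixed. For a swap between (u-)bigram frequencies,
e.g. baseline SS and comparison SL,

    outcome = b1 * b(S,L) + b2 * rb + e,   rb = (nd - 1) - b(S,L) - b(S,S)

Exchanging baseline and comparison is a linear reparametrization of the
same design, so the estimate negates exactly and its CI width is unchanged.

Adjustment sets follow a fixed series: model1 is unadjusted; model2 adds
the named covariates (demographic/behavioural confounders); model3 is
model2 plus the four state durations Sd..Vd; model4 is model2 plus mCPM.
Effects are reported per 10-unit swap (times 10) or per 1 SD of the
baseline feature. Confidence intervals are 95% t-intervals on residual
degrees of freedom. Complete-case analysis per model; no multiplicity
correction is applied across a grid of contrasts.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .features import BIGRAMS, DURATION_COLUMNS, UBIGRAMS, ubigram_key
from .preprocess import STATES

ADJUSTMENTS = ("model1", "model2", "model3", "model4")
KINDS = ("state_transfer", "bigram_swap", "ubigram_swap")
SCALES = ("per_10", "per_sd")


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {', '.join(columns)}")


class DegenerateFeatureError(ValueError):
    """A model feature has zero variance in the analysis rows."""


def _canonical_key(kind: str, key: str) -> str:
    if kind == "state_transfer":
        if key not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {key!r}")
        return key
    if kind == "bigram_swap":
        if key not in BIGRAMS:
            raise ValueError(f"bigram must be one of {BIGRAMS}, got {key!r}")
        return key
    if kind == "ubigram_swap":
        bare = key.strip("[]")
        if len(bare) != 2 or any(s not in STATES for s in bare):
            raise ValueError(f"u-bigram key {key!r} not over alphabet {STATES}")
        return ubigram_key(bare[0], bare[1])
    raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")


@dataclass(frozen=True)
class SwapModelSpec:
    """Definition of one baseline-vs-comparison regression.

    ``covariates`` names the confounder columns that enter under model2-4.
    ``use_observed_pairs`` replaces the nominal pair budget nd - 1 in the
    bigram remainder with each participant's observed non-missing pairs per
    day (an auditing option; the nominal budget is the primary analysis).
    """

    kind: str
    baseline: str
    comparison: str
    adjustment: str = "model1"
    scale: str = "per_10"
    nd: int = 1440
    covariates: tuple[str, ...] = ()
    use_observed_pairs: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.adjustment not in ADJUSTMENTS:
            raise ValueError(
                f"adjustment must be one of {ADJUSTMENTS}, got {self.adjustment!r}"
            )
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        object.__setattr__(self, "baseline", _canonical_key(self.kind, self.baseline))
        object.__setattr__(
            self, "comparison", _canonical_key(self.kind, self.comparison)
        )
        if self.baseline == self.comparison:
            raise ValueError("baseline and comparison must differ")
        if self.kind == "state_transfer" and self.adjustment in ("model3", "model4"):
            raise ValueError(
                "model3/model4 adjust for state durations or mCPM and are only "
                "meaningful for bigram/u-bigram swaps"
            )
        if self.nd <= 0:
            raise ValueError("nd must be positive")
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class SwapModelResult:
    """Fitted output of one swap regression."""

    kind: str
    baseline: str
    comparison: str
    adjustment: str
    scale: str
    beta_scaled: float
    ci_low: float
    ci_high: float
    raw_beta: float
    raw_se: float
    n_used: int
    sd_of_baseline: float | None = None


def _check_design(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    names = ["const"] + list(X.columns)
    for j, col in enumerate(X.columns):
        if np.ptp(X[col].to_numpy(dtype=float)) == 0.0:
            raise DegenerateFeatureError(f"column {col!r} has zero variance")
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR: columns whose R diagonal collapses are the dependents
        _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise CollinearityError(sorted(set(bad) - {"const"}) or names[1:])


def _fit(
    table: pd.DataFrame,
    outcome: str,
    x1: pd.Series,
    remainder: pd.Series,
    covariates: list[str],
    scale: str,
    scale_factor_per10: float,
    baseline_for_sd: pd.Series,
    kind: str,
    baseline: str,
    comparison: str,
    adjustment: str,
) -> SwapModelResult:
    X = pd.DataFrame({"comparison": x1, "remainder": remainder})
    for cov in covariates:
        X[cov] = pd.to_numeric(table[cov], errors="raise")
    y = pd.to_numeric(table[outcome], errors="raise")
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X.loc[keep], y.loc[keep]
    n_used = int(len(y))
    if n_used < X.shape[1] + 2:
        raise ValueError(
            f"{n_used} complete cases for {X.shape[1] + 1} model terms"
        )
    _check_design(X)
    res = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy(dtype=float))).fit()
    raw_beta = float(res.params[1])
    raw_se = float(res.bse[1])
    lo, hi = (float(v) for v in res.conf_int(alpha=0.05)[1])
    sd_base: float | None = None
    if scale == "per_10":
        factor = scale_factor_per10
    else:
        sd_base = float(baseline_for_sd.loc[keep].std(ddof=1))
        factor = sd_base
    return SwapModelResult(
        kind=kind,
        baseline=baseline,
        comparison=comparison,
        adjustment=adjustment,
        scale=scale,
        beta_scaled=raw_beta * factor,
        ci_low=lo * factor,
        ci_high=hi * factor,
        raw_beta=raw_beta,
        raw_se=raw_se,
        n_used=n_used,
        sd_of_baseline=sd_base,
    )


def _adjustment_covariates(spec: SwapModelSpec) -> list[str]:
    if spec.adjustment == "model1":
        return []
    covs = list(spec.covariates)
    if spec.adjustment == "model3":
        covs += list(DURATION_COLUMNS)
    elif spec.adjustment == "model4":
        covs += ["mCPM"]
    return covs


def fit_state_transfer(
    table: pd.DataFrame, spec: SwapModelSpec, outcome: str = "BMI"
) -> SwapModelResult:
    """Fit the transfer-of-time model for one (baseline, comparison) state pair.

    The comparison state's minutes/day enter the model together with the
    remaining time r = nd - (comparison + baseline minutes); the estimate is
    the outcome difference per minute/day transferred from baseline to
    comparison, reported x10 (``per_10``) or per SD of the baseline state's
    minutes (``per_sd``).
    """
    if spec.kind != "state_transfer":
        raise ValueError(f"spec.kind must be 'state_transfer', got {spec.kind!r}")
    comp_col = spec.comparison + "d"
    base_col = spec.baseline + "d"
    x1 = pd.to_numeric(table[comp_col], errors="raise")
    base = pd.to_numeric(table[base_col], errors="raise")
    remainder = spec.nd - (x1 + base)
    return _fit(
        table, outcome, x1, remainder, _adjustment_covariates(spec),
        spec.scale, 10.0, base,
        spec.kind, spec.baseline, spec.comparison, spec.adjustment,
    )


def fit_bigram_swap(
    table: pd.DataFrame, spec: SwapModelSpec, outcome: str = "BMI"
) -> SwapModelResult:
    """Fit the frequency-swap model for one (u-)bigram pair.

    The comparison frequency enters with the pooled remainder
    rb = (nd - 1) - comparison - baseline, which absorbs collateral changes
    in all other (u-)bigrams while their total is held fixed. Adjustment
    covariates follow model1-4. With ``use_observed_pairs`` the nominal
    budget nd - 1 is replaced by each participant's observed valid pairs per
    day.
    """
    if spec.kind not in ("bigram_swap", "ubigram_swap"):
        raise ValueError(
            f"spec.kind must be a swap kind, got {spec.kind!r}"
        )
    x1 = pd.to_numeric(table[spec.comparison], errors="raise")
    base = pd.to_numeric(table[spec.baseline], errors="raise")
    if spec.use_observed_pairs:
        budget = pd.to_numeric(table["n_valid_pairs"], errors="raise") / pd.to_numeric(
            table["D"], errors="raise"
        )
    else:
        budget = float(spec.nd - 1)
    remainder = budget - x1 - base
    return _fit(
        table, outcome, x1, remainder, _adjustment_covariates(spec),
        spec.scale, 10.0, base,
        spec.kind, spec.baseline, spec.comparison, spec.adjustment,
    )


def fit_swap(table: pd.DataFrame, spec: SwapModelSpec, outcome: str = "BMI") -> SwapModelResult:
    """Dispatch a spec to the matching fit routine."""
    if spec.kind == "state_transfer":
        return fit_state_transfer(table, spec, outcome)
    return fit_bigram_swap(table, spec, outcome)


def fit_cpm_models(
    table: pd.DataFrame,
    adjustment: str = "model1",
    mutual: bool = False,
    covariates: tuple[str, ...] = (),
    outcome: str = "BMI",
) -> tuple[SwapModelResult, SwapModelResult]:
    """Association of mCPM and sdCPM with the outcome, individually.

    Returns (mCPM result, sdCPM result). The mCPM effect is reported per
    100 counts/min; the sdCPM effect per sample SD of sdCPM. With
    ``mutual=True`` each model additionally adjusts for the other variable
    (the classic mean-vs-variability decomposition).
    """
    if adjustment not in ("model1", "model2"):
        raise ValueError("cpm models support adjustment 'model1' or 'model2'")
    covs = list(covariates) if adjustment == "model2" else []
    results = []
    for var, other in (("mCPM", "sdCPM"), ("sdCPM", "mCPM")):
        x1 = pd.to_numeric(table[var], errors="raise")
        X = pd.DataFrame({var: x1})
        model_covs = covs + ([other] if mutual else [])
        for cov in model_covs:
            X[cov] = pd.to_numeric(table[cov], errors="raise")
        y = pd.to_numeric(table[outcome], errors="raise")
        keep = y.notna() & X.notna().all(axis=1)
        X, y = X.loc[keep], y.loc[keep]
        _check_design(X)
        res = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy(dtype=float))).fit()
        raw_beta = float(res.params[1])
        raw_se = float(res.bse[1])
        lo, hi = (float(v) for v in res.conf_int(alpha=0.05)[1])
        if var == "mCPM":
            factor, scale, sd_base = 100.0, "per_100_counts", None
        else:
            sd_base = float(x1.loc[keep].std(ddof=1))
            factor, scale = sd_base, "per_sd"
        results.append(
            SwapModelResult(
                kind="cpm",
                baseline="",
                comparison=var,
                adjustment=adjustment + ("+mutual" if mutual else ""),
                scale=scale,
                beta_scaled=raw_beta * factor,
                ci_low=lo * factor,
                ci_high=hi * factor,
                raw_beta=raw_beta,
                raw_se=raw_se,
                n_used=int(len(y)),
                sd_of_baseline=sd_base,
            )
        )
    return results[0], results[1]


_RESULT_COLUMNS = (
    "kind", "baseline", "comparison", "model", "scale",
    "beta", "ci_low", "ci_high", "raw_beta", "raw_se", "n", "sd_baseline",
    "error",
)


def run_full_grid(
    table: pd.DataFrame,
    kinds: tuple[str, ...] = ("state_transfer", "ubigram_swap"),
    adjustments: tuple[str, ...] = ("model1", "model2"),
    scale: str = "per_10",
    covariates: tuple[str, ...] = (),
    outcome: str = "BMI",
    nd: int = 1440,
    use_observed_pairs: bool = False,
) -> pd.DataFrame:
    """Fit every unordered contrast of each requested family.

    One orientation per pair is emitted (the reverse orientation is the
    exact negation): 6 transfer contrasts over the 4 states, 45 u-bigram
    contrasts over the 10 u-bigrams, 120 for ordered bigrams. Per-fit
    failures become flagged rows rather than aborting the grid.
    """
    alphabets = {
        "state_transfer": STATES,
        "bigram_swap": BIGRAMS,
        "ubigram_swap": UBIGRAMS,
    }
    rows = []
    for kind in kinds:
        keys = alphabets[kind]
        for baseline, comparison in itertools.combinations(keys, 2):
            for adjustment in adjustments:
                if kind == "state_transfer" and adjustment in ("model3", "model4"):
                    continue
                try:
                    spec = SwapModelSpec(
                        kind=kind, baseline=baseline, comparison=comparison,
                        adjustment=adjustment, scale=scale, nd=nd,
                        covariates=covariates,
                        use_observed_pairs=use_observed_pairs,
                    )
                    r = fit_swap(table, spec, outcome)
                    rows.append({
                        "kind": kind, "baseline": r.baseline,
                        "comparison": r.comparison, "model": adjustment,
                        "scale": scale, "beta": r.beta_scaled,
                        "ci_low": r.ci_low, "ci_high": r.ci_high,
                        "raw_beta": r.raw_beta, "raw_se": r.raw_se,
                        "n": r.n_used, "sd_baseline": r.sd_of_baseline,
                        "error": "",
                    })
                except (ValueError, KeyError) as exc:
                    rows.append({
                        "kind": kind, "baseline": baseline,
                        "comparison": comparison, "model": adjustment,
                        "scale": scale, "beta": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "raw_beta": np.nan,
                        "raw_se": np.nan, "n": 0, "sd_baseline": np.nan,
                        "error": str(exc),
                    })
    return pd.DataFrame(rows, columns=list(_RESULT_COLUMNS))
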
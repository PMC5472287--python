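"""Logistic-regression evaluation, internal validation, power calculation.

Logistic fits delegate to statsmodels' Newton/IRLS maximum-likelihood
solver. "Variance explained" by a score is a pseudo-R²: Nagelkerke
(rescaled Cox–Snell, the GRS-literature convention) by default, McFadden
alongside. Internal validation re-runs the whole pipeline — association,
panel selection, weighting — on a stratified 75% training split and scores
the held-out 25%, comparing the two AUCs with the unpaired z-test and
reporting confusion metrics at the training-set Youden threshold. The power
of the allelic test is a two-sided normal approximation for comparing two
allele proportions, 2n alleles per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import association, grs, roc
from .cohort import GenotypeMatrix, SnpMeta
from .simulate import case_raf

TRAITS = ("nail", "psa", "onset_class", "family_history")


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, SEs, log-likelihoods."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    loglik_null: float
    n: int
    converged: bool

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.coefficients[term]))

    def wald_p(self, term: str) -> float:
        z = self.coefficients[term] / self.standard_errors[term]
        return float(2.0 * stats.norm.sf(abs(z)))

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        zc = stats.norm.ppf(0.5 + level / 2.0)
        c, se = self.coefficients[term], self.standard_errors[term]
        return float(np.exp(c - zc * se)), float(np.exp(c + zc * se))


def fit_logistic(design, outcome) -> LogisticFit:
    """Maximum-likelihood logistic regression (intercept added).

    `design` is a DataFrame / 2-D array of predictors (or a Series for a
    single predictor); `outcome` is binary. Perfect separation or other
    non-convergence is flagged rather than raised.
    """
    if isinstance(design, pd.Series):
        X = design.to_frame()
    elif isinstance(design, pd.DataFrame):
        X = design.copy()
    else:
        arr = np.atleast_2d(np.asarray(design, dtype=float))
        if arr.shape[0] == 1 and np.asarray(outcome).size != 1:
            arr = arr.T
        X = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples in each outcome class")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, method="bfgs")
            converged = False
    # huge coefficients signal (quasi-)separation even if the solver "converged"
    if np.max(np.abs(res.params.values)) > 50:
        converged = False
    null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
    return LogisticFit(
        coefficients={k: float(v) for k, v in res.params.items()},
        standard_errors={k: float(v) for k, v in res.bse.items()},
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        n=int(y.size),
        converged=converged,
    )


def variance_explained(fit: LogisticFit, method: str = "nagelkerke") -> float:
    """Pseudo-R² of a logistic fit.

    McFadden: 1 − ll/ll0. Nagelkerke: Cox–Snell
    1 − exp(2(ll0 − ll)/n) rescaled by its maximum 1 − exp(2·ll0/n).
    """
    ll, ll0, n = fit.loglik, fit.loglik_null, fit.n
    if method == "mcfadden":
        return float(1.0 - ll / ll0) if ll0 != 0 else 0.0
    if method == "nagelkerke":
        cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        max_cs = 1.0 - np.exp(2.0 * ll0 / n)
        return float(cox_snell / max_cs) if max_cs > 0 else 0.0
    raise ValueError(f"unknown pseudo-R² method {method!r}")


@dataclass(frozen=True)
class SubphenotypeResult:
    trait: str
    or_per_unit: float
    ci95: tuple[float, float]
    p: float
    n: int


def subphenotype_association(scores: grs.ScoreSet | pd.Series, ph: pd.DataFrame,
                             trait: str, standardize: bool = False) -> SubphenotypeResult:
    """Within-case logistic regression of a sub-phenotype on the GRS.

    ``onset_class`` is coded T2Ps = 1 vs T1Ps = 0; the yes/no traits code
    yes = 1. Unknowns are dropped; at least 20 informative cases required.
    ``standardize`` rescales the score to unit SD (OR per SD instead of
    per raw score unit).
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; choose from {TRAITS}")
    s = scores.complete_scores() if isinstance(scores, grs.ScoreSet) else scores.dropna()
    ph = ph.set_index("sample_id", drop=False)
    cases = ph[ph["status"] == "case"]
    common = s.index.intersection(cases.index)
    sub = cases.loc[common]
    if trait == "onset_class":
        known = sub["onset_class"].isin(["T1Ps", "T2Ps"])
        y = (sub.loc[known, "onset_class"] == "T2Ps").astype(float)
    else:
        known = sub[trait].isin(["yes", "no"])
        y = (sub.loc[known, trait] == "yes").astype(float)
    x = s.loc[y.index]
    if y.nunique() < 2:
        raise ValueError(f"trait {trait!r} is constant among informative cases")
    if len(y) < 20:
        raise ValueError(f"only {len(y)} informative cases for trait {trait!r} (need >= 20)")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
    fit = fit_logistic(x.rename("grs"), y.to_numpy())
    return SubphenotypeResult(
        trait=trait,
        or_per_unit=fit.odds_ratio("grs"),
        ci95=fit.conf_int("grs"),
        p=fit.wald_p("grs"),
        n=int(len(y)),
    )


@dataclass
class ValidationReport:
    """Train/test internal validation of a re-fitted GRS panel."""

    train_auc: float
    test_auc: float
    auc_p: float
    train_metrics: roc.ConfusionMetrics
    test_metrics: roc.ConfusionMetrics
    threshold: float
    panel: grs.GrsPanel
    seed: int
    split: tuple[float, float] = (0.75, 0.25)
    train_ids: list[str] = field(default_factory=list, repr=False)
    test_ids: list[str] = field(default_factory=list, repr=False)


def internal_validation(gm: GenotypeMatrix, ph: pd.DataFrame,
                        meta: Sequence[SnpMeta] | None, variant: str,
                        seed: int, train_frac: float = 0.75,
                        bonferroni_m: int | None = None,
                        ld_drop: Sequence[str] = association.DEFAULT_LD_DROP,
                        hwe_sample: str = "controls") -> ValidationReport:
    """75/25 internal validation with full re-estimation on the training set.

    The split is random but stratified by case status and fully determined
    by `seed`. Association ORs, panel membership under `variant` and the
    ln(OR) weights are re-estimated on the training samples only; both sets
    are then scored, their AUCs compared with the unpaired z-test, and
    confusion metrics evaluated at the training-set Youden threshold.
    """
    rng = np.random.default_rng(seed)
    status = pd.Series(ph["status"].values, index=ph["sample_id"].values)
    status = status.reindex(gm.sample_ids)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for stratum in ("case", "control"):
        ids = np.array([s for s in gm.sample_ids if status[s] == stratum])
        perm = rng.permutation(ids.size)
        n_train = int(round(train_frac * ids.size))
        train_ids += list(ids[perm[:n_train]])
        test_ids += list(ids[perm[n_train:]])
    for name, ids in (("training", train_ids), ("test", test_ids)):
        sub = status.loc[ids]
        if (sub == "case").sum() == 0 or (sub == "control").sum() == 0:
            raise ValueError(f"{name} split lost an outcome stratum; cohort too small")

    ph_idx = ph.set_index("sample_id", drop=False)
    gm_train = gm.subset(sample_ids=train_ids)
    results = association.association_table(
        gm_train, ph_idx.loc[train_ids], hwe_sample=hwe_sample,
        bonferroni_m=bonferroni_m)
    panel = grs.build_panel(results, variant, ld_drop=ld_drop, m=bonferroni_m)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, ids in (("train", train_ids), ("test", test_ids)):
        ss = grs.score(gm.subset(sample_ids=ids), panel)
        sc = ss.complete_scores()
        lab = (status.loc[sc.index] == "case").to_numpy()
        out[name] = (sc.to_numpy(), lab)

    roc_train = roc.auc(out["train"][0][out["train"][1]], out["train"][0][~out["train"][1]])
    roc_test = roc.auc(out["test"][0][out["test"][1]], out["test"][0][~out["test"][1]])
    cmp = roc.compare_auc(out["train"][0], out["test"][0],
                          labels=out["train"][1], labels_b=out["test"][1], paired=False)
    thr = roc.youden_threshold(roc_train)
    return ValidationReport(
        train_auc=roc_train.auc, test_auc=roc_test.auc, auc_p=cmp.p,
        train_metrics=roc.confusion_metrics(*out["train"], threshold=thr),
        test_metrics=roc.confusion_metrics(*out["test"], threshold=thr),
        threshold=thr, panel=panel, seed=seed,
        split=(train_frac, 1.0 - train_frac),
        train_ids=train_ids, test_ids=test_ids,
    )


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the allelic-test power calculation."""

    p0: float
    or_alt: float
    n_case: int
    n_ctrl: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0,1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")


def power_allelic(spec: PowerSpec) -> float:
    """Normal-approximation power of the two-proportion allelic test.

    The alternative case RAF is the image of ``p0`` under the allelic-odds
    map at ``or_alt``; each stratum contributes 2n alleles. Two-sided at
    level alpha, pooled-variance null SE, unpooled alternative SE; at
    OR = 1 the power equals alpha.
    """
    p1 = case_raf(spec.p0, spec.or_alt)
    m1, m0 = 2 * spec.n_case, 2 * spec.n_ctrl
    delta = p1 - spec.p0
    pbar = (m1 * p1 + m0 * spec.p0) / (m1 + m0)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m0))
    se1 = np.sqrt(p1 * (1 - p1) / m1 + spec.p0 * (1 - spec.p0) / m0)
    zc = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    upper = stats.norm.sf((zc * se0 - delta) / se1)
    lower = stats.norm.cdf((-zc * se0 - delta) / se1)
    return float(upper + lower)
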
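"""Weighted genetic risk scores, named panel variants, quartile dose-response.

The score of a sample is Σ (risk-allele dosage × ln OR) over a panel of
SNPs, the weights being the in-sample allelic odds ratios re-estimated from
the analysed cohort (literature weights may be supplied instead). Samples
missing any panel dosage are flagged incomplete and excluded listwise from
downstream statistics (a mean-dosage imputation option exists but is off by
default).

Named panel variants:

=============  ==========================================================
``ALL``        every analysed SNP minus the LD-dropped proxy
``0.1``        SNPs with association P < 0.1
``N``          SNPs nominally associated (P < 0.05) — the headline panel
``B``          SNPs surviving the Bonferroni gate
``HLA``        the single HLA-C*06:02 proxy SNP
``N+HLA-``     ``N`` without the HLA proxy
``N(subst.)``  ``N`` with the HLA proxy replaced by its LD partner
=============  ==========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import (DEFAULT_HLA_SNP, DEFAULT_LD_DROP, AlleleCounts2x2,
                          allelic_test, select_panel)
from .cohort import GenotypeMatrix

PANEL_VARIANTS = ("ALL", "0.1", "N", "B", "HLA", "N+HLA-", "N(subst.)")

_VARIANT_RULE = {"ALL": "all", "0.1": "p<0.1", "N": "p<0.05", "B": "bonferroni"}


class DegenerateCutpointsWarning(UserWarning):
    """Quartile cutpoints collapsed because of massive score ties."""


@dataclass(frozen=True)
class GrsPanel:
    """A named SNP subset with ln(OR) weights."""

    name: str
    snp_ids: tuple[str, ...]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("panel SNP ids must be unique")
        for snp in self.snp_ids:
            w = self.weights.get(snp)
            if w is None or not np.isfinite(w):
                raise ValueError(f"panel SNP {snp!r} lacks a finite weight")


@dataclass
class ScoreSet:
    """Per-sample GRS values with completeness flags.

    ``complete`` is False iff any panel dosage was missing for the sample;
    incomplete samples carry a NaN score unless imputation was requested.
    """

    scores: pd.Series = field(repr=False)
    complete: pd.Series = field(repr=False)
    panel_name: str = "custom"

    def complete_scores(self) -> pd.Series:
        return self.scores[self.complete]

    @property
    def n_excluded(self) -> int:
        return int((~self.complete).sum())


def build_panel(results: pd.DataFrame, variant: str,
                ld_drop: Sequence[str] = DEFAULT_LD_DROP,
                hla_snp: str = DEFAULT_HLA_SNP,
                proxy_snp: str = "rs10484554",
                m: int | None = None,
                weight_column: str = "or") -> GrsPanel:
    """Construct a named panel from an association results table.

    `results` needs ``snp_id``, ``p`` and the odds-ratio column named by
    `weight_column` (set it to a literature-OR column for external
    weights). Weights are the natural logs of those odds ratios, each SNP
    weighted by its own OR (the substituted proxy included).
    """
    if variant not in PANEL_VARIANTS:
        raise ValueError(f"unknown panel variant {variant!r}; choose from {PANEL_VARIANTS}")
    ors = dict(zip(results["snp_id"], results[weight_column]))

    if variant == "HLA":
        snps = [hla_snp]
    elif variant in _VARIANT_RULE:
        snps = select_panel(results, _VARIANT_RULE[variant], ld_drop=ld_drop, m=m)
    else:
        base = select_panel(results, "p<0.05", ld_drop=ld_drop, m=m)
        if variant == "N+HLA-":
            snps = [s for s in base if s != hla_snp]
        else:  # N(subst.)
            snps = [proxy_snp if s == hla_snp else s for s in base]
    missing = [s for s in snps if s not in ors]
    if missing:
        raise ValueError(f"panel {variant!r} needs SNP {missing[0]!r}, absent from results")
    weights = {s: float(np.log(ors[s])) for s in snps}
    return GrsPanel(name=variant, snp_ids=tuple(snps), weights=weights)


def score(gm: GenotypeMatrix, panel: GrsPanel, impute_missing: bool = False) -> ScoreSet:
    """Compute the weighted risk score of every sample under a panel.

    With ``impute_missing`` a missing dosage is replaced by the SNP's mean
    dosage across the cohort (samples stay flagged incomplete).
    """
    absent = [s for s in panel.snp_ids if s not in gm.dosages.columns]
    if absent:
        raise ValueError(f"genotype matrix lacks panel SNP {absent[0]!r}")
    dos = gm.dosages[list(panel.snp_ids)].to_numpy(dtype=float)
    w = np.array([panel.weights[s] for s in panel.snp_ids])
    complete = ~np.isnan(dos).any(axis=1)
    if impute_missing and dos.size:
        col_means = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
        col_means = np.nan_to_num(col_means, nan=0.0)
        dos = np.where(np.isnan(dos), col_means, dos)
    vals = dos @ w
    if not impute_missing:
        vals = np.where(complete, vals, np.nan)
    idx = gm.dosages.index
    return ScoreSet(scores=pd.Series(vals, index=idx, name="grs"),
                    complete=pd.Series(complete, index=idx, name="complete"),
                    panel_name=panel.name)


def quartile_cutpoints(scores: pd.Series, reference_mask: pd.Series | None = None) -> np.ndarray:
    """Empirical quartile boundaries of a reference score distribution.

    `reference_mask` restricts the reference sample (typically controls);
    binning downstream is half-open, [Q_k, Q_{k+1}). Collapsed cutpoints
    (massive ties) are allowed but warned about.
    """
    ref = scores if reference_mask is None else scores[reference_mask.reindex(scores.index, fill_value=False)]
    ref = ref.dropna()
    if len(ref) < 4:
        raise ValueError(f"need at least 4 complete reference samples, got {len(ref)}")
    cuts = np.quantile(ref.to_numpy(), [0.25, 0.5, 0.75])
    if len(np.unique(cuts)) < 3:
        warnings.warn("tied scores collapse quartile cutpoints",
                      DegenerateCutpointsWarning, stacklevel=2)
    return cuts


def assign_quartiles(scores: pd.Series, cutpoints: np.ndarray) -> pd.Series:
    """Quartile index 1–4 per sample under half-open [Qk, Qk+1) binning."""
    vals = scores.to_numpy(dtype=float)
    q = np.full(vals.shape, np.nan)
    ok = ~np.isnan(vals)
    q[ok] = 1 + np.searchsorted(np.asarray(cutpoints), vals[ok], side="right")
    return pd.Series(q, index=scores.index, name="quartile")


@dataclass
class QuartileReport:
    """Per-quartile case/control counts and ORs vs the bottom quartile."""

    cutpoints: np.ndarray
    table: pd.DataFrame = field(repr=False)


def quartile_or_table(scores: ScoreSet | pd.Series, ph: pd.DataFrame,
                      cutpoints: np.ndarray, method: str = "counts") -> QuartileReport:
    """Dose-response table: odds of disease per score quartile vs bottom.

    ``method="counts"`` computes OR_k = (case_k·ctrl_1)/(ctrl_k·case_1)
    with a Woolf CI and chi-square P against the bottom quartile;
    ``method="logistic"`` fits a logistic model with the quartile as a
    categorical predictor (same point estimates — the categorical model is
    saturated — with Wald-based CI/P).
    """
    s = scores.complete_scores() if isinstance(scores, ScoreSet) else scores.dropna()
    status = pd.Series(ph["status"].values, index=ph["sample_id"].values)
    status = status.reindex(s.index)
    if status.isna().any():
        raise ValueError("every scored sample needs a phenotype row")
    quart = assign_quartiles(s, cutpoints)
    n_case_total = int((status == "case").sum())

    counts = {k: (int(((quart == k) & (status == "case")).sum()),
                  int(((quart == k) & (status == "control")).sum()))
              for k in (1, 2, 3, 4)}
    case1, ctrl1 = counts[1]
    if case1 == 0 or ctrl1 == 0:
        raise ValueError("bottom quartile must contain at least one case and one control")

    fit = None
    if method == "logistic":
        import statsmodels.api as sm

        X = pd.get_dummies(quart.astype(int).astype("category"), prefix="q",
                           drop_first=True, dtype=float)
        X = sm.add_constant(X)
        fit = sm.Logit((status == "case").astype(float), X).fit(disp=0)
    elif method != "counts":
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for k in (1, 2, 3, 4):
        case_k, ctrl_k = counts[k]
        row = {"quartile": k, "n_case": case_k,
               "pct_case": 100.0 * case_k / n_case_total if n_case_total else np.nan,
               "n_ctrl": ctrl_k}
        if k == 1:
            row.update({"or": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
        elif method == "counts":
            res = allelic_test(AlleleCounts2x2(a=case_k, b=ctrl_k, c=case1, d=ctrl1))
            row.update({"or": res.or_hat, "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1], "p": res.p})
        else:
            name = f"q_{k}"
            coef = fit.params[name]
            lo, hi = fit.conf_int().loc[name]
            row.update({"or": float(np.exp(coef)), "ci_low": float(np.exp(lo)),
                        "ci_high": float(np.exp(hi)), "p": float(fit.pvalues[name])})
        rows.append(row)
    return QuartileReport(cutpoints=np.asarray(cutpoints), table=pd.DataFrame(rows))
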
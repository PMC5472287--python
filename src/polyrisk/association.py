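"""Per-SNP case-control allelic association and QC.

The sampling unit is the allele: each SNP contributes a 2×2 table of risk
vs. other allele counts in cases and controls. The test statistic is the
uncorrected 1-df Pearson chi-square on that table (PLINK's basic allelic
test); the odds ratio gets a Woolf log-interval. Hardy-Weinberg equilibrium
is checked with the 1-df goodness-of-fit chi-square, by default in controls
only — under retrospective case-control sampling a true allelic effect makes
the pooled sample depart from HWE through the Wahlund effect, so the
combined sample is not a valid QC null (a ``combined`` option exists).
Multiple testing uses a Bonferroni gate at 0.05/m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix

PANEL_RULES = ("all", "p<0.1", "p<0.05", "bonferroni", "hla_only")

#: Default LD prune: of the two HLA-C tags only rs4406273 is ever scored.
DEFAULT_LD_DROP = ("rs10484554",)
DEFAULT_HLA_SNP = "rs4406273"


class DegenerateFrequencyError(ValueError):
    """An allele frequency of exactly 0 or 1 leaves the odds undefined."""


@dataclass(frozen=True)
class AlleleCounts2x2:
    """Allele-level 2×2 table: (a, b) case risk/other, (c, d) control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @classmethod
    def from_dosages(cls, case_dosages: np.ndarray, ctrl_dosages: np.ndarray) -> "AlleleCounts2x2":
        """Count risk/other alleles from 0/1/2 dosage vectors (NaN skipped)."""
        case = np.asarray(case_dosages, dtype=float)
        ctrl = np.asarray(ctrl_dosages, dtype=float)
        case = case[~np.isnan(case)]
        ctrl = ctrl[~np.isnan(ctrl)]
        a = int(case.sum())
        c = int(ctrl.sum())
        return cls(a=a, b=2 * case.size - a, c=c, d=2 * ctrl.size - c)


@dataclass(frozen=True)
class AllelicTestResult:
    """Odds ratio, Woolf CI and chi-square P for one allele 2×2 table."""

    or_hat: float
    ci95: tuple[float, float]
    chi2: float
    p: float
    raf_case: float
    raf_ctrl: float
    zero_cell_corrected: bool = False


def allelic_or_from_raf(p1: float, p0: float) -> float:
    """Allelic odds ratio implied by case (`p1`) and control (`p0`) RAFs.

    OR = [p1/(1−p1)] / [p0/(1−p0)].
    """
    for name, p in (("p1", p1), ("p0", p0)):
        if not 0.0 < p < 1.0:
            raise DegenerateFrequencyError(f"{name}={p} is a boundary frequency")
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


def allelic_test(counts: AlleleCounts2x2, method: str = "chi2") -> AllelicTestResult:
    """Case-control allelic association from a 2×2 allele table.

    P value from the uncorrected Pearson chi-square (``method="chi2"``,
    matching PLINK's allelic test) or Fisher's exact test
    (``method="fisher"``, for small cells). A zero cell triggers the
    Haldane–Anscombe +0.5 correction for the OR and CI (flagged); the
    chi-square itself is computed from the raw table.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if a + b == 0 or c + d == 0:
        raise ValueError("empty stratum: no non-missing alleles in cases or controls")
    n = a + b + c + d
    raf_case = a / (a + b)
    raf_ctrl = c / (c + d)

    zero_cell = min(a, b, c, d) == 0
    if zero_cell:
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    or_hat = (af * df) / (bf * cf)
    se_log = np.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    log_or = np.log(or_hat)
    ci = (float(np.exp(log_or - 1.959963984540054 * se_log)),
          float(np.exp(log_or + 1.959963984540054 * se_log)))

    # Pearson chi-square on the raw table; zero margins give chi2 = 0.
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if c1 == 0 or c2 == 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        p = float(stats.chi2.sf(chi2, df=1))
    if method == "fisher":
        p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    elif method != "chi2":
        raise ValueError(f"unknown test method {method!r}")
    return AllelicTestResult(
        or_hat=float(or_hat), ci95=ci, chi2=float(chi2), p=p,
        raf_case=raf_case, raf_ctrl=raf_ctrl, zero_cell_corrected=zero_cell,
    )


def hwe_test(geno_counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square against Hardy-Weinberg proportions.

    `geno_counts` = (risk homozygotes, heterozygotes, other homozygotes).
    Monomorphic SNPs return (0.0, 1.0) by convention.
    """
    n_rr, n_het, n_oo = geno_counts
    n = n_rr + n_het + n_oo
    if n <= 0:
        raise ValueError("no genotyped samples")
    p = (2 * n_rr + n_het) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    observed = np.array([n_rr, n_het, n_oo], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def is_monomorphic(geno_counts: tuple[int, int, int]) -> bool:
    n_rr, n_het, n_oo = geno_counts
    return n_het == 0 and (n_rr == 0 or n_oo == 0)


def bonferroni_gate(p: float, m: int) -> bool:
    """True iff p clears the Bonferroni-corrected 0.05 level (p < 0.05/m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < 0.05 / m


def select_panel(results: pd.DataFrame, rule: str,
                 ld_drop: Sequence[str] = DEFAULT_LD_DROP,
                 m: int | None = None,
                 hla_snp: str = DEFAULT_HLA_SNP) -> list[str]:
    """SNPs passing a significance rule, minus the LD-pruned ids.

    `results` needs columns ``snp_id`` and ``p``. The Bonferroni factor `m`
    defaults to the number of SNPs in `results` (all SNPs tested, before the
    LD drop). Order follows the input.
    """
    if rule not in PANEL_RULES:
        raise ValueError(f"unknown panel rule {rule!r}; choose from {PANEL_RULES}")
    snp_ids = list(results["snp_id"])
    pvals = dict(zip(results["snp_id"], results["p"]))
    dropped = set(ld_drop)
    if rule == "hla_only":
        if hla_snp not in snp_ids:
            raise ValueError(f"HLA SNP {hla_snp!r} not among results")
        return [hla_snp]
    if rule == "all":
        keep = snp_ids
    elif rule == "p<0.1":
        keep = [s for s in snp_ids if pvals[s] < 0.1]
    elif rule == "p<0.05":
        keep = [s for s in snp_ids if pvals[s] < 0.05]
    else:  # bonferroni
        m_eff = len(snp_ids) if m is None else m
        keep = [s for s in snp_ids if bonferroni_gate(pvals[s], m_eff)]
    return [s for s in keep if s not in dropped]


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(risk hom, het, other hom) counts from a dosage vector, NaN skipped."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def association_table(gm: GenotypeMatrix, ph: pd.DataFrame,
                      hwe_sample: str = "controls",
                      hwe_threshold: float = 0.05,
                      bonferroni_m: int | None = None,
                      method: str = "chi2") -> pd.DataFrame:
    """Full per-SNP association and QC table for a cohort.

    One row per SNP: allele counts, RAFs, OR with 95% CI, chi-square P,
    Bonferroni flag (factor = `bonferroni_m` or the number of SNPs tested),
    HWE P (in ``controls``, ``cases`` or ``combined``) and its deviation
    flag at `hwe_threshold`.
    """
    if hwe_sample not in ("controls", "cases", "combined"):
        raise ValueError(f"unknown hwe_sample {hwe_sample!r}")
    status = pd.Series(ph["status"].values, index=ph["sample_id"].values)
    status = status.reindex(gm.sample_ids)
    if status.isna().any():
        missing = status.index[status.isna()][0]
        raise ValueError(f"sample {missing!r} has no phenotype row")
    case_mask = (status == "case").to_numpy()
    ctrl_mask = (status == "control").to_numpy()
    dos = gm.dosages.to_numpy(dtype=float)

    m_factor = bonferroni_m if bonferroni_m is not None else len(gm.snp_ids)
    rows = []
    for j, snp_id in enumerate(gm.snp_ids):
        col = dos[:, j]
        counts = AlleleCounts2x2.from_dosages(col[case_mask], col[ctrl_mask])
        res = allelic_test(counts, method=method)
        if hwe_sample == "controls":
            hwe_col = col[ctrl_mask]
        elif hwe_sample == "cases":
            hwe_col = col[case_mask]
        else:
            hwe_col = col
        gcounts = genotype_counts(hwe_col)
        hwe_chi2, hwe_p = hwe_test(gcounts)
        rows.append({
            "snp_id": snp_id,
            "a": counts.a, "b": counts.b, "c": counts.c, "d": counts.d,
            "raf_case": res.raf_case, "raf_ctrl": res.raf_ctrl,
            "or": res.or_hat, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "chi2": res.chi2, "p": res.p,
            "p_bonf_pass": bonferroni_gate(res.p, m_factor),
            "zero_cell_corrected": res.zero_cell_corrected,
            "hwe_p": hwe_p, "hwe_deviation": hwe_p < hwe_threshold,
            "monomorphic": is_monomorphic(gcounts),
            "missing_frac": float(np.isnan(col).mean()),
        })
    return pd.DataFrame(rows)
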
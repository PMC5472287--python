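"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access to individual-level genotypes:

* controls carry Hardy-Weinberg binomial genotypes at the control
  risk-allele frequency ``p0``; cases are drawn the same way at the case
  frequency implied by the target allelic odds ratio (retrospective allelic
  sampling — the exact model under which the allelic OR is the estimand);
* SNPs are independent except one declared LD pair, drawn from a two-locus
  haplotype distribution whose D is chosen to hit the target r² (same D
  sign in both strata, |D| capped by the Lewontin bound);
* genotypes go missing completely at random at a small per-cell rate;
* clinical sub-phenotypes of cases are Bernoulli with a logistic link in
  the raw genetic risk score, the intercept solved to hit a target marginal
  prevalence.

The packaged :func:`default_cohort_spec` reproduces the bundled 38-SNP
psoriasis panel study conditions: 480 cases / 490 controls, the published
control RAFs and ORs as targets, the HLA-C LD pair at r² = 0.79 (clipped to
the per-stratum attainable bound, see note in docs), 0.1% per-cell
missingness, and the published sub-phenotype effect sizes and prevalences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import panel_data
from .cohort import GenotypeMatrix, SnpMeta, validate_phenotypes
from .association import DegenerateFrequencyError


class FeasibilityError(ValueError):
    """A requested LD target exceeds what the allele frequencies allow."""


#: Marginal prevalences of case sub-phenotypes (study defaults).
DEFAULT_PREVALENCES = {
    "nail": 0.523,
    "psa": 0.338,
    "family_history": 0.433,
    "t2ps": 0.25,
}

#: Per-unit-GRS log odds for each sub-phenotype (study defaults).
DEFAULT_SUBPHENO_EFFECTS = {
    "nail": math.log(0.92),
    "psa": math.log(0.73),
    "t2ps": math.log(0.56),
    "family_history": math.log(1.83),
}

_TRAITS = ("nail", "psa", "t2ps", "family_history")


@dataclass(frozen=True)
class SnpSimSpec:
    """Simulation target for one SNP: control RAF and allelic OR."""

    snp_id: str
    p0: float
    or_target: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise DegenerateFrequencyError(f"{self.snp_id}: p0={self.p0} must be in (0,1)")
        if self.or_target <= 0:
            raise ValueError(f"{self.snp_id}: or_target must be positive")


@dataclass(frozen=True)
class LdPairSpec:
    """Two SNPs coupled at a target squared haplotype correlation."""

    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be in [0,1]")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of one simulated case-control cohort."""

    snps: tuple[SnpSimSpec, ...]
    n_case: int = panel_data.N_CASES
    n_ctrl: int = panel_data.N_CONTROLS
    ld_pair: LdPairSpec | None = None
    missing_rate: float = 0.001
    subpheno_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBPHENO_EFFECTS))
    subpheno_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    score_snps: tuple[str, ...] | None = None
    seed: int = 0
    ld_clip: bool = False

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in spec")
        if not 0.0 <= self.missing_rate < 0.05:
            raise ValueError("missing_rate must be in [0, 0.05)")
        if self.n_case < 0 or self.n_ctrl < 0:
            raise ValueError("stratum sizes must be non-negative")
        if self.ld_pair is not None:
            for snp in (self.ld_pair.snp_a, self.ld_pair.snp_b):
                if snp not in ids:
                    raise ValueError(f"LD pair member {snp!r} not among spec SNPs")


def case_raf(p0: float, or_target: float) -> float:
    """Case risk-allele frequency implied by control RAF and allelic OR.

    p1 = OR·o0 / (1 + OR·o0) with o0 = p0/(1−p0); the allelic OR computed
    back from (p1, p0) equals `or_target` exactly.
    """
    if not 0.0 < p0 < 1.0:
        raise DegenerateFrequencyError(f"p0={p0} must be strictly inside (0,1)")
    if or_target <= 0:
        raise ValueError("or_target must be positive")
    o1 = or_target * p0 / (1.0 - p0)
    return o1 / (1.0 + o1)


def max_abs_d(pa: float, pb: float, sign: int = 1) -> float:
    """Lewontin bound on |D| for given allele frequencies and D sign."""
    qa, qb = 1.0 - pa, 1.0 - pb
    if sign >= 0:
        return min(pa * qb, qa * pb)
    return min(pa * pb, qa * qb)


def max_r2(pa: float, pb: float, sign: int = 1) -> float:
    """Largest attainable r² between two loci at the given frequencies."""
    qa, qb = 1.0 - pa, 1.0 - pb
    d = max_abs_d(pa, pb, sign)
    return d * d / (pa * qa * pb * qb)


def _haplotype_probs(pa: float, pb: float, r2: float, clip: bool) -> np.ndarray:
    """Probabilities of haplotypes (AB, Ab, aB, ab); risk alleles coupled."""
    qa, qb = 1.0 - pa, 1.0 - pb
    d_target = math.sqrt(r2) * math.sqrt(pa * qa * pb * qb)
    d_bound = max_abs_d(pa, pb, sign=1)
    if d_target > d_bound + 1e-12:
        if not clip:
            raise FeasibilityError(
                f"r²={r2:.3f} not attainable at frequencies ({pa:.3f}, {pb:.3f}); "
                f"maximum attainable r² is {max_r2(pa, pb):.3f}"
            )
        d_target = d_bound
    probs = np.array([
        pa * pb + d_target,
        pa * qb - d_target,
        qa * pb - d_target,
        qa * qb + d_target,
    ])
    return np.clip(probs, 0.0, 1.0) / probs.clip(0.0, 1.0).sum()


def _simulate_stratum(freqs: np.ndarray, n: int, ld_idx: tuple[int, int] | None,
                      ld_r2: float, ld_clip: bool, rng: np.random.Generator) -> np.ndarray:
    geno = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    if ld_idx is not None and n > 0:
        ia, ib = ld_idx
        probs = _haplotype_probs(freqs[ia], freqs[ib], ld_r2, ld_clip)
        haps = rng.multinomial(2, probs, size=n)  # counts of AB, Ab, aB, ab
        geno[:, ia] = haps[:, 0] + haps[:, 1]
        geno[:, ib] = haps[:, 0] + haps[:, 2]
    return geno


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, pd.DataFrame, list[SnpMeta]]:
    """Draw genotypes and a bare phenotype table for one cohort.

    Controls are HWE-binomial at ``p0``; cases at ``case_raf(p0, OR)``.
    SNPs are independent apart from the declared LD pair. Deterministic
    under a fixed ``spec.seed``. Sub-phenotypes are left ``unknown`` /
    ``none``; use :func:`simulate_study` or :func:`assign_subphenotypes`
    to link them to the risk score.
    """
    rng = np.random.default_rng(spec.seed)
    snp_ids = [s.snp_id for s in spec.snps]
    p0 = np.array([s.p0 for s in spec.snps])
    p1 = np.array([case_raf(s.p0, s.or_target) for s in spec.snps])
    ld_idx = None
    ld_r2 = 0.0
    if spec.ld_pair is not None:
        ld_idx = (snp_ids.index(spec.ld_pair.snp_a), snp_ids.index(spec.ld_pair.snp_b))
        ld_r2 = spec.ld_pair.r2
        # surface infeasibility before any draws, for both strata
        for freqs in (p0, p1):
            _haplotype_probs(freqs[ld_idx[0]], freqs[ld_idx[1]], ld_r2, spec.ld_clip)

    case_geno = _simulate_stratum(p1, spec.n_case, ld_idx, ld_r2, spec.ld_clip, rng)
    ctrl_geno = _simulate_stratum(p0, spec.n_ctrl, ld_idx, ld_r2, spec.ld_clip, rng)

    sample_ids = [f"case_{i + 1:04d}" for i in range(spec.n_case)] + \
                 [f"ctrl_{i + 1:04d}" for i in range(spec.n_ctrl)]
    dosages = pd.DataFrame(
        np.vstack([case_geno, ctrl_geno]) if sample_ids else
        np.empty((0, len(snp_ids))),
        index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids,
    )
    ph = validate_phenotypes(pd.DataFrame({
        "sample_id": sample_ids,
        "status": ["case"] * spec.n_case + ["control"] * spec.n_ctrl,
        "onset_class": "none",
        "nail": "unknown",
        "psa": "unknown",
        "family_history": "unknown",
    }))
    other = {"A": "G", "G": "A", "C": "T", "T": "C"}
    bundled = {m.snp_id: m for m in panel_data.reference_meta()}
    meta = [
        bundled.get(s.snp_id) or SnpMeta(snp_id=s.snp_id, risk_allele="A",
                                         other_allele=other["A"], ref_raf=s.p0,
                                         ref_or=s.or_target)
        for s in spec.snps
    ]
    return GenotypeMatrix(dosages), ph, meta


def apply_missingness(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Blank each non-missing cell independently with probability `rate`."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0,1)")
    if rate == 0.0:
        return GenotypeMatrix(gm.dosages.copy())
    rng = np.random.default_rng(seed)
    vals = gm.dosages.to_numpy(dtype=float, copy=True)
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    return GenotypeMatrix(pd.DataFrame(vals, index=gm.dosages.index,
                                       columns=gm.dosages.columns))


def _solve_intercept(scores: np.ndarray, beta: float, prevalence: float) -> float:
    """Intercept alpha with mean(expit(alpha + beta*g)) == prevalence."""
    def gap(alpha: float) -> float:
        return float(expit(alpha + beta * scores).mean() - prevalence)
    lo, hi = -60.0, 60.0
    return brentq(gap, lo, hi)


def assign_subphenotypes(ph: pd.DataFrame, scores: pd.Series,
                         effects: Mapping[str, float], seed: int,
                         prevalences: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Draw case sub-phenotypes from a logistic link in the risk score.

    For each trait t, case i is positive with probability
    ``expit(alpha_t + beta_t * score_i)``, alpha_t solved so the marginal
    prevalence among cases matches the target. ``t2ps`` positivity sets
    ``onset_class`` to T2Ps (else T1Ps); other traits map to yes/no.
    Controls are untouched.
    """
    prevalences = dict(DEFAULT_PREVALENCES) | dict(prevalences or {})
    for trait in effects:
        if trait not in _TRAITS:
            raise ValueError(f"unknown trait {trait!r}; known traits: {_TRAITS}")
    ph = validate_phenotypes(ph).copy()
    case_rows = ph.index[ph["status"] == "case"]
    case_ids = ph.loc[case_rows, "sample_id"]
    missing_scores = [sid for sid in case_ids if sid not in scores.index]
    if missing_scores:
        raise ValueError(f"scores missing for case {missing_scores[0]!r}")
    g = scores.loc[case_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    ph.loc[case_rows, "onset_class"] = "T1Ps"
    for trait, beta in effects.items():
        pi = prevalences[trait]
        alpha = _solve_intercept(g, beta, pi)
        positive = rng.random(g.size) < expit(alpha + beta * g)
        if trait == "t2ps":
            ph.loc[case_rows, "onset_class"] = np.where(positive, "T2Ps", "T1Ps")
        else:
            ph.loc[case_rows, trait] = np.where(positive, "yes", "no")
    return validate_phenotypes(ph)


def true_score(gm: GenotypeMatrix, spec: CohortSpec) -> pd.Series:
    """Generating-model risk score: Σ dosage × ln(OR target) over score SNPs.

    The score SNP set defaults to every spec SNP with OR ≠ 1 (LD-dropped
    members excluded via ``spec.score_snps`` when provided).
    """
    if spec.score_snps is not None:
        snps = [s for s in spec.snps if s.snp_id in set(spec.score_snps)]
    else:
        snps = [s for s in spec.snps if s.or_target != 1.0]
    weights = np.array([math.log(s.or_target) for s in snps])
    dos = gm.dosages[[s.snp_id for s in snps]].to_numpy(dtype=float)
    return pd.Series(dos @ weights, index=gm.dosages.index, name="true_score")


def simulate_study(spec: CohortSpec) -> tuple[GenotypeMatrix, pd.DataFrame, list[SnpMeta]]:
    """Full generator: genotypes → score-linked sub-phenotypes → missingness.

    Sub-phenotypes are assigned from the complete (pre-missingness)
    generating score so every case is covered; missingness is applied last.
    All randomness derives from ``spec.seed``.
    """
    gm, ph, meta = simulate_cohort(spec)
    if spec.subpheno_effects and spec.n_case > 0:
        scores = true_score(gm, spec)
        ph = assign_subphenotypes(ph, scores, spec.subpheno_effects,
                                  seed=spec.seed + 1,
                                  prevalences=spec.subpheno_prevalences)
    gm = apply_missingness(gm, spec.missing_rate, seed=spec.seed + 2)
    return gm, ph, meta


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The bundled 38-SNP psoriasis study conditions as a CohortSpec.

    Control RAFs and OR targets come from the packaged reference panel;
    the HLA-C pair is coupled at the published r² = 0.79 with per-stratum
    Lewontin clipping (the printed rounded frequencies cannot reach 0.79
    exactly). The generating score uses the 16 nominally associated SNPs
    minus the LD-dropped proxy.
    """
    table = panel_data.reference_table()
    snps = tuple(
        SnpSimSpec(snp_id=r.snp_id, p0=r.raf_ctrl, or_target=r.odds_ratio)
        for r in table.itertuples()
    )
    nominal = [r.snp_id for r in table.itertuples()
               if r.p < 0.05 and r.snp_id != panel_data.HLA_PROXY_SNP]
    params = dict(
        snps=snps,
        n_case=panel_data.N_CASES,
        n_ctrl=panel_data.N_CONTROLS,
        ld_pair=LdPairSpec(panel_data.HLA_SNP, panel_data.HLA_PROXY_SNP,
                           panel_data.HLA_PAIR_R2),
        ld_clip=True,
        missing_rate=0.001,
        score_snps=tuple(nominal),
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from a YAML config (CLI carrier format)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    snps = tuple(SnpSimSpec(snp_id=s["snp_id"], p0=float(s["p0"]),
                            or_target=float(s["or_target"]))
                 for s in raw["snps"])
    ld = raw.get("ld_pair")
    return CohortSpec(
        snps=snps,
        n_case=int(raw.get("n_case", panel_data.N_CASES)),
        n_ctrl=int(raw.get("n_ctrl", panel_data.N_CONTROLS)),
        ld_pair=LdPairSpec(ld["snp_a"], ld["snp_b"], float(ld["r2"])) if ld else None,
        missing_rate=float(raw.get("missing_rate", 0.001)),
        subpheno_effects={k: float(v) for k, v in raw.get("subpheno_effects",
                                                          DEFAULT_SUBPHENO_EFFECTS).items()},
        subpheno_prevalences={k: float(v) for k, v in raw.get("subpheno_prevalences",
                                                              DEFAULT_PREVALENCES).items()},
        score_snps=tuple(raw["score_snps"]) if raw.get("score_snps") else None,
        seed=int(raw.get("seed", 0)),
        ld_clip=bool(raw.get("ld_clip", False)),
    )


def spec_to_yaml(spec: CohortSpec, path) -> None:
    import yaml

    raw = {
        "snps": [{"snp_id": s.snp_id, "p0": s.p0, "or_target": s.or_target}
                 for s in spec.snps],
        "n_case": spec.n_case,
        "n_ctrl": spec.n_ctrl,
        "missing_rate": spec.missing_rate,
        "subpheno_effects": dict(spec.subpheno_effects),
        "subpheno_prevalences": dict(spec.subpheno_prevalences),
        "seed": spec.seed,
        "ld_clip": spec.ld_clip,
    }
    if spec.ld_pair is not None:
        raw["ld_pair"] = {"snp_a": spec.ld_pair.snp_a, "snp_b": spec.ld_pair.snp_b,
                          "r2": spec.ld_pair.r2}
    if spec.score_snps is not None:
        raw["score_snps"] = list(spec.score_snps)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
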
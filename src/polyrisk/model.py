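"""Study-level model object tying the pipeline together.

:class:`GrsStudy` is built from a cohort (genotypes, phenotypes, SNP
metadata); :meth:`GrsStudy.fit` runs HWE QC, per-SNP allelic association,
panel construction and scoring for the requested panel variants and returns
a :class:`GrsStudyResults` carrying the association table, the fitted
panels and scores, ROC/AUC machinery, quartile dose-response tables,
pseudo-R², sub-phenotype regressions, internal validation and a text
``summary()``.

Typical use::

    study = GrsStudy(gm, ph, meta)
    res = study.fit()
    print(res.summary())
    res.compare("N", "B")        # DeLong z-test of two panel AUCs
    res.quartiles("N").table     # dose-response odds ratios
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import association, grs, model_eval, roc
from .cohort import (GenotypeMatrix, SnpMeta, read_cohort, validate_phenotypes)

DEFAULT_VARIANTS = ("ALL", "0.1", "N", "B", "HLA", "N+HLA-", "N(subst.)")


class GrsStudy:
    """Case-control GRS analysis model for one cohort.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Risk-allele dosages, samples × SNPs.
    phenotypes : DataFrame
        Sample table (sample_id, status, onset_class, nail, psa,
        family_history).
    meta : sequence of SnpMeta
        Orientation metadata; must cover every genotyped SNP.
    hwe_threshold, hwe_sample, hwe_exclude
        HWE QC: deviating SNPs (P below threshold, tested in `hwe_sample`)
        are excluded from analysis when `hwe_exclude` is set.
    ld_drop, hla_snp
        LD pruning of scored panels and the identity of the HLA proxy SNP.
    bonferroni_m
        Multiplicity factor; defaults to the number of SNPs analysed after
        HWE exclusion.
    """

    def __init__(self, genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                 meta: Sequence[SnpMeta], *,
                 hwe_threshold: float = 0.05,
                 hwe_sample: str = "controls",
                 hwe_exclude: bool = True,
                 ld_drop: Sequence[str] = association.DEFAULT_LD_DROP,
                 hla_snp: str = association.DEFAULT_HLA_SNP,
                 bonferroni_m: int | None = None):
        self.genotypes = genotypes
        self.phenotypes = validate_phenotypes(phenotypes)
        self.meta = list(meta)
        meta_ids = {m.snp_id for m in self.meta}
        missing = [s for s in genotypes.snp_ids if s not in meta_ids]
        if missing:
            raise ValueError(f"SNP {missing[0]!r} has no metadata")
        pheno_ids = set(self.phenotypes["sample_id"])
        orphans = [s for s in genotypes.sample_ids if s not in pheno_ids]
        if orphans:
            raise ValueError(f"sample {orphans[0]!r} has no phenotype row")
        self.hwe_threshold = hwe_threshold
        self.hwe_sample = hwe_sample
        self.hwe_exclude = hwe_exclude
        self.ld_drop = tuple(ld_drop)
        self.hla_snp = hla_snp
        self.bonferroni_m = bonferroni_m

    @classmethod
    def from_cohort_dir(cls, path, fmt: str = "tsv", **kwargs) -> "GrsStudy":
        """Build a study from a cohort directory written by write_cohort."""
        gm, ph, meta = read_cohort(path, fmt=fmt)
        return cls(gm, ph, meta, **kwargs)

    def fit(self, variants: Sequence[str] = DEFAULT_VARIANTS) -> "GrsStudyResults":
        """Run QC, association and scoring; return the results object."""
        assoc_all = association.association_table(
            self.genotypes, self.phenotypes, hwe_sample=self.hwe_sample,
            hwe_threshold=self.hwe_threshold, bonferroni_m=self.bonferroni_m)
        if self.hwe_exclude:
            excluded = list(assoc_all.loc[assoc_all["hwe_deviation"], "snp_id"])
        else:
            excluded = []
        kept = [s for s in self.genotypes.snp_ids if s not in set(excluded)]
        gm = self.genotypes.subset(snp_ids=kept) if excluded else self.genotypes
        m = self.bonferroni_m if self.bonferroni_m is not None else len(kept)
        assoc = association.association_table(
            gm, self.phenotypes, hwe_sample=self.hwe_sample,
            hwe_threshold=self.hwe_threshold, bonferroni_m=m)

        status = pd.Series(self.phenotypes["status"].values,
                           index=self.phenotypes["sample_id"].values)
        panels: dict[str, grs.GrsPanel] = {}
        scores: dict[str, grs.ScoreSet] = {}
        for variant in variants:
            try:
                panel = grs.build_panel(assoc, variant, ld_drop=self.ld_drop,
                                        hla_snp=self.hla_snp, m=m)
            except ValueError as exc:
                if "needs SNP" in str(exc) or "not among results" in str(exc):
                    continue  # variant unavailable in this cohort (e.g. HLA SNP HWE-excluded)
                raise
            if not panel.snp_ids:
                continue
            panels[variant] = panel
            scores[variant] = grs.score(gm, panel)
        return GrsStudyResults(
            study=self, genotypes_qc=gm, association=assoc,
            excluded_snps=excluded, bonferroni_m=m, panels=panels,
            scores=scores, status=status.reindex(gm.sample_ids),
        )


@dataclass
class GrsStudyResults:
    """Fitted GRS study: association table, panels, scores, evaluation."""

    study: GrsStudy
    genotypes_qc: GenotypeMatrix = field(repr=False)
    association: pd.DataFrame = field(repr=False)
    excluded_snps: list[str]
    bonferroni_m: int
    panels: dict[str, grs.GrsPanel] = field(repr=False)
    scores: dict[str, grs.ScoreSet] = field(repr=False)
    status: pd.Series = field(repr=False)

    def _case_ctrl(self, variant: str) -> tuple[np.ndarray, np.ndarray]:
        sc = self._scores(variant).complete_scores()
        lab = (self.status.loc[sc.index] == "case").to_numpy()
        return sc.to_numpy()[lab], sc.to_numpy()[~lab]

    def _scores(self, variant: str) -> grs.ScoreSet:
        if variant not in self.scores:
            raise KeyError(f"variant {variant!r} was not fitted; have {sorted(self.scores)}")
        return self.scores[variant]

    def roc(self, variant: str) -> roc.RocResult:
        case, ctrl = self._case_ctrl(variant)
        return roc.auc(case, ctrl)

    def auc(self, variant: str) -> float:
        return self.roc(variant).auc

    def compare(self, variant_a: str, variant_b: str) -> roc.AucComparison:
        """Paired DeLong z-test between two panel AUCs.

        Samples incomplete on either panel are dropped from both sides so
        the pairing is valid.
        """
        sa = self._scores(variant_a)
        sb = self._scores(variant_b)
        both = sa.complete & sb.complete
        ids = both.index[both]
        labels = (self.status.loc[ids] == "case").to_numpy()
        return roc.compare_auc(sa.scores.loc[ids].to_numpy(),
                               sb.scores.loc[ids].to_numpy(),
                               labels=labels, paired=True)

    def quartiles(self, variant: str = "N", reference: str = "controls",
                  method: str = "counts") -> grs.QuartileReport:
        """Dose-response odds ratios across score quartiles."""
        ss = self._scores(variant)
        if reference == "controls":
            mask = (self.status == "control") & ss.complete
        elif reference == "combined":
            mask = ss.complete
        else:
            raise ValueError(f"unknown quartile reference {reference!r}")
        cuts = grs.quartile_cutpoints(ss.scores, reference_mask=mask)
        return grs.quartile_or_table(ss, self.study.phenotypes, cuts, method=method)

    def logistic_fit(self, variant: str = "N") -> model_eval.LogisticFit:
        """Case status regressed on the (raw) GRS."""
        sc = self._scores(variant).complete_scores()
        y = (self.status.loc[sc.index] == "case").astype(float).to_numpy()
        return model_eval.fit_logistic(sc.rename("grs"), y)

    def variance_explained(self, variant: str = "N",
                           method: str = "nagelkerke") -> float:
        return model_eval.variance_explained(self.logistic_fit(variant), method=method)

    def subphenotype(self, variant: str = "N", trait: str = "family_history",
                     standardize: bool = False) -> model_eval.SubphenotypeResult:
        return model_eval.subphenotype_association(
            self._scores(variant), self.study.phenotypes, trait,
            standardize=standardize)

    def validate(self, variant: str = "N", seed: int = 0,
                 train_frac: float = 0.75) -> model_eval.ValidationReport:
        return model_eval.internal_validation(
            self.genotypes_qc, self.study.phenotypes, self.study.meta,
            variant, seed=seed, train_frac=train_frac,
            bonferroni_m=self.study.bonferroni_m,
            ld_drop=self.study.ld_drop, hwe_sample=self.study.hwe_sample)

    def summary(self) -> str:
        """Human-readable overview of the fitted study."""
        n_case = int((self.status == "case").sum())
        n_ctrl = int((self.status == "control").sum())
        lines = [
            "Case-control GRS study",
            "=" * 58,
            f"samples: {n_case} cases / {n_ctrl} controls",
            f"SNPs analysed: {len(self.genotypes_qc.snp_ids)}"
            + (f" (HWE-excluded: {', '.join(self.excluded_snps)})" if self.excluded_snps else ""),
            f"Bonferroni factor m = {self.bonferroni_m} (gate p < {0.05 / self.bonferroni_m:.2e})",
            "",
            f"{'panel':<10}{'SNPs':>6}{'AUC':>9}{'SE':>9}{'excl.':>7}",
            "-" * 41,
        ]
        for variant, panel in self.panels.items():
            r = self.roc(variant)
            lines.append(
                f"{variant:<10}{len(panel.snp_ids):>6}{r.auc:>9.3f}"
                f"{r.se_auc:>9.3f}{self._scores(variant).n_excluded:>7}"
            )
        top = self.association.nsmallest(5, "p")
        lines += ["", "strongest associations:",
                  f"{'snp':<12}{'OR':>7}{'95% CI':>17}{'P':>12}"]
        for _, row in top.iterrows():
            lines.append(
                f"{row['snp_id']:<12}{row['or']:>7.2f}"
                f"{'(' + format(row['ci_low'], '.2f') + '-' + format(row['ci_high'], '.2f') + ')':>17}"
                f"{row['p']:>12.2e}"
            )
        return "\n".join(lines)
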
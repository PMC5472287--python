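import numpy as np
import pandas as pd
import pytest

import polyrisk as pr
from polyrisk import panel_data
from polyrisk.simulate import CohortSpec, SnpSimSpec


@pytest.fixture(scope="session")
def reference_table() -> pd.DataFrame:
    """Published 38-SNP summary statistics bundled with the package."""
    return panel_data.reference_table()


@pytest.fixture(scope="session")
def nominal_spec() -> CohortSpec:
    """Simulation spec for the 16 nominally associated panel SNPs."""
    t = panel_data.reference_table()
    rows = [r for r in t.itertuples()
            if r.p < 0.05 and r.snp_id != panel_data.HLA_PROXY_SNP]
    snps = tuple(SnpSimSpec(r.snp_id, r.raf_ctrl, r.odds_ratio) for r in rows)
    return CohortSpec(snps=snps, seed=11, score_snps=tuple(s.snp_id for s in snps))


@pytest.fixture(scope="session")
def sim_study():
    """One full default-spec cohort with a fitted study (session-cached)."""
    spec = pr.default_cohort_spec(seed=7)
    gm, ph, meta = pr.simulate_study(spec)
    study = pr.GrsStudy(gm, ph, meta)
    return spec, gm, ph, meta, study.fit()


def random_cohort(seed: int, n_samples: int = 12, n_snps: int = 4):
    """Small random cohort (matrix, phenotypes, meta) for round-trip tests."""
    rng = np.random.default_rng(seed)
    snp_ids = [f"rs{100 + i}" for i in range(n_snps)]
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    vals = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    vals[rng.random(vals.shape) < 0.1] = np.nan
    gm = pr.GenotypeMatrix(pd.DataFrame(vals, index=pd.Index(sample_ids, name="sample_id"),
                                        columns=snp_ids))
    status = rng.choice(["case", "control"], size=n_samples)
    ph = pd.DataFrame({
        "sample_id": sample_ids,
        "status": status,
        "onset_class": np.where(status == "case",
                                rng.choice(["T1Ps", "T2Ps"], size=n_samples), "none"),
        "nail": np.where(status == "case",
                         rng.choice(["yes", "no", "unknown"], size=n_samples), "unknown"),
        "psa": "unknown",
        "family_history": "unknown",
    })
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    meta = [pr.SnpMeta(snp_id=s, chrom_band=f"{i + 1}q21", gene_label=f"GENE{i}",
                       risk_allele=alleles[i % 4][0], other_allele=alleles[i % 4][1])
            for i, s in enumerate(snp_ids)]
    return gm, ph, meta
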
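"""Bundled 38-SNP psoriasis replication panel.

Literature-reported psoriasis susceptibility SNPs with their control-group
risk-allele frequencies, allelic odds ratios and association P values from a
published Polish case-control replication study (480 cases / 490 controls).
These numbers serve two purposes: they are the default simulation targets of
:mod:`polyrisk.simulate`, and they are the worked-example inputs used by the
documentation and the acceptance checks (panel membership rules, allelic-OR
arithmetic) that operate on published summary statistics alone.

The two HLA-C SNPs (rs4406273, a near-perfect proxy for HLA-C*06:02, and
rs10484554) are in strong linkage disequilibrium; by convention only
rs4406273 enters any scored panel.
"""

from __future__ import annotations

import pandas as pd

from .cohort import SnpMeta

# (snp_id, chrom_band, gene, risk_allele, raf_ctrl, raf_case, allelic OR, P)
_PANEL_ROWS = [
    ("rs7552167", "1p36.11", "IL28RA", "G", 0.833, 0.871, 1.36, 0.017),
    ("rs7530511", "1p31.3", "IL23R", "C", 0.851, 0.866, 1.13, 0.37),
    ("rs11209026", "1p31.3", "IL23R", "G", 0.960, 0.979, 1.98, 0.013),
    ("rs2476601", "1p13.2", "PTPN22", "G", 0.859, 0.869, 1.10, 0.46),
    ("rs4112788", "1q21.3", "LCE3C-LCE3B", "C", 0.627, 0.667, 1.19, 0.07),
    ("rs6701216", "1q21.3", "LCE1C", "T", 0.147, 0.168, 1.18, 0.20),
    ("rs702873", "2p13-p12", "REL", "G", 0.557, 0.642, 1.42, 2.5e-4),
    ("rs10865331", "2p15", "B3GNT2", "A", 0.400, 0.467, 1.32, 2.5e-3),
    ("rs17716942", "2q24", "IFIH1", "T", 0.893, 0.898, 1.07, 0.68),
    ("rs30187", "5q15", "ERAP1", "T", 0.313, 0.344, 1.15, 0.14),
    ("rs20541", "5q31.1", "IL13", "C", 0.739, 0.782, 1.27, 0.026),
    ("rs1024995", "5q33.1", "TNIP1", "C", 0.137, 0.166, 1.26, 0.07),
    ("rs3212227", "5q33.3", "IL12B", "A", 0.774, 0.853, 1.69, 1.2e-5),
    ("rs6887695", "5q33.3", "IL12B", "G", 0.697, 0.760, 1.38, 2.1e-3),
    ("rs2431697", "5q33.3", "PTTG1", "C", 0.396, 0.430, 1.15, 0.13),
    ("rs6908425", "6p22.3", "CDKAL1", "C", 0.775, 0.811, 1.24, 0.051),
    ("rs1150735", "6p21.3", "RNF39", "T", 0.344, 0.367, 1.10, 0.31),
    ("rs1264569", "6p21.3", "TRIM39/RPP21", "A", 0.794, 0.871, 1.75, 1.1e-5),
    ("rs879882", "6p21.31", "POU5F1", "C", 0.615, 0.723, 1.63, 3.4e-7),
    ("rs4406273", "6p21.33", "HLA-C", "A", 0.112, 0.335, 3.98, 4.6e-33),
    ("rs10484554", "6p21.33", "HLA-C", "T", 0.222, 0.444, 2.80, 5e-26),
    ("rs13437088", "6p21.33", "MICA", "T", 0.303, 0.404, 1.57, 3.3e-6),
    ("rs240993", "6q21", "TRAF3IP2", "T", 0.296, 0.319, 1.11, 0.28),
    ("rs610604", "6p23.3", "TNFAIP3", "C", 0.305, 0.325, 1.09, 0.37),
    ("rs7007032", "8p23.2", "CSMD1", "T", 0.690, 0.691, 1.00, 0.99),
    ("rs12580100", "12q13", "RPS26", "A", 0.839, 0.856, 1.14, 0.31),
    ("rs3751385", "13q11-q12", "GJB2", "C", 0.833, 0.843, 1.07, 0.57),
    ("rs7993214", "13q13.3", "COG6", "C", 0.622, 0.628, 1.03, 0.79),
    ("rs8016947", "14q13", "NFKBIA", "G", 0.531, 0.591, 1.27, 7.5e-3),
    ("rs4780355", "16p13.13", "SOCS1", "T", 0.668, 0.680, 1.06, 0.58),
    ("rs12445568", "16p11.2", "FBXL19", "C", 0.406, 0.427, 1.09, 0.35),
    ("rs4795067", "17q11.2", "NOS2", "G", 0.347, 0.392, 1.21, 0.049),
    ("rs744166", "17q21.31", "STAT3", "C", 0.370, 0.371, 1.00, 0.97),
    ("rs12720356", "19p13.2", "TYK2", "T", 0.929, 0.951, 1.49, 0.042),
    ("rs892085", "19p13.2", "IL3/CARM1", "T", 0.602, 0.634, 1.15, 0.15),
    ("rs9304742", "19q13.41", "ZNF816", "C", 0.320, 0.339, 1.09, 0.36),
    ("rs1008953", "20q12", "SDC4", "G", 0.745, 0.798, 1.35, 5.9e-3),
    ("rs2235617", "20q13.13", "RNF114", "G", 0.522, 0.568, 1.20, 0.045),
]

#: SNP kept when the HLA-C LD pair is pruned (proxy for HLA-C*06:02).
HLA_SNP = "rs4406273"
#: HLA-C tag SNP dropped from scored panels because of LD with HLA_SNP.
HLA_PROXY_SNP = "rs10484554"
#: Published squared correlation between the two HLA-C tags.
HLA_PAIR_R2 = 0.79

#: Study stratum sizes.
N_CASES = 480
N_CONTROLS = 490

# other_allele is not part of the published summary table; a transition
# partner is assigned so ped/map round-trips have a concrete second allele.
_OTHER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def reference_table() -> pd.DataFrame:
    """Published summary statistics as a DataFrame.

    Columns: snp_id, chrom_band, gene, risk_allele, raf_ctrl, raf_case,
    odds_ratio, p.
    """
    return pd.DataFrame(
        _PANEL_ROWS,
        columns=[
            "snp_id", "chrom_band", "gene", "risk_allele",
            "raf_ctrl", "raf_case", "odds_ratio", "p",
        ],
    )


def reference_meta() -> list[SnpMeta]:
    """The bundled panel as :class:`~polyrisk.cohort.SnpMeta` records."""
    return [
        SnpMeta(
            snp_id=r[0], chrom_band=r[1], gene_label=r[2],
            risk_allele=r[3], other_allele=_OTHER[r[3]],
            ref_or=r[6], ref_raf=r[4],
        )
        for r in _PANEL_ROWS
    ]
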
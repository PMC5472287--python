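"""Cohort data model and file I/O.

A cohort consists of three pieces:

* a :class:`GenotypeMatrix` — samples × SNPs risk-allele dosages in
  {0, 1, 2} with NaN for missing genotypes;
* a phenotype table — one row per sample with case/control status and the
  clinical sub-phenotypes (onset class, nail involvement, psoriatic
  arthritis, family history);
* per-SNP metadata (:class:`SnpMeta`) fixing the risk-allele orientation.

Two on-disk formats are supported: a plain tab-separated dosage matrix
(header = SNP ids, first column = sample id, missing = ``NA``) and
PLINK-style ped/map text files (allele pairs, ``0`` = missing allele).
Chromosomal coordinates are not used anywhere; ``chrom_band`` is a display
label only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_VALID_ALLELES = frozenset("ACGT")

STATUS_VALUES = ("case", "control")
ONSET_VALUES = ("T1Ps", "T2Ps", "none")
YNU_VALUES = ("yes", "no", "unknown")

PHENOTYPE_COLUMNS = (
    "sample_id", "status", "onset_class", "nail", "psa", "family_history",
)


class ParseError(ValueError):
    """A cohort file does not conform to the declared dialect."""


@dataclass(frozen=True)
class SnpMeta:
    """Identity and orientation of one biallelic SNP.

    ``risk_allele`` defines the dosage orientation: dosage counts copies of
    this allele. ``ref_or``/``ref_raf`` optionally carry a literature odds
    ratio and control risk-allele frequency.
    """

    snp_id: str
    chrom_band: str = ""
    gene_label: str = ""
    risk_allele: str = "A"
    other_allele: str = "G"
    ref_or: float | None = None
    ref_raf: float | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_ALLELES:
            raise ParseError(f"{self.snp_id}: risk allele {self.risk_allele!r} not in A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            raise ParseError(f"{self.snp_id}: other allele {self.other_allele!r} not in A/C/G/T")
        if self.risk_allele == self.other_allele:
            raise ParseError(f"{self.snp_id}: risk and other allele are both {self.risk_allele!r}")
        if self.ref_raf is not None and not 0.0 <= self.ref_raf <= 1.0:
            raise ValueError(f"{self.snp_id}: ref_raf {self.ref_raf} outside [0,1]")
        if self.ref_or is not None and self.ref_or <= 0:
            raise ValueError(f"{self.snp_id}: ref_or must be positive")


@dataclass
class GenotypeMatrix:
    """Samples × SNPs additive risk-allele dosages.

    ``dosages`` is a float DataFrame indexed by sample id with SNP-id
    columns; cells are 0/1/2 or NaN (missing genotype).
    """

    dosages: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.dosages
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ParseError(f"duplicate SNP id {dup!r}")
        vals = df.to_numpy(dtype=float, copy=False)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ParseError(
                f"invalid dosage {vals[i, j]!r} at sample {df.index[i]!r}, SNP {df.columns[j]!r}"
            )
        self.dosages = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosages)

    def missingness(self) -> pd.Series:
        """Per-SNP fraction of missing genotypes."""
        if self.n_samples == 0:
            return pd.Series(0.0, index=self.dosages.columns)
        return self.dosages.isna().mean(axis=0)

    def subset(self, sample_ids: Sequence[str] | None = None,
               snp_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        df = self.dosages
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        if snp_ids is not None:
            df = df[list(snp_ids)]
        return GenotypeMatrix(df.copy())

    def flip_orientation(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        """Swap risk/other orientation for the given SNPs (d → 2 − d)."""
        df = self.dosages.copy()
        for snp in snp_ids:
            df[snp] = 2.0 - df[snp]
        return GenotypeMatrix(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        a, b = self.dosages, other.dosages
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)
        )


def validate_phenotypes(ph: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table against the cohort contract.

    Controls must have onset_class ``none``; categorical columns must use
    the canonical vocabularies. Returns the (column-ordered) table.
    """
    missing_cols = set(PHENOTYPE_COLUMNS) - set(ph.columns)
    if missing_cols:
        raise ParseError(f"phenotype table missing columns {sorted(missing_cols)}")
    ph = ph[list(PHENOTYPE_COLUMNS)].copy()
    if ph["sample_id"].duplicated().any():
        dup = ph.loc[ph["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample id {dup!r} in phenotype table")
    checks = {
        "status": STATUS_VALUES,
        "onset_class": ONSET_VALUES,
        "nail": YNU_VALUES,
        "psa": YNU_VALUES,
        "family_history": YNU_VALUES,
    }
    for col, allowed in checks.items():
        bad = ~ph[col].isin(allowed)
        if bad.any():
            raise ParseError(f"phenotype column {col!r}: invalid value {ph.loc[bad, col].iloc[0]!r}")
    ctrl_bad = (ph["status"] == "control") & (ph["onset_class"] != "none")
    if ctrl_bad.any():
        raise ParseError("controls must have onset_class 'none'")
    return ph


# ---------------------------------------------------------------------------
# TSV dosage format
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated dosage matrix (header = SNP ids, NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return GenotypeMatrix(df)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.dosages.copy()
    # integer rendering keeps output byte-stable and diff-friendly
    out = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PLINK-style ped/map
# ---------------------------------------------------------------------------

def _band_to_chrom(band: str) -> str:
    digits = ""
    for ch in band:
        if ch.isdigit():
            digits += ch
        else:
            break
    return digits or "0"


def read_pedmap(ped_path: str | Path, map_path: str | Path,
                meta: Sequence[SnpMeta]) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read genotypes (and case/control status) from ped/map text files.

    The map file fixes SNP order; `meta` fixes the risk-allele orientation.
    Allele code ``0`` means missing; an allele matching neither risk nor
    other allele renders the genotype missing. Returns the matrix and a
    minimal phenotype table built from the ped status column (2 = case,
    1 = control, anything else = control).
    """
    meta_by_id = {m.snp_id: m for m in meta}
    snp_order: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{map_path}:{lineno}: expected >=2 columns")
            snp_id = parts[1]
            if snp_id in snp_order:
                raise ParseError(f"{map_path}:{lineno}: duplicate SNP id {snp_id!r}")
            if snp_id not in meta_by_id:
                raise ParseError(f"{map_path}:{lineno}: SNP {snp_id!r} has no metadata")
            snp_order.append(snp_id)

    rows: list[list[float]] = []
    sample_ids: list[str] = []
    statuses: list[str] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_order):
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snp_order)} fields, got {len(parts)}"
                )
            sid = parts[1]
            if sid in sample_ids:
                raise ParseError(f"{ped_path}:{lineno}: duplicate sample id {sid!r}")
            sample_ids.append(sid)
            statuses.append("case" if parts[5] == "2" else "control")
            dosages: list[float] = []
            for k, snp_id in enumerate(snp_order):
                a1, a2 = parts[6 + 2 * k], parts[7 + 2 * k]
                m = meta_by_id[snp_id]
                d = 0.0
                ok = True
                for allele in (a1, a2):
                    if allele == "0":
                        ok = False
                    elif allele == m.risk_allele:
                        d += 1.0
                    elif allele == m.other_allele:
                        pass
                    elif allele in _VALID_ALLELES:
                        ok = False  # inconsistent with declared alleles
                    else:
                        raise ParseError(
                            f"{ped_path}:{lineno}: allele {allele!r} not in A/C/G/T or 0"
                        )
                dosages.append(d if ok else np.nan)
            rows.append(dosages)

    df = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                      columns=snp_order, dtype=float)
    ph = pd.DataFrame({
        "sample_id": sample_ids,
        "status": statuses,
        "onset_class": "none",
        "nail": "unknown",
        "psa": "unknown",
        "family_history": "unknown",
    })
    return GenotypeMatrix(df), validate_phenotypes(ph)


def write_pedmap(gm: GenotypeMatrix, ph: pd.DataFrame, meta: Sequence[SnpMeta],
                 ped_path: str | Path, map_path: str | Path) -> None:
    meta_by_id = {m.snp_id: m for m in meta}
    status = dict(zip(ph["sample_id"], ph["status"]))
    with open(map_path, "w") as fh:
        for pos, snp_id in enumerate(gm.snp_ids, 1):
            m = meta_by_id[snp_id]
            fh.write(f"{_band_to_chrom(m.chrom_band)}\t{snp_id}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for sid, row in gm.dosages.iterrows():
            code = "2" if status.get(sid) == "case" else "1"
            fields = [str(sid), str(sid), "0", "0", "0", code]
            for snp_id in gm.snp_ids:
                m = meta_by_id[snp_id]
                d = row[snp_id]
                if pd.isna(d):
                    fields += ["0", "0"]
                else:
                    d = int(d)
                    fields += [m.risk_allele] * d + [m.other_allele] * (2 - d)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# SNP metadata / phenotype tables, cohort-level round trip
# ---------------------------------------------------------------------------

_META_COLUMNS = ("snp_id", "chrom_band", "gene_label", "risk_allele",
                 "other_allele", "ref_or", "ref_raf")


def read_snp_meta(path: str | Path) -> list[SnpMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    metas = []
    for _, r in df.iterrows():
        metas.append(SnpMeta(
            snp_id=str(r["snp_id"]),
            chrom_band=str(r.get("chrom_band", "")) if pd.notna(r.get("chrom_band", "")) else "",
            gene_label=str(r.get("gene_label", "")) if pd.notna(r.get("gene_label", "")) else "",
            risk_allele=str(r["risk_allele"]),
            other_allele=str(r["other_allele"]),
            ref_or=None if pd.isna(r.get("ref_or", np.nan)) else float(r["ref_or"]),
            ref_raf=None if pd.isna(r.get("ref_raf", np.nan)) else float(r["ref_raf"]),
        ))
    ids = [m.snp_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate SNP ids in metadata")
    return metas


def write_snp_meta(meta: Sequence[SnpMeta], path: str | Path) -> None:
    rows = [(m.snp_id, m.chrom_band, m.gene_label, m.risk_allele, m.other_allele,
             "" if m.ref_or is None else repr(m.ref_or),
             "" if m.ref_raf is None else repr(m.ref_raf)) for m in meta]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t", dtype=str))


def write_phenotypes(ph: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(ph).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, fmt: str = "tsv",
                   meta: Sequence[SnpMeta] | None = None,
                   map_path: str | Path | None = None):
    """Dispatching reader for the supported genotype formats.

    ``fmt="tsv"`` reads an already-oriented dosage matrix; ``fmt="pedmap"``
    needs the map file and SNP metadata to orient alleles. Returns a
    :class:`GenotypeMatrix` for tsv, or (matrix, phenotype table) for pedmap.
    """
    if fmt == "tsv":
        return read_genotype_tsv(path)
    if fmt == "pedmap":
        if meta is None or map_path is None:
            raise ValueError("pedmap format requires meta and map_path")
        return read_pedmap(path, map_path, meta)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_cohort(gm: GenotypeMatrix, ph: pd.DataFrame, meta: Sequence[SnpMeta],
                 out_dir: str | Path, fmt: str = "tsv") -> dict[str, Path]:
    """Write a full cohort to a directory; returns the written paths.

    Round-trip safe for both formats: ``read_cohort(write_cohort(x)) == x``
    including missing cells (ped/map loses sub-phenotype columns, which live
    in the separate phenotype file in either format).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph = validate_phenotypes(ph)
    if list(ph["sample_id"]) != gm.sample_ids:
        raise ValueError("phenotype rows must match genotype samples (same ids, same order)")
    paths = {
        "meta": out / "snps.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    write_snp_meta(meta, paths["meta"])
    write_phenotypes(ph, paths["phenotypes"])
    if fmt == "tsv":
        paths["genotypes"] = out / "genotypes.tsv"
        write_genotype_tsv(gm, paths["genotypes"])
    elif fmt == "pedmap":
        paths["ped"] = out / "cohort.ped"
        paths["map"] = out / "cohort.map"
        write_pedmap(gm, ph, meta, paths["ped"], paths["map"])
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    return paths


def read_cohort(in_dir: str | Path, fmt: str = "tsv"):
    """Read back a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    meta = read_snp_meta(src / "snps.tsv")
    ph = read_phenotypes(src / "phenotypes.tsv")
    if fmt == "tsv":
        gm = read_genotype_tsv(src / "genotypes.tsv")
    elif fmt == "pedmap":
        gm, _ = read_pedmap(src / "cohort.ped", src / "cohort.map", meta)
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    return gm, ph, meta
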
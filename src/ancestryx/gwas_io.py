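"""Genotype, sample-sheet, and genomic-region I/O.

The central container is :class:`GenotypeDataset`: an N x M additive dosage
matrix (alt/counted-allele counts in {0, 1, 2}, NaN for missing) together
with the per-sample phenotype, collection-of-origin label, and adjustment
covariates. Dosage tables are read and written in a PLINK ``.raw``-style
whitespace-delimited dialect; genotypes can also be imported from VCF
(biallelic SNVs only). Sample metadata travels in a separate TSV sample
sheet with columns ``sample_id``, ``phenotype``, ``collection`` plus any
number of covariate columns.

I/O is lossless: missing dosages are stored as NaN and written as the
literal ``NA`` token, never imputed here. Long-range-LD exclusion regions
are plain BED (0-based, half-open); marker positions are 1-based, and the
coordinate conversion happens inside the region-query methods.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ancestryx")

#: columns of the PLINK .raw preamble, in order
_RAW_PREAMBLE = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class SampleMismatchError(ValueError):
    """Genotype file and sample sheet do not describe the same samples."""


class BedParseError(ValueError):
    """Malformed BED line (reports the 1-based line number)."""


@dataclass
class GenotypeDataset:
    """Samples x markers additive dosages plus per-sample metadata.

    Attributes
    ----------
    dosages : (N, M) float array
        Counted-allele dosage in {0, 1, 2}; NaN marks a missing genotype.
    sample_ids, marker_ids : str arrays
    marker_chrom : (M,) str array
        Chromosome per marker, without any ``chr`` prefix.
    marker_pos : (M,) int array
        1-based physical position per marker.
    counted_allele : (M,) str array
        Allele whose copies the dosage counts (ALT for VCF input).
    y : (N,) float array
        Phenotype: binary 0/1 for case-control, real for quantitative.
    collection : (N,) str array
        Cohort-of-origin label fixed by study design.
    W : (N, q) float array
        Main-effect adjustment covariates (q >= 0).
    covariate_names : list of str
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    y: np.ndarray
    collection: np.ndarray
    W: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    counted_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, m = self.dosages.shape
        if n < 2:
            raise ValueError("a dataset needs at least 2 samples")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must lie in {0, 1, 2} or be missing (NaN)")
        for name, arr, length in (
            ("sample_ids", self.sample_ids, n),
            ("y", self.y, n),
            ("collection", self.collection, n),
            ("marker_ids", self.marker_ids, m),
            ("marker_chrom", self.marker_chrom, m),
            ("marker_pos", self.marker_pos, m),
        ):
            if len(arr) != length:
                raise ValueError(f"{name} has length {len(arr)}, expected {length}")
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.marker_ids = np.asarray(self.marker_ids, dtype=str)
        self.marker_chrom = np.asarray(self.marker_chrom, dtype=str)
        self.marker_pos = np.asarray(self.marker_pos, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.collection = np.asarray(self.collection, dtype=str)
        self.W = np.asarray(self.W, dtype=np.float64).reshape(n, -1)
        if self.W.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names must match W columns")
        if self.counted_allele is None:
            self.counted_allele = np.full(m, "A", dtype=object)
        self.counted_allele = np.asarray(self.counted_allele, dtype=str)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_binary(self) -> bool:
        finite = self.y[np.isfinite(self.y)]
        return bool(np.isin(finite, (0.0, 1.0)).all())

    def validate_case_control(self) -> None:
        """Raise if the phenotype is not binary with both classes present."""
        if not self.is_binary:
            raise ValueError("phenotype is not coded 0/1")
        if len(np.unique(self.y[np.isfinite(self.y)])) < 2:
            raise ValueError("case-control mode needs both phenotype classes")

    def subset_markers(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            marker_ids=self.marker_ids[idx],
            marker_chrom=self.marker_chrom[idx],
            marker_pos=self.marker_pos[idx],
            counted_allele=self.counted_allele[idx],
        )

    def __eq__(self, other) -> bool:  # value equality, NaN == NaN for dosages
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.dosages.shape == other.dosages.shape
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.marker_ids, other.marker_ids)
            and np.array_equal(self.marker_chrom, other.marker_chrom)
            and np.array_equal(self.marker_pos, other.marker_pos)
            and np.array_equal(self.counted_allele, other.counted_allele)
            and np.allclose(self.y, other.y, equal_nan=True)
            and np.array_equal(self.collection, other.collection)
            and self.covariate_names == other.covariate_names
            and np.allclose(self.W, other.W, equal_nan=True)
        )


@dataclass
class RegionList:
    """Ordered list of (chrom, start, end) half-open 0-based intervals."""

    records: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.records:
            if start < 0 or start >= end:
                raise ValueError(f"invalid region {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.records)

    def contains(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Boolean mask: does each 1-based marker position fall in any region?

        Overlapping regions are handled via their union. A BED interval
        [start, end) covers 1-based positions start+1 .. end.
        """
        chrom = np.asarray([_norm_chrom(c) for c in np.asarray(chrom, dtype=str)])
        pos = np.asarray(pos_1based, dtype=np.int64)
        hit = np.zeros(pos.shape, dtype=bool)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.records:
            by_chrom.setdefault(_norm_chrom(c), []).append((s, e))
        for c, ivals in by_chrom.items():
            merged = _merge_intervals(ivals)
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            sel = chrom == c
            if not sel.any():
                continue
            # interval index whose start is the rightmost <= pos-1
            j = np.searchsorted(starts, pos[sel] - 1, side="right") - 1
            ok = j >= 0
            inside = np.zeros(sel.sum(), dtype=bool)
            inside[ok] = pos[sel][ok] - 1 < ends[j[ok]]
            hit[sel] = inside
        return hit


def _norm_chrom(c: str) -> str:
    return c[3:] if c.lower().startswith("chr") else c


def _merge_intervals(ivals):
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "collection": str})
    required = {"sample_id", "phenotype", "collection"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    return sheet


def _check_sample_match(geno_ids, sheet_ids) -> None:
    geno, sheet = set(geno_ids), set(sheet_ids)
    if geno != sheet:
        only_g = sorted(geno - sheet)
        only_s = sorted(sheet - geno)
        raise SampleMismatchError(
            "genotype file and sample sheet disagree: "
            f"{len(only_g)} only in genotypes {only_g[:10]}, "
            f"{len(only_s)} only in sample sheet {only_s[:10]}"
        )


# ---------------------------------------------------------------------------
# .raw dialect

def _marker_token(mid: str, chrom: str, pos: int, allele: str) -> str:
    return f"{chrom}:{pos}:{mid}_{allele}"


def _parse_marker_token(tok: str):
    """Split a ``chrom:pos:id_ALLELE`` (or plain ``id_ALLELE``) header token."""
    stem, _, allele = tok.rpartition("_")
    if not stem:
        stem, allele = tok, "A"
    parts = stem.split(":")
    if len(parts) >= 3 and parts[1].isdigit():
        return ":".join(parts[2:]), _norm_chrom(parts[0]), int(parts[1]), allele
    return stem, "0", -1, allele


def read_dataset(genotype_path, samples_path, format: str = "raw") -> GenotypeDataset:
    """Read a dataset from a dosage table (or VCF) plus a TSV sample sheet.

    Sample order follows the genotype file; the sheet is aligned to it. The
    two sample sets must be identical (an error lists any asymmetric
    difference). Missing dosages are preserved as NaN.
    """
    if format not in ("raw", "vcf"):
        raise ValueError(f"unknown format {format!r}")
    sheet = read_sample_sheet(samples_path)
    if format == "raw":
        tab = pd.read_csv(genotype_path, sep=r"\s+", na_values=["NA"], dtype={"IID": str})
        marker_cols = [c for c in tab.columns if c not in _RAW_PREAMBLE]
        sample_ids = tab["IID"].to_numpy(dtype=str)
        dosages = tab[marker_cols].to_numpy(dtype=np.float64)
        parsed = [_parse_marker_token(t) for t in marker_cols]
        marker_ids = np.array([p[0] for p in parsed], dtype=str)
        chrom = np.array([p[1] for p in parsed], dtype=str)
        pos = np.array([p[2] for p in parsed], dtype=np.int64)
        if (pos < 0).any():  # dialect without embedded coordinates
            pos = np.arange(1, len(marker_cols) + 1, dtype=np.int64)
        allele = np.array([p[3] for p in parsed], dtype=str)
    else:
        sample_ids, marker_ids, chrom, pos, allele, dosages = _read_vcf(genotype_path)

    _check_sample_match(sample_ids, sheet["sample_id"])
    sheet = sheet.set_index("sample_id").loc[sample_ids].reset_index()
    cov_names = [c for c in sheet.columns if c not in ("sample_id", "phenotype", "collection")]
    return GenotypeDataset(
        dosages=dosages,
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        marker_chrom=chrom,
        marker_pos=pos,
        counted_allele=allele,
        y=sheet["phenotype"].to_numpy(dtype=np.float64),
        collection=sheet["collection"].to_numpy(dtype=str),
        W=sheet[cov_names].to_numpy(dtype=np.float64).reshape(len(sheet), -1),
        covariate_names=cov_names,
    )


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples, dtype=str)
    ids, chroms, poss, alts, cols = [], [], [], [], []
    # cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_to_dosage = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            logger.warning("skipping non-biallelic-SNV record %s:%s", v.CHROM, v.POS)
            continue
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(_norm_chrom(v.CHROM))
        poss.append(v.POS)
        alts.append(v.ALT[0])
        cols.append(gt_to_dosage[np.asarray(v.gt_types)])
    vcf.close()
    if not ids:
        raise ValueError(f"no usable biallelic SNV records in {path}")
    dosages = np.column_stack(cols)
    return (
        sample_ids,
        np.asarray(ids, dtype=str),
        np.asarray(chroms, dtype=str),
        np.asarray(poss, dtype=np.int64),
        np.asarray(alts, dtype=str),
        dosages,
    )


def write_dataset(ds: GenotypeDataset, path, format: str = "raw", samples_path=None):
    """Write ``ds`` as a .raw-style dosage table plus a TSV sample sheet.

    ``samples_path`` defaults to ``<path>.samples.tsv``. Marker header
    tokens embed chromosome and position (``chrom:pos:id_ALLELE``) so that
    a read/write round trip reproduces the dataset exactly; missing
    dosages are written as the literal ``NA``.
    """
    if format != "raw":
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    if samples_path is None:
        samples_path = path.with_suffix(path.suffix + ".samples.tsv")
    header = _RAW_PREAMBLE + [
        _marker_token(m, c, int(p), a)
        for m, c, p, a in zip(ds.marker_ids, ds.marker_chrom, ds.marker_pos, ds.counted_allele)
    ]
    # PHENOTYPE written plink-style (1/2) for binary traits; the sample
    # sheet remains the authoritative phenotype source on read
    pheno = ds.y + 1 if ds.is_binary else ds.y
    buf = io.StringIO()
    buf.write(" ".join(header) + "\n")
    for i in range(ds.n_samples):
        row = [ds.sample_ids[i], ds.sample_ids[i], "0", "0", "0", _fmt(pheno[i])]
        row.extend(_fmt(v) for v in ds.dosages[i])
        buf.write(" ".join(row) + "\n")
    path.write_text(buf.getvalue())

    sheet = pd.DataFrame({"sample_id": ds.sample_ids, "phenotype": ds.y, "collection": ds.collection})
    for j, name in enumerate(ds.covariate_names):
        sheet[name] = ds.W[:, j]
    sheet.to_csv(samples_path, sep="\t", index=False)
    return path


def _fmt(v: float) -> str:
    if not np.isfinite(v):
        return "NA"
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# BED regions


def read_regions(path) -> RegionList:
    """Parse a BED file of exclusion regions (0-based, half-open)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"line {lineno}: start must satisfy 0 <= start < end")
            records.append((chrom, start, end))
    return RegionList(records)


def default_ld_regions() -> RegionList:
    """The bundled long-range-LD exclusion regions (hg19 coordinates)."""
    with resources.as_file(
        resources.files("ancestryx.data") / "long_range_ld_hg19.bed"
    ) as p:
        return read_regions(p)
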
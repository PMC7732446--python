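"""Genotype table IO and locus-level filtering for inbred-line SNP panels.

Supported formats:

``matrix``
    Plain TSV/CSV: first column sample ID, header row of locus IDs, one
    single-letter homozygous call per cell.
``hapmap``
    TASSEL ``.hmp.txt`` dialect: 11 metadata columns (rs#, alleles, chrom,
    pos, strand, assembly#, center, protLSID, assayLSID, panelLSID, QCcode)
    followed by one column per sample; rows are loci.
``vcf``
    VCFv4.x with GT genotypes, biallelic SNP records only.

Lines are assumed (near-)fully homozygous; heterozygous or IUPAC-ambiguous
calls are mapped to the missing sentinel ``N`` on input (``strict=True``
raises instead). ``-`` and ``.`` are also accepted as missing on input.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = "N"
NUCLEOTIDES = ("A", "C", "G", "T")
#: IUPAC ambiguity codes that denote heterozygous calls in hapmap files.
_AMBIGUOUS = set("RYSWKMBDHV")
_MISSING_INPUT = {"N", "-", ".", ""}

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class GenotypeFormatError(ValueError):
    """Malformed genotype file (reported with line number where known)."""


@dataclass
class SNPMatrix:
    """Sample x locus table of homozygous nucleotide calls.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    locus_ids : list of str
        Unique locus identifiers, one per column.
    calls : ndarray of shape (n, L), dtype ``<U1``
        Entries in {A, C, G, T, N} where N marks a missing call.
    true_labels : list of str, optional
        Known subpopulation per sample, used only for evaluation.
    """

    sample_ids: list
    locus_ids: list
    calls: np.ndarray
    true_labels: Optional[list] = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, L = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.locus_ids) != L:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {L} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus IDs")
        bad = ~np.isin(self.calls, NUCLEOTIDES + (MISSING,))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.true_labels is not None and len(self.true_labels) != n:
            raise ValueError("true_labels length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SNPMatrix)
            and self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class LocusStats:
    """Per-locus allele tally, minor allele frequency and missingness."""

    locus_id: str
    allele_counts: dict
    maf: float
    missing_fraction: float
    #: True when no non-missing call was observed (maf undefined, set to nan).
    undefined: bool = field(default=False)


def _clean_call(raw: str, *, strict: bool, where: str) -> str:
    c = raw.strip().upper()
    if c in _MISSING_INPUT:
        return MISSING
    if c in NUCLEOTIDES:
        return c
    if len(c) == 1 and c in _AMBIGUOUS:
        if strict:
            raise GenotypeFormatError(f"heterozygous/ambiguous call {raw!r} at {where}")
        return MISSING
    # two-letter hapmap diploid calls, e.g. "AA" or "AT"
    if len(c) == 2 and set(c) <= set(NUCLEOTIDES):
        if c[0] == c[1]:
            return c[0]
        if strict:
            raise GenotypeFormatError(f"heterozygous call {raw!r} at {where}")
        return MISSING
    raise GenotypeFormatError(f"unrecognised call {raw!r} at {where}")


def _sniff_delimiter(header_line: str) -> str:
    return "," if ("," in header_line and "\t" not in header_line) else "\t"


def _read_matrix(path: Path, strict: bool) -> SNPMatrix:
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise GenotypeFormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        locus_ids = [h.strip() for h in header[1:]]
        if not locus_ids:
            raise GenotypeFormatError(f"{path}: no locus columns in header")
        sample_ids, rows = [], []
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not rec or not "".join(rec).strip():
                continue
            if len(rec) != len(locus_ids) + 1:
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {len(locus_ids) + 1} fields, got {len(rec)}"
                )
            sample_ids.append(rec[0].strip())
            rows.append([
                _clean_call(c, strict=strict, where=f"{path}:{lineno}") for c in rec[1:]
            ])
    if not sample_ids:
        raise GenotypeFormatError(f"{path}: no sample rows")
    return SNPMatrix(sample_ids, locus_ids, np.array(rows, dtype="<U1"))


def _read_hapmap(path: Path, strict: bool) -> SNPMatrix:
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise GenotypeFormatError(f"{path}: hapmap header needs 11 metadata columns plus samples")
        sample_ids = [h.strip() for h in header[11:]]
        locus_ids, cols = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            rec = line.rstrip("\n").split("\t")
            if len(rec) != len(header):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(rec)}"
                )
            locus_ids.append(rec[0].strip())
            cols.append([
                _clean_call(c, strict=strict, where=f"{path}:{lineno}") for c in rec[11:]
            ])
    if not locus_ids:
        raise GenotypeFormatError(f"{path}: no locus rows")
    calls = np.array(cols, dtype="<U1").T  # loci-rows -> samples-rows
    return SNPMatrix(sample_ids, locus_ids, calls)


def _read_vcf(path: Path, strict: bool) -> SNPMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise GenotypeFormatError(f"{path}: VCF contains no samples")
    locus_ids, cols = [], []
    for idx, var in enumerate(vcf, start=1):
        alts = [a for a in var.ALT if a not in (".", "")]
        if len(alts) > 1:
            raise GenotypeFormatError(
                f"{path}: record {idx} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        alleles = [var.REF] + alts
        if any(len(a) != 1 or a.upper() not in NUCLEOTIDES for a in alleles):
            raise GenotypeFormatError(
                f"{path}: record {idx} ({var.CHROM}:{var.POS}) is not a SNP"
            )
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        locus_ids.append(lid)
        col = []
        for s, gt in zip(sample_ids, var.genotypes):
            a, b = gt[0], gt[1] if len(gt) > 2 else gt[0]
            if a < 0 or b < 0:
                col.append(MISSING)
            elif a == b:
                col.append(alleles[a].upper())
            elif strict:
                raise GenotypeFormatError(
                    f"{path}: heterozygous GT for sample {s} at record {idx}"
                )
            else:
                col.append(MISSING)  # inbred-line convention
        cols.append(col)
    if not locus_ids:
        raise GenotypeFormatError(f"{path}: VCF contains no usable records")
    return SNPMatrix(sample_ids, locus_ids, np.array(cols, dtype="<U1").T)


def read_genotype_table(path, format: str, strict: bool = False) -> SNPMatrix:
    """Read a genotype table.

    Parameters
    ----------
    path : path-like
    format : {"vcf", "hapmap", "matrix"}
    strict : bool
        Raise on heterozygous/ambiguous calls instead of mapping to missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"matrix": _read_matrix, "hapmap": _read_hapmap, "vcf": _read_vcf}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path, strict)


def _locus_alleles(column: np.ndarray) -> tuple:
    """(ref, alt) for one locus column: ref = most frequent allele, ties A<C<G<T."""
    vals, counts = np.unique(column[column != MISSING], return_counts=True)
    order = sorted(range(len(vals)), key=lambda i: (-counts[i], vals[i]))
    ranked = [vals[i] for i in order]
    ref = ranked[0] if ranked else "A"
    alt = ranked[1] if len(ranked) > 1 else None
    return ref, alt


def write_genotype_table(m: SNPMatrix, path, format: str) -> None:
    """Write ``m`` so that :func:`read_genotype_table` round-trips it exactly."""
    if m.n_loci == 0 or m.n_samples == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    if format == "matrix":
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(m.locus_ids) + "\n")
            for sid, row in zip(m.sample_ids, m.calls):
                fh.write(sid + "\t" + "\t".join(row) + "\n")
    elif format == "hapmap":
        with open(path, "w") as fh:
            fh.write("\t".join(HAPMAP_COLUMNS + list(m.sample_ids)) + "\n")
            for j, lid in enumerate(m.locus_ids):
                ref, alt = _locus_alleles(m.calls[:, j])
                alleles = f"{ref}/{alt}" if alt else ref
                meta = [lid, alleles, "1", str(j + 1), "+"] + ["NA"] * 6
                fh.write("\t".join(meta + list(m.calls[:, j])) + "\n")
    elif format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(m.sample_ids) + "\n"
            )
            for j, lid in enumerate(m.locus_ids):
                ref, alt = _locus_alleles(m.calls[:, j])
                gts = []
                for c in m.calls[:, j]:
                    if c == MISSING:
                        gts.append("./.")
                    elif c == ref:
                        gts.append("0/0")
                    elif alt is not None and c == alt:
                        gts.append("1/1")
                    else:  # >2 alleles at this locus cannot be a biallelic record
                        raise ValueError(f"locus {lid} has more than two alleles")
                fh.write(
                    f"1\t{j + 1}\t{lid}\t{ref}\t{alt or '.'}\t.\t.\t.\tGT\t"
                    + "\t".join(gts) + "\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def compute_locus_stats(m: SNPMatrix) -> list:
    """Allele counts, MAF and missing fraction per locus.

    MAF is the count of the second-most-frequent observed allele divided by
    the non-missing count; monomorphic loci get 0, all-missing loci are
    flagged ``undefined`` with maf = nan.
    """
    out = []
    n = m.n_samples
    for j, lid in enumerate(m.locus_ids):
        col = m.calls[:, j]
        obs = col[col != MISSING]
        vals, counts = np.unique(obs, return_counts=True)
        allele_counts = dict(zip(vals.tolist(), counts.tolist()))
        n_obs = obs.size
        missing_fraction = (n - n_obs) / n
        if n_obs == 0:
            out.append(LocusStats(lid, {}, float("nan"), missing_fraction, undefined=True))
            continue
        if len(counts) == 1:
            maf = 0.0
        else:
            maf = float(np.sort(counts)[-2]) / n_obs
        out.append(LocusStats(lid, allele_counts, maf, missing_fraction))
    return out


def filter_loci(m: SNPMatrix, maf_min: float = 0.15, max_missing: float = 0.0) -> SNPMatrix:
    """Keep loci with MAF strictly above ``maf_min`` and missing fraction at
    most ``max_missing``; boundary-MAF and all-missing loci are dropped.
    """
    if not (0 <= maf_min <= 1 and 0 <= max_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    stats = compute_locus_stats(m)
    keep = [
        j for j, s in enumerate(stats)
        if not s.undefined and s.maf > maf_min and s.missing_fraction <= max_missing
    ]
    dropped = m.n_loci - len(keep)
    logger.info("filter_loci: dropped %d of %d loci (maf>%g, missing<=%g)",
                dropped, m.n_loci, maf_min, max_missing)
    if not keep:
        raise ValueError(
            f"all {m.n_loci} loci removed by maf>{maf_min}, missing<={max_missing}"
        )
    return SNPMatrix(
        list(m.sample_ids),
        [m.locus_ids[j] for j in keep],
        m.calls[:, keep],
        true_labels=list(m.true_labels) if m.true_labels is not None else None,
    )
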
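"""Genotype matrix container and I/O.

A :class:`GenotypeMatrix` is a dense varieties x loci table of categorical
genotype codes.  Genotypes are treated as unordered classes ("A/A", "A/T",
...), not allele dosages: the selection method scores loci by genotype-class
frequencies, which is the natural parameterisation for inbred, mostly
homozygous panels.  Each cell holds a small non-negative integer code that is
meaningful only together with the per-locus ``code_labels`` mapping; ``-1``
(:data:`MISSING`) marks a missing call.  Missing calls are excluded from every
frequency computation in the package.

Supported on-disk formats are VCF 4.x (GT field only, via cyvcf2) and a plain
TSV dialect with columns ``locus_id, chrom, pos, <sample...>`` and one row per
locus.  The TSV dialect round-trips exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Reserved genotype code for a missing call.
MISSING = -1


class GenotypeIOError(ValueError):
    """Raised for malformed genotype input files."""


@dataclass(frozen=True)
class Locus:
    """A genomic site: unique identifier, 1-based coordinate, allele labels."""

    locus_id: str
    chrom: str
    pos: int
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.locus_id}: pos must be >= 1, got {self.pos}")
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.locus_id}: needs at least one allele label")


class GenotypeMatrix:
    """Dense varieties x loci table of categorical genotype codes.

    Parameters
    ----------
    samples
        Unique variety labels, one per row.
    loci
        :class:`Locus` records, one per column; ``locus_id`` unique.
    calls
        ``(n_samples, n_loci)`` integer array of genotype codes;
        :data:`MISSING` marks missing calls.
    code_labels
        One ``{code: genotype string}`` mapping per locus; every non-missing
        code occurring in the corresponding column must have a label.
    """

    __slots__ = ("samples", "loci", "calls", "code_labels", "_locus_index")

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
        code_labels: Sequence[Mapping[int, str]],
    ) -> None:
        samples = list(samples)
        loci = list(loci)
        calls = np.asarray(calls, dtype=np.int16)
        if len(set(samples)) != len(samples):
            raise ValueError("sample labels must be unique")
        ids = [loc.locus_id for loc in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus_id must be unique within a matrix")
        if calls.shape != (len(samples), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(samples)}, {len(loci)})"
            )
        if len(code_labels) != len(loci):
            raise ValueError("need one code->label mapping per locus")
        for j, labels in enumerate(code_labels):
            present = set(np.unique(calls[:, j])) - {MISSING}
            missing_labels = present - set(labels)
            if missing_labels:
                raise ValueError(
                    f"locus {loci[j].locus_id}: codes {sorted(missing_labels)} have no label"
                )
        self.samples = samples
        self.loci = loci
        self.calls = calls
        self.code_labels = [dict(m) for m in code_labels]
        self._locus_index = {loc.locus_id: j for j, loc in enumerate(loci)}

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def locus_col(self, locus_id: str) -> int:
        """Column index of a locus; KeyError with the offending id otherwise."""
        try:
            return self._locus_index[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus id: {locus_id!r}") from None

    def genotype_label(self, i: int, j: int) -> str | None:
        """Genotype string at cell (sample i, locus j); None when missing."""
        code = int(self.calls[i, j])
        if code == MISSING:
            return None
        return self.code_labels[j][code]

    def labels_matrix(self) -> np.ndarray:
        """Object array of genotype strings (None where missing)."""
        out = np.empty(self.calls.shape, dtype=object)
        for j, labels in enumerate(self.code_labels):
            col = self.calls[:, j]
            colout = out[:, j]
            for code, lab in labels.items():
                colout[col == code] = lab
        return out

    # -- derived matrices ---------------------------------------------------

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given loci, in the given order."""
        cols = [self.locus_col(l) for l in locus_ids]
        return GenotypeMatrix(
            self.samples,
            [self.loci[j] for j in cols],
            self.calls[:, cols].copy(),
            [self.code_labels[j] for j in cols],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.loci, self.calls.copy(), self.code_labels)

    @classmethod
    def from_label_rows(
        cls,
        samples: Sequence[str],
        loci: Sequence[Locus],
        rows: Iterable[Sequence[str | None]],
    ) -> "GenotypeMatrix":
        """Build a matrix from per-locus rows of genotype strings.

        Empty strings and None count as missing.  Codes are assigned in order
        of first appearance down each row, which makes the encoding canonical
        for a given table.
        """
        samples = list(samples)
        loci = list(loci)
        calls = np.full((len(samples), len(loci)), MISSING, dtype=np.int16)
        code_labels: list[dict[int, str]] = []
        for j, row in enumerate(rows):
            if len(row) != len(samples):
                raise GenotypeIOError(
                    f"locus row {j}: expected {len(samples)} genotypes, got {len(row)}"
                )
            mapping: dict[str, int] = {}
            for i, g in enumerate(row):
                if g is None or g == "":
                    continue
                if g not in mapping:
                    mapping[g] = len(mapping)
                calls[i, j] = mapping[g]
            code_labels.append({code: lab for lab, code in mapping.items()})
        if len(code_labels) != len(loci):
            raise GenotypeIOError("number of locus rows does not match loci")
        return cls(samples, loci, calls, code_labels)

    # -- equality is semantic: same labels per cell, same loci/samples.
    # Allele labels compare as a set because the TSV dialect cannot carry
    # their order (it is recovered from the genotype strings on read).

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.samples != other.samples:
            return False
        if len(self.loci) != len(other.loci):
            return False
        for a, b in zip(self.loci, other.loci):
            if (a.locus_id, a.chrom, a.pos) != (b.locus_id, b.chrom, b.pos):
                return False
            if set(a.alleles) != set(b.alleles):
                return False
        if self.calls.shape != other.calls.shape:
            return False
        return bool(np.array_equal(self.labels_matrix(), other.labels_matrix()))

    def __hash__(self) -> int:  # mutable container; identity hash
        return id(self)

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_FIXED = ("locus_id", "chrom", "pos")


def read_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the package's TSV genotype dialect.

    Header: ``locus_id  chrom  pos  <sample> ...``; one row per locus with
    genotype strings, empty cell = missing call.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeIOError(f"{path}: empty file") from None
        if tuple(header[:3]) != _TSV_FIXED:
            raise GenotypeIOError(
                f"{path}: header must start with {_TSV_FIXED}, got {header[:3]}"
            )
        samples = header[3:]
        loci: list[Locus] = []
        rows: list[list[str]] = []
        for idx, row in enumerate(reader, start=1):
            if len(row) != len(header):
                raise GenotypeIOError(
                    f"{path}: row {idx}: expected {len(header)} fields, got {len(row)}"
                )
            locus_id, chrom, pos_s = row[:3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise GenotypeIOError(f"{path}: row {idx}: bad pos {pos_s!r}") from None
            genotypes = row[3:]
            alleles = _alleles_from_labels(genotypes)
            loci.append(Locus(locus_id, chrom, pos, alleles))
            rows.append(genotypes)
    return GenotypeMatrix.from_label_rows(samples, loci, rows)


def _alleles_from_labels(genotypes: Sequence[str]) -> tuple[str, ...]:
    """Distinct allele labels occurring in a row of genotype strings."""
    seen: dict[str, None] = {}
    for g in genotypes:
        if not g:
            continue
        for a in g.split("/"):
            seen.setdefault(a, None)
    if not seen:
        seen["N"] = None  # fully missing locus still needs an allele label
    return tuple(seen)


def write_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect; ``read_tsv(write_tsv(m)) == m``."""
    path = Path(path)
    labels = matrix.labels_matrix()
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(_TSV_FIXED) + matrix.samples)
        for j, loc in enumerate(matrix.loci):
            col = ["" if g is None else g for g in labels[:, j]]
            writer.writerow([loc.locus_id, loc.chrom, str(loc.pos)] + col)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, het_policy: str = "own_class") -> GenotypeMatrix:
    """Read GT calls from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Every distinct unphased genotype at a site becomes its own class;
    phased separators are normalised (``0|1`` == ``1/0``).  ``./.`` maps to
    the missing code.

    Parameters
    ----------
    het_policy
        ``"own_class"`` keeps heterozygous calls as their own genotype class;
        ``"missing"`` converts them to missing calls.
    """
    if het_policy not in ("own_class", "missing"):
        raise ValueError(f"het_policy must be 'own_class' or 'missing', got {het_policy!r}")
    from cyvcf2 import VCF  # deferred: import cost + optional at runtime

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise GenotypeIOError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeIOError(f"{path}: duplicate sample IDs in header")
    loci: list[Locus] = []
    rows: list[list[str | None]] = []
    try:
        for k, var in enumerate(vcf):
            alleles = tuple([var.REF] + list(var.ALT))
            locus_id = var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}"
            row: list[str | None] = []
            for gt in var.genotypes:
                # cyvcf2 genotype entries are [allele, allele, phased] for
                # diploids and [allele, phased] for haploid calls
                if len(gt) >= 3:
                    a, b = gt[0], gt[1]
                else:
                    a = b = gt[0]
                if a < 0 or b < 0:
                    row.append(None)
                    continue
                i, j = sorted((a, b))
                if i != j and het_policy == "missing":
                    row.append(None)
                else:
                    row.append(f"{alleles[i]}/{alleles[j]}")
            loci.append(Locus(locus_id, var.CHROM, var.POS, alleles))
            rows.append(row)
    except GenotypeIOError:
        raise
    except Exception as exc:
        raise GenotypeIOError(
            f"{path}: parse error at record {len(rows) + 1}: {exc}"
        ) from exc
    return GenotypeMatrix.from_label_rows(samples, loci, rows)


# ---------------------------------------------------------------------------
# In-scope pre-filters
# ---------------------------------------------------------------------------


def drop_uninformative(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci genotypically identical across all samples.

    A retained locus has at least two distinct non-missing genotype classes.
    Idempotent; never touches samples.
    """
    keep = []
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j]
        if len(np.unique(col[col != MISSING])) >= 2:
            keep.append(matrix.loci[j].locus_id)
    return matrix.subset_loci(keep)


def basic_filters(
    matrix: GenotypeMatrix, max_missing: float = 0.20, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Drop loci with a high missing rate or a low minor-allele frequency.

    Allele frequencies are computed from the allele labels of the non-missing
    genotype strings; the minor-allele frequency is the second-highest allele
    frequency at the locus (zero when only one allele is observed).
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("max_missing and min_maf must lie in [0, 1]")
    keep = []
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j]
        n = len(col)
        n_missing = int((col == MISSING).sum())
        if n_missing / n > max_missing:
            continue
        counts: dict[str, int] = {}
        for code, label in matrix.code_labels[j].items():
            k = int((col == code).sum())
            if k == 0:
                continue
            for allele in label.split("/"):
                counts[allele] = counts.get(allele, 0) + k
        total = sum(counts.values())
        if total == 0:
            continue
        freqs = sorted((c / total for c in counts.values()), reverse=True)
        maf = freqs[1] if len(freqs) > 1 else 0.0
        if maf < min_maf:
            continue
        keep.append(matrix.loci[j].locus_id)
    return matrix.subset_loci(keep)
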
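"""Genotype input/output and allele-frequency tables.

Reads the two genotype container formats standard in ancient-DNA population
genetics — EIGENSTRAT (a trio of plain-text ``.geno``/``.snp``/``.ind``
files) and PACKEDANCESTRYMAP (the same ``.snp``/``.ind`` plus a packed
binary ``.geno``) — and turns them into a per-population allele-frequency
table.

Genotype codes count copies of the first allele listed in the ``.snp``
record (0, 1 or 2); ``9`` in text files and the 2-bit code ``3`` in packed
files mark missing data.  Which of the two alleles plays the role of
"reference" is immaterial downstream: every statistic computed from the
frequency table is invariant under the per-SNP substitution p -> 1 - p.

Missing-data rule: a SNP is dropped from the frequency table if and only if
at least one *selected* population has no genotyped individual at that SNP.
A SNP that is only partially missing within a population is retained, with
the allele frequency computed over the non-missing individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "FrequencyTable",
    "GenotypeFormatError",
    "parse_eigenstrat",
    "parse_packedancestrymap",
    "write_eigenstrat",
    "write_packedancestrymap",
    "compute_frequency_table",
    "write_frequency_table",
    "read_frequency_table",
]

#: Internal sentinel for a missing genotype call.
MISSING: int = -1

#: Minimum record length (bytes) of a PACKEDANCESTRYMAP genotype row.
_PACKED_MIN_RECORD = 48


class GenotypeFormatError(ValueError):
    """A structural problem in a genotype file (ragged rows, bad codes...)."""


@dataclass
class GenotypeDataset:
    """Per-individual genotype matrix with SNP and sample metadata.

    Attributes
    ----------
    genotypes
        ``(n_snps, n_individuals)`` int8 matrix with entries in
        ``{0, 1, 2, MISSING}``; the value counts copies of the first allele
        of the ``.snp`` record.
    snps
        One row per SNP, columns ``id, chrom, gpos, pos, ref, alt`` exactly
        as read from the ``.snp`` file.
    individual_ids
        Sample identifiers in column order.
    population_of
        Maps each individual id to its population label.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    individual_ids: list[str]
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        valid = np.isin(g, (0, 1, 2, MISSING))
        if not valid.all():
            bad = g[~valid][0]
            raise GenotypeFormatError(f"invalid genotype code {bad}")
        if g.shape[0] != len(self.snps):
            raise GenotypeFormatError(
                f"{g.shape[0]} genotype rows but {len(self.snps)} SNP records"
            )
        if g.shape[1] != len(self.individual_ids):
            raise GenotypeFormatError(
                f"genotype rows have {g.shape[1]} entries but "
                f"{len(self.individual_ids)} individuals are declared"
            )
        self.genotypes = g

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["id"])

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance in the .ind file."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)


@dataclass
class FrequencyTable:
    """SNP x population allele-frequency matrix after missing-data filtering.

    ``s``, the effective number of SNPs, is the number of rows retained by
    the all-missing-per-population filter.
    """

    freqs: np.ndarray
    populations: list[str]
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=np.float64)
        if f.ndim != 2:
            raise ValueError("freqs must be a 2-D (snp, population) matrix")
        if f.shape[1] != len(self.populations):
            raise ValueError("freqs width does not match number of populations")
        if not self.snp_ids:
            self.snp_ids = [f"snp{i}" for i in range(f.shape[0])]
        if len(self.snp_ids) != f.shape[0]:
            raise ValueError("snp_ids length does not match number of rows")
        if f.size and (np.isnan(f).any() or f.min() < 0 or f.max() > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        self.freqs = f

    @property
    def s(self) -> int:
        """Effective number of SNPs."""
        return self.freqs.shape[0]

    def column(self, population: str) -> np.ndarray:
        """Frequency vector of one population (read-only view)."""
        try:
            k = self.populations.index(population)
        except ValueError:
            raise KeyError(
                f"unknown population {population!r}; "
                f"valid labels: {', '.join(self.populations)}"
            ) from None
        v = self.freqs[:, k]
        v.flags.writeable = False
        return v

    def subset_snps(self, index: slice | np.ndarray) -> "FrequencyTable":
        """A new table restricted to the given SNP rows (never mutates self)."""
        ids = np.asarray(self.snp_ids, dtype=object)[index]
        return FrequencyTable(
            self.freqs[index].copy(), list(self.populations), list(ids)
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT (plain text)
# ---------------------------------------------------------------------------

def _read_ind(ind_path) -> tuple[list[str], dict[str, str]]:
    individual_ids: list[str] = []
    population_of: dict[str, str] = {}
    with open(ind_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                raise GenotypeFormatError(
                    f"{ind_path}: line {lineno}: expected 3 columns "
                    f"(id, sex, population), got {len(fields)}"
                )
            ind_id, _sex, pop = fields  # sex read and ignored
            individual_ids.append(ind_id)
            population_of[ind_id] = pop
    return individual_ids, population_of


def _read_snp(snp_path) -> pd.DataFrame:
    rows = []
    with open(snp_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise GenotypeFormatError(
                    f"{snp_path}: line {lineno}: expected >= 4 columns, "
                    f"got {len(fields)}"
                )
            fields = fields + [""] * (6 - len(fields))
            rows.append(fields[:6])
    return pd.DataFrame(
        rows, columns=["id", "chrom", "gpos", "pos", "ref", "alt"]
    )


_GENO_CODE = {ord("0"): 0, ord("1"): 1, ord("2"): 2, ord("9"): MISSING}


def parse_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeDataset:
    """Parse an EIGENSTRAT trio of plain-text files.

    The ``.geno`` file holds one line per SNP, one character per individual,
    over the alphabet ``{0, 1, 2, 9}`` (9 = missing).

    Raises
    ------
    GenotypeFormatError
        If a ``.geno`` line width disagrees with the ``.ind`` count, or an
        unknown genotype character appears (the message names the offending
        SNP line).
    """
    individual_ids, population_of = _read_ind(ind_path)
    snps = _read_snp(snp_path)
    n_ind = len(individual_ids)

    rows = np.empty((len(snps), n_ind), dtype=np.int8)
    with open(geno_path) as fh:
        snp_idx = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise GenotypeFormatError(
                    f"{geno_path}: line {lineno}: {len(line)} genotype "
                    f"characters but {n_ind} individuals in {ind_path}"
                )
            if snp_idx >= len(snps):
                raise GenotypeFormatError(
                    f"{geno_path}: more genotype lines than SNP records "
                    f"({len(snps)})"
                )
            try:
                rows[snp_idx] = [_GENO_CODE[c] for c in line.encode()]
            except KeyError:
                bad = next(c for c in line if c not in "0129")
                raise GenotypeFormatError(
                    f"{geno_path}: SNP index {snp_idx}: unknown genotype "
                    f"character {bad!r}"
                ) from None
            snp_idx += 1
    if snp_idx != len(snps):
        raise GenotypeFormatError(
            f"{geno_path}: {snp_idx} genotype lines but {len(snps)} SNP records"
        )
    return GenotypeDataset(rows, snps, individual_ids, population_of)


def write_eigenstrat(ds: GenotypeDataset, geno_path, snp_path, ind_path) -> None:
    """Write a dataset as an EIGENSTRAT trio (inverse of :func:`parse_eigenstrat`)."""
    code = {0: "0", 1: "1", 2: "2", MISSING: "9"}
    with open(geno_path, "w") as fh:
        for row in ds.genotypes:
            fh.write("".join(code[int(g)] for g in row) + "\n")
    with open(snp_path, "w") as fh:
        for rec in ds.snps.itertuples(index=False):
            fh.write("\t".join(str(v) for v in rec if v != "") + "\n")
    with open(ind_path, "w") as fh:
        for ind in ds.individual_ids:
            fh.write(f"{ind}\tU\t{ds.population_of[ind]}\n")


# ---------------------------------------------------------------------------
# PACKEDANCESTRYMAP (binary .geno)
# ---------------------------------------------------------------------------

def _packed_record_length(n_ind: int) -> int:
    return max(_PACKED_MIN_RECORD, math.ceil(n_ind / 4))


def parse_packedancestrymap(geno_path, snp_path, ind_path) -> GenotypeDataset:
    """Parse a PACKEDANCESTRYMAP dataset (binary ``.geno``).

    The binary file starts with an ASCII header record containing the
    literal ``GENO`` followed by the individual and SNP counts; each
    subsequent record holds one SNP, two bits per individual (most
    significant pair first), with the 2-bit code 3 meaning missing.

    Raises
    ------
    GenotypeFormatError
        If the header counts disagree with the ``.ind``/``.snp`` files, or
        the file is shorter than the declared number of SNP records.
    """
    individual_ids, population_of = _read_ind(ind_path)
    snps = _read_snp(snp_path)
    n_ind, n_snp = len(individual_ids), len(snps)
    record_len = _packed_record_length(n_ind)

    with open(geno_path, "rb") as fh:
        raw = fh.read()
    header = raw[:record_len].split(b"\x00", 1)[0].decode("ascii", "replace")
    parts = header.split()
    if len(parts) < 3 or parts[0] != "GENO":
        raise GenotypeFormatError(
            f"{geno_path}: not a PACKEDANCESTRYMAP file (header {header!r})"
        )
    try:
        h_ind, h_snp = int(parts[1]), int(parts[2])
    except ValueError:
        raise GenotypeFormatError(
            f"{geno_path}: malformed header counts in {header!r}"
        ) from None
    if h_ind != n_ind or h_snp != n_snp:
        raise GenotypeFormatError(
            f"{geno_path}: header declares {h_ind} individuals / {h_snp} SNPs "
            f"but .ind has {n_ind} and .snp has {n_snp}"
        )
    body = raw[record_len:]
    if len(body) < n_snp * record_len:
        raise GenotypeFormatError(
            f"{geno_path}: truncated: {len(body)} bytes of genotype records, "
            f"expected {n_snp * record_len}"
        )

    packed = np.frombuffer(
        body[: n_snp * record_len], dtype=np.uint8
    ).reshape(n_snp, record_len)
    # Unpack 2-bit codes, most significant pair first within each byte.
    shifts = np.array([6, 4, 2, 0], dtype=np.uint8)
    codes = (packed[:, :, None] >> shifts[None, None, :]) & 3
    codes = codes.reshape(n_snp, record_len * 4)[:, :n_ind].astype(np.int8)
    codes[codes == 3] = MISSING
    return GenotypeDataset(codes, snps, individual_ids, population_of)


def write_packedancestrymap(ds: GenotypeDataset, geno_path) -> None:
    """Pack genotypes into a PACKEDANCESTRYMAP binary ``.geno`` file.

    Companion ``.snp``/``.ind`` files are the same as for EIGENSTRAT and can
    be written with :func:`write_eigenstrat`.
    """
    n_snp, n_ind = ds.genotypes.shape
    record_len = _packed_record_length(n_ind)
    header = f"GENO {n_ind} {n_snp} 0 0".encode("ascii")
    header = header.ljust(record_len, b"\x00")

    codes = ds.genotypes.astype(np.int16).copy()
    codes[codes == MISSING] = 3
    width = record_len * 4
    padded = np.full((n_snp, width), 3, dtype=np.uint8)  # pad slots = missing
    padded[:, :n_ind] = codes
    quads = padded.reshape(n_snp, record_len, 4)
    packed = (
        (quads[:, :, 0] << 6)
        | (quads[:, :, 1] << 4)
        | (quads[:, :, 2] << 2)
        | quads[:, :, 3]
    ).astype(np.uint8)
    with open(geno_path, "wb") as fh:
        fh.write(header)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Frequency table
# ---------------------------------------------------------------------------

def compute_frequency_table(
    ds: GenotypeDataset,
    selected_populations: list[str] | None = None,
    max_snps: int | None = None,
) -> FrequencyTable:
    """Build the per-population allele-frequency table.

    A SNP is dropped if and only if at least one selected population has all
    its individuals missing at that SNP; otherwise the frequency for each
    population is the mean allele count over its non-missing individuals,
    divided by 2.  When ``max_snps`` is given, only the first ``max_snps``
    SNPs in file order are considered, *before* filtering.

    Raises
    ------
    KeyError
        Unknown population label (message lists the valid ones).
    ValueError
        No SNP survives the filter.
    """
    if selected_populations is None:
        selected_populations = ds.populations
    valid = set(ds.population_of.values())
    for pop in selected_populations:
        if pop not in valid:
            raise KeyError(
                f"unknown population {pop!r}; valid labels: "
                f"{', '.join(sorted(valid))}"
            )
    if len(set(selected_populations)) != len(selected_populations):
        raise ValueError("selected population labels must be unique")

    g = ds.genotypes
    if max_snps is not None:
        g = g[:max_snps]
    n_snp = g.shape[0]

    freqs = np.empty((n_snp, len(selected_populations)))
    keep = np.ones(n_snp, dtype=bool)
    pops_arr = np.array([ds.population_of[i] for i in ds.individual_ids])
    for k, pop in enumerate(selected_populations):
        sub = g[:, pops_arr == pop]
        observed = sub != MISSING
        n_obs = observed.sum(axis=1)
        count = np.where(observed, sub, 0).sum(axis=1)
        keep &= n_obs > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[:, k] = count / (2 * n_obs)

    if not keep.any():
        raise ValueError(
            "empty frequency table: every SNP has an all-missing population "
            "among the selected ones"
        )
    ids = [sid for sid, k in zip(ds.snp_ids[:n_snp], keep) if k]
    return FrequencyTable(freqs[keep], list(selected_populations), ids)


def write_frequency_table(ft: FrequencyTable, path) -> None:
    """Save a frequency table as plain text.

    First line: whitespace-separated population labels.  One line per SNP
    follows, frequencies in fixed 6-decimal notation.
    """
    if ft.s == 0:
        raise ValueError("refusing to write an empty frequency table")
    with open(path, "w") as fh:
        fh.write(" ".join(ft.populations) + "\n")
        for row in ft.freqs:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_frequency_table(path) -> FrequencyTable:
    """Read a table written by :func:`write_frequency_table`.

    SNP identifiers are not stored in the text format, so generic row labels
    are synthesised.
    """
    with open(path) as fh:
        populations = fh.readline().split()
        freqs = np.loadtxt(fh, ndmin=2)
    return FrequencyTable(freqs, populations)
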
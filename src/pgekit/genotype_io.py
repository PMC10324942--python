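"""Readers and writers for brood genotype tables and per-SNP allele count tables.

Two on-disk dialects are defined here:

* **Brood CSV** — one row per individual per microsatellite locus, columns
  ``family, species, individual, role, locus, allele1, allele2``.  Alleles are
  opaque labels (typically fragment lengths); they are compared for equality
  only, never ordered numerically.
* **Allele count tables** — either the GATK ASEReadCounter tab-separated
  dialect (columns ``contig, position, refCount, altCount, otherBases``, one
  file per sample) or a minimal CSV dialect with an explicit ``sample`` column
  (``sample, contig, position, ref_count, alt_count, other_count``).

Positions are 1-based throughout (the VCF/ASEReadCounter convention).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenotypeCall",
    "IndividualGenotypes",
    "Brood",
    "SnpCounts",
    "BroodTableError",
    "CountTableError",
    "read_brood_table",
    "write_brood_table",
    "read_ase_counts",
    "write_ase_counts",
]


class BroodTableError(ValueError):
    """A brood genotype table violates the dialect contract."""


class CountTableError(ValueError):
    """An allele count table violates the dialect contract."""


@dataclass(frozen=True)
class GenotypeCall:
    """One individual's genotype at one microsatellite locus.

    A call with a single recorded allele is stored as an apparent homozygote
    ``(a, a)`` with ``from_single_allele=True``, because allelic dropout
    cannot be excluded for single-peak profiles.  Downstream inference treats
    it as homozygous; the flag is preserved through round-trips.
    """

    individual_id: str
    locus_id: str
    alleles: tuple[str, ...]  # () if missing, else exactly 2 labels
    missing: bool = False
    from_single_allele: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            if self.alleles:
                raise ValueError("missing call must have no alleles")
        else:
            if len(self.alleles) != 2:
                raise ValueError("non-missing call must store 2 alleles")
            if not all(self.alleles):
                raise ValueError("allele labels must be non-empty")

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)

    @property
    def is_heterozygous(self) -> bool:
        return not self.missing and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class IndividualGenotypes:
    """All locus calls for one individual, keyed by locus id."""

    individual_id: str
    calls: Mapping[str, GenotypeCall]

    def call(self, locus_id: str) -> GenotypeCall:
        return self.calls[locus_id]


@dataclass(frozen=True)
class Brood:
    """A mother and her genotyped offspring over a shared set of loci."""

    family_id: str
    species: str
    loci: tuple[str, ...]
    mother: IndividualGenotypes
    offspring: tuple[IndividualGenotypes, ...]

    def __post_init__(self) -> None:
        if not self.offspring:
            raise ValueError(f"family {self.family_id}: at least one offspring required")
        declared = set(self.loci)
        for indiv in (self.mother, *self.offspring):
            if set(indiv.calls) != declared:
                raise ValueError(
                    f"family {self.family_id}: individual {indiv.individual_id} "
                    f"does not cover the declared loci"
                )

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)


@dataclass(frozen=True)
class SnpCounts:
    """Reference/alternate/other read counts for one sample at one SNP site."""

    sample_id: str
    contig: str
    position: int  # 1-based
    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("read counts must be non-negative")
        if self.position < 1:
            raise ValueError("positions are 1-based; must be >= 1")

    @property
    def site_id(self) -> tuple[str, int]:
        return (self.contig, self.position)

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


# ---------------------------------------------------------------------------
# Brood tables
# ---------------------------------------------------------------------------

_BROOD_COLUMNS = ("family", "species", "individual", "role", "locus", "allele1", "allele2")

#: Default header names; a column map may rename any of them (permissive
#: reading of third-party tables whose headers differ).
DEFAULT_BROOD_COLUMN_MAP = {c: c for c in _BROOD_COLUMNS}


def _make_call(individual: str, locus: str, a1: str, a2: str) -> GenotypeCall:
    a1, a2 = a1.strip(), a2.strip()
    if not a1 and not a2:
        return GenotypeCall(individual, locus, (), missing=True)
    if a1 and not a2:
        return GenotypeCall(individual, locus, (a1, a1), from_single_allele=True)
    if a2 and not a1:
        return GenotypeCall(individual, locus, (a2, a2), from_single_allele=True)
    return GenotypeCall(individual, locus, (a1, a2))


def read_brood_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[Brood]:
    """Read a brood CSV into a list of :class:`Brood`, one per family.

    Parameters
    ----------
    path
        CSV file with header columns ``family, species, individual, role,
        locus, allele1, allele2`` (or as renamed by *column_map*, a mapping
        from canonical name to the header actually used in the file).
        ``role`` is ``mother`` or ``offspring``; both allele columns blank
        means a missing call.

    Offspring order follows first appearance in the file and is never
    reordered.  Validation failures raise :class:`BroodTableError` naming the
    offending family and line numbers.
    """
    colmap = dict(DEFAULT_BROOD_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [colmap[c] for c in _BROOD_COLUMNS if colmap[c] not in header]
        if missing_cols:
            raise BroodTableError(f"{path}: missing required columns {missing_cols}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            rows.append((lineno, {c: (row.get(colmap[c]) or "") for c in _BROOD_COLUMNS}))

    families: dict[str, list[tuple[int, dict[str, str]]]] = {}
    family_order: list[str] = []
    for lineno, row in rows:
        fam = row["family"].strip()
        if not fam:
            raise BroodTableError(f"{path}: line {lineno}: empty family id")
        if fam not in families:
            families[fam] = []
            family_order.append(fam)
        families[fam].append((lineno, row))

    broods = []
    for fam in family_order:
        broods.append(_build_brood(path, fam, families[fam]))
    return broods


def _build_brood(path: Path, fam: str, fam_rows: list[tuple[int, dict[str, str]]]) -> Brood:
    species = fam_rows[0][1]["species"].strip()
    loci: list[str] = []
    mothers: list[str] = []
    offspring_order: list[str] = []
    calls: dict[str, dict[str, tuple[int, GenotypeCall]]] = {}
    roles: dict[str, str] = {}

    for lineno, row in fam_rows:
        indiv = row["individual"].strip()
        role = row["role"].strip().lower()
        locus = row["locus"].strip()
        if role not in ("mother", "offspring"):
            raise BroodTableError(
                f"{path}: line {lineno}: family {fam}: unknown role {row['role']!r}"
            )
        if not indiv or not locus:
            raise BroodTableError(
                f"{path}: line {lineno}: family {fam}: empty individual or locus"
            )
        prev_role = roles.setdefault(indiv, role)
        if prev_role != role:
            raise BroodTableError(
                f"{path}: line {lineno}: family {fam}: individual {indiv} "
                f"listed with conflicting roles"
            )
        if role == "mother":
            if indiv not in mothers:
                mothers.append(indiv)
        elif indiv not in offspring_order:
            offspring_order.append(indiv)
        if locus not in loci:
            loci.append(locus)
        per_indiv = calls.setdefault(indiv, {})
        if locus in per_indiv:
            raise BroodTableError(
                f"{path}: line {lineno}: family {fam}: duplicate call for "
                f"individual {indiv} at locus {locus} "
                f"(first at line {per_indiv[locus][0]})"
            )
        per_indiv[locus] = (lineno, _make_call(indiv, locus, row["allele1"], row["allele2"]))

    if len(mothers) != 1:
        raise BroodTableError(
            f"{path}: family {fam}: expected exactly one mother, found "
            f"{len(mothers)} ({mothers or 'none'})"
        )
    if not offspring_order:
        raise BroodTableError(f"{path}: family {fam}: no offspring rows")

    locus_set = set(loci)
    for indiv, per_indiv in calls.items():
        if set(per_indiv) != locus_set:
            absent = sorted(locus_set - set(per_indiv))
            raise BroodTableError(
                f"{path}: family {fam}: individual {indiv} lacks rows for "
                f"loci {absent}; locus sets must be consistent within a family"
            )

    def genotypes(indiv: str) -> IndividualGenotypes:
        return IndividualGenotypes(indiv, {loc: calls[indiv][loc][1] for loc in loci})

    return Brood(
        family_id=fam,
        species=species,
        loci=tuple(loci),
        mother=genotypes(mothers[0]),
        offspring=tuple(genotypes(o) for o in offspring_order),
    )


def write_brood_table(broods: Iterable[Brood], path: str | Path) -> None:
    """Write broods to the brood CSV dialect; inverse of :func:`read_brood_table`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BROOD_COLUMNS)
        for brood in broods:
            for indiv, role in [(brood.mother, "mother")] + [
                (o, "offspring") for o in brood.offspring
            ]:
                for locus in brood.loci:
                    call = indiv.calls[locus]
                    if call.missing:
                        a1 = a2 = ""
                    elif call.from_single_allele:
                        a1, a2 = call.alleles[0], ""
                    else:
                        a1, a2 = call.alleles
                    writer.writerow(
                        [brood.family_id, brood.species, indiv.individual_id,
                         role, locus, a1, a2]
                    )


# ---------------------------------------------------------------------------
# Allele count tables
# ---------------------------------------------------------------------------

_ASE_REQUIRED = ("contig", "position", "refCount", "altCount", "otherBases")
_MINIMAL_REQUIRED = ("sample", "contig", "position", "ref_count", "alt_count", "other_count")


def _parse_count(value: str, name: str, lineno: int, path: Path) -> int:
    try:
        n = int(value)
    except (TypeError, ValueError):
        raise CountTableError(f"{path}: line {lineno}: malformed {name} {value!r}") from None
    if n < 0:
        raise CountTableError(f"{path}: line {lineno}: negative {name} ({n})")
    return n


_TRUTHY = {"1", "true", "yes", "t"}


def read_ase_counts(path: str | Path, sample_id: str | None = None) -> list[SnpCounts]:
    """Read per-SNP allele counts from either supported dialect.

    The dialect is detected from the header: a tab-separated table with
    ``refCount``/``altCount``/``otherBases`` columns is treated as GATK
    ASEReadCounter output (*sample_id* then names the sample, defaulting to
    the file stem), while a comma-separated table with a ``sample`` column is
    the package's minimal dialect.  Rows flagged in an optional
    ``multiallelic`` column are dropped (multiallelic SNPs are excluded from
    the bias analysis).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        delim = "\t" if "\t" in first else ","
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        if all(c in header for c in _ASE_REQUIRED):
            dialect = "asereadcounter"
            sid_default = sample_id if sample_id is not None else path.stem
        elif all(c in header for c in _MINIMAL_REQUIRED):
            dialect = "minimal"
            sid_default = sample_id
        else:
            raise CountTableError(
                f"{path}: header matches neither the ASEReadCounter dialect "
                f"{_ASE_REQUIRED} nor the minimal dialect {_MINIMAL_REQUIRED}"
            )

        out: list[SnpCounts] = []
        for lineno, row in enumerate(reader, start=2):
            if (row.get("multiallelic") or "").strip().lower() in _TRUTHY:
                continue
            if dialect == "asereadcounter":
                sid = sid_default
                ref = _parse_count(row["refCount"], "refCount", lineno, path)
                alt = _parse_count(row["altCount"], "altCount", lineno, path)
                other = _parse_count(row["otherBases"], "otherBases", lineno, path)
            else:
                sid = row["sample"] if sample_id is None else sample_id
                ref = _parse_count(row["ref_count"], "ref_count", lineno, path)
                alt = _parse_count(row["alt_count"], "alt_count", lineno, path)
                other = _parse_count(row["other_count"], "other_count", lineno, path)
            contig = (row["contig"] or "").strip()
            if not contig:
                raise CountTableError(f"{path}: line {lineno}: empty contig")
            pos = _parse_count(row["position"], "position", lineno, path)
            if pos < 1:
                raise CountTableError(f"{path}: line {lineno}: position must be 1-based")
            try:
                out.append(SnpCounts(str(sid), contig, pos, ref, alt, other))
            except ValueError as exc:
                raise CountTableError(f"{path}: line {lineno}: {exc}") from None
        return out


def write_ase_counts(counts: Sequence[SnpCounts], path: str | Path) -> None:
    """Write counts in the minimal CSV dialect (inverse of :func:`read_ase_counts`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MINIMAL_REQUIRED)
        for c in counts:
            writer.writerow(
                [c.sample_id, c.contig, c.position, c.ref_count, c.alt_count, c.other_count]
            )
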
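"""Karyotype definitions and I/O for per-chromosome count tables.

This module owns the three data structures everything else consumes:

* :class:`Karyotype` — the chromosome universe: names, lengths, roles
  (autosome / shared sex chromosome / sex-limited chromosome / excluded)
  and the sex-determination system (XY or ZW).
* :class:`IdxstatsTable` — per-reference mapped/unmapped counts for one
  sample, in the ``samtools idxstats`` 4-column dialect.
* :class:`JoinedCounts` — the inner join of the two, with lengths taken
  from the karyotype, ready for the ratio computation.

Karyotypes can be built from a FASTA index (``.fai``) plus a naming rule,
or round-tripped through a small tab-separated config file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from rxsex.errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

# Relative length disagreement between idxstats and karyotype that triggers
# a warning when joining.
LENGTH_MISMATCH_TOL = 1e-3


class Role(str, Enum):
    """Role of a reference sequence within a karyotype."""

    AUTOSOME = "autosome"
    SHARED_SEX = "shared_sex"  # X in XY systems, Z in ZW systems
    LIMITED_SEX = "limited_sex"  # Y in XY systems, W in ZW systems
    EXCLUDED = "excluded"  # mitochondrion, unplaced scaffolds, ...


@dataclass(frozen=True)
class ChromosomeRecord:
    """One reference sequence: its name, length in bp, and role."""

    name: str
    length: int
    role: Role

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("chromosome name must be nonempty")
        if self.length <= 0:
            raise ValidationError(
                f"chromosome {self.name!r}: length must be positive, got {self.length}"
            )


@dataclass(frozen=True)
class Karyotype:
    """An ordered set of chromosome records plus the sex-determination system.

    Invariants enforced at construction: unique nonempty names, exactly one
    shared sex chromosome, at most one sex-limited chromosome, and at least
    three autosomes (the SE needs >=2 ratio terms and the coverage regression
    needs residual degrees of freedom).
    """

    chromosomes: tuple[ChromosomeRecord, ...]
    system: str = "XY"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if self.system not in ("XY", "ZW"):
            raise ConfigurationError(f"system must be 'XY' or 'ZW', got {self.system!r}")
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate chromosome names: {dupes}")
        n_shared = sum(c.role is Role.SHARED_SEX for c in self.chromosomes)
        if n_shared != 1:
            raise ConfigurationError(
                f"karyotype must have exactly one shared sex chromosome, got {n_shared}"
            )
        n_limited = sum(c.role is Role.LIMITED_SEX for c in self.chromosomes)
        if n_limited > 1:
            raise ConfigurationError(
                f"karyotype may have at most one sex-limited chromosome, got {n_limited}"
            )
        if len(self.autosomes) < 3:
            raise ConfigurationError(
                f"karyotype needs at least 3 autosomes, got {len(self.autosomes)}"
            )

    @property
    def autosomes(self) -> tuple[ChromosomeRecord, ...]:
        return tuple(c for c in self.chromosomes if c.role is Role.AUTOSOME)

    @property
    def shared_sex(self) -> ChromosomeRecord:
        return next(c for c in self.chromosomes if c.role is Role.SHARED_SEX)

    @property
    def limited_sex(self) -> ChromosomeRecord | None:
        return next((c for c in self.chromosomes if c.role is Role.LIMITED_SEX), None)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def __getitem__(self, name: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class IdxstatsRow:
    """One row of an idxstats table.

    ``mapped`` is a float so that noise-free simulated tables (which carry
    exact expected counts) can be represented; tables read from disk always
    hold integers.
    """

    name: str
    length: int
    mapped: float
    unmapped: float = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("reference name must be nonempty")
        if self.length <= 0:
            raise ValidationError(
                f"reference {self.name!r}: length must be positive, got {self.length}"
            )
        if self.mapped < 0 or self.unmapped < 0:
            raise ValidationError(
                f"reference {self.name!r}: counts must be nonnegative"
            )


@dataclass
class IdxstatsTable:
    """Per-reference mapped/unmapped counts for one sample.

    The unaligned placeholder row (``*``) of the samtools dialect is never
    stored; input order is preserved.
    """

    rows: list[IdxstatsRow]
    sample_id: str = ""

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate reference names: {dupes}")
        if any(r.name == "*" for r in self.rows):
            raise ValidationError("the '*' placeholder row must not be stored")

    @property
    def total_mapped(self) -> float:
        return sum(r.mapped for r in self.rows)

    def mapped_by_name(self) -> dict[str, float]:
        return {r.name: r.mapped for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class JoinedRecord:
    """A chromosome after joining counts with the karyotype."""

    name: str
    length: int
    role: Role
    mapped: float


@dataclass(frozen=True)
class JoinedCounts:
    """Output of :func:`join_counts`: non-excluded chromosomes with counts.

    Carries the sex-determination system and sample id through to the
    statistic so downstream code needs no extra context.
    """

    records: tuple[JoinedRecord, ...]
    system: str
    sample_id: str = ""

    @property
    def autosome_records(self) -> tuple[JoinedRecord, ...]:
        return tuple(r for r in self.records if r.role is Role.AUTOSOME)

    @property
    def shared_sex_record(self) -> JoinedRecord:
        return next(r for r in self.records if r.role is Role.SHARED_SEX)


# ---------------------------------------------------------------------------
# idxstats I/O
# ---------------------------------------------------------------------------

def read_idxstats(path: Union[str, Path], sample_id: str = "") -> IdxstatsTable:
    """Read a samtools ``idxstats`` text file.

    Expects >=4 tab-separated columns per line (name, length, mapped,
    unmapped); extra trailing columns are tolerated and ignored. The ``*``
    placeholder row is dropped. Raises :class:`ParseError` naming the line
    number on malformed input and :class:`ValidationError` on an empty file
    or negative counts.
    """
    path = Path(path)
    if not sample_id:
        sample_id = path.stem
    rows: list[IdxstatsRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            try:
                length = int(fields[1])
                mapped = int(fields[2])
                unmapped = int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if name == "*":
                continue
            if mapped < 0 or unmapped < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative read count"
                )
            rows.append(IdxstatsRow(name, length, mapped, unmapped))
    if not rows:
        raise ValidationError(f"{path}: no references")
    return IdxstatsTable(rows=rows, sample_id=sample_id)


def write_idxstats(table: IdxstatsTable, path: Union[str, Path]) -> None:
    """Write a table in idxstats text format (no ``*`` row).

    Float counts from noise-free simulation are written with full precision;
    integral values are written as plain integers so that tables produced
    from real data round-trip byte-identically.
    """
    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    with open(path, "w") as fh:
        for r in table.rows:
            fh.write(f"{r.name}\t{r.length}\t{fmt(r.mapped)}\t{fmt(r.unmapped)}\n")


# ---------------------------------------------------------------------------
# Karyotype construction and I/O
# ---------------------------------------------------------------------------

def karyotype_from_fai(
    path: Union[str, Path],
    shared_sex_name: str,
    autosomes: Union[Sequence[str], str],
    system: str = "XY",
    limited_sex_name: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Karyotype:
    """Build a :class:`Karyotype` from a FASTA index (``.fai``) file.

    Parameters
    ----------
    path
        ``.fai`` file; only the first two columns (name, length) are used.
    shared_sex_name
        Name of the X (or Z) chromosome in the index.
    autosomes
        Either an explicit list of names or a regular expression that a name
        must fully match to be treated as an autosome.
    system
        ``"XY"`` or ``"ZW"``.
    limited_sex_name
        Optional name of the Y (or W) chromosome.
    aliases
        Optional mapping from names as they appear in the index to canonical
        names (e.g. ``{"X": "chrX"}``); applied before role assignment.

    Every reference not matched as autosome or sex chromosome gets role
    ``excluded``. Order of the index file is preserved.
    """
    path = Path(path)
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields"
                )
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[0]
            if aliases and name in aliases:
                name = aliases[name]
            entries.append((name, length))
    if not entries:
        raise ValidationError(f"{path}: no references")

    if isinstance(autosomes, str):
        pattern = re.compile(autosomes)
        is_autosome = lambda name: pattern.fullmatch(name) is not None  # noqa: E731
    else:
        wanted = set(autosomes)
        is_autosome = lambda name: name in wanted  # noqa: E731

    names = {name for name, _ in entries}
    if shared_sex_name not in names:
        raise ConfigurationError(
            f"shared sex chromosome {shared_sex_name!r} not found in {path}"
        )
    if limited_sex_name is not None and limited_sex_name not in names:
        raise ConfigurationError(
            f"sex-limited chromosome {limited_sex_name!r} not found in {path}"
        )

    records = []
    for name, length in entries:
        if name == shared_sex_name:
            role = Role.SHARED_SEX
        elif limited_sex_name is not None and name == limited_sex_name:
            role = Role.LIMITED_SEX
        elif is_autosome(name):
            role = Role.AUTOSOME
        else:
            role = Role.EXCLUDED
        records.append(ChromosomeRecord(name, length, role))

    n_autosomes = sum(r.role is Role.AUTOSOME for r in records)
    if n_autosomes < 3:
        raise ConfigurationError(
            f"only {n_autosomes} autosomes matched in {path}; need at least 3"
        )
    return Karyotype(chromosomes=tuple(records), system=system)


def write_karyotype(karyotype: Karyotype, path: Union[str, Path]) -> None:
    """Write a karyotype as a tab-separated config file.

    Format: a ``#system<TAB><XY|ZW>`` header line followed by one
    ``name<TAB>length<TAB>role`` row per chromosome, in order.
    """
    with open(path, "w") as fh:
        fh.write(f"#system\t{karyotype.system}\n")
        for c in karyotype.chromosomes:
            fh.write(f"{c.name}\t{c.length}\t{c.role.value}\n")


def read_karyotype(path: Union[str, Path]) -> Karyotype:
    """Read a karyotype config written by :func:`write_karyotype`."""
    path = Path(path)
    system = "XY"
    records: list[ChromosomeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#system"):
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{path}: line {lineno}: bad system header")
                system = parts[1]
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            name, length_s, role_s = fields
            try:
                length = int(length_s)
                role = Role(role_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(ChromosomeRecord(name, length, role))
    if not records:
        raise ValidationError(f"{path}: no chromosomes")
    return Karyotype(chromosomes=tuple(records), system=system)


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------

def join_counts(table: IdxstatsTable, karyotype: Karyotype) -> JoinedCounts:
    """Join a count table against a karyotype by chromosome name.

    Lengths are taken from the karyotype (the authority); a disagreement of
    more than 0.1% with the table's length is logged as a warning. Excluded
    chromosomes are dropped, extra table rows not in the karyotype are
    ignored (logged at debug level). A missing autosome or shared sex
    chromosome is a hard error listing the missing names.
    """
    mapped = table.mapped_by_name()
    lengths = {r.name: r.length for r in table.rows}

    missing = [
        c.name
        for c in karyotype.chromosomes
        if c.role in (Role.AUTOSOME, Role.SHARED_SEX) and c.name not in mapped
    ]
    if missing:
        raise ValidationError(
            f"sample {table.sample_id!r}: chromosomes missing from idxstats table: "
            + ", ".join(missing)
        )

    records: list[JoinedRecord] = []
    for c in karyotype.chromosomes:
        if c.role is Role.EXCLUDED:
            continue
        if c.name not in mapped:  # absent sex-limited chromosome is tolerated
            continue
        table_length = lengths[c.name]
        if abs(table_length - c.length) > LENGTH_MISMATCH_TOL * c.length:
            logger.warning(
                "sample %r: length mismatch for %s: table has %d, karyotype has %d",
                table.sample_id, c.name, table_length, c.length,
            )
        records.append(JoinedRecord(c.name, c.length, c.role, mapped[c.name]))

    extra = set(mapped) - set(karyotype.names)
    if extra:
        logger.debug(
            "sample %r: %d references not in karyotype ignored",
            table.sample_id, len(extra),
        )
    return JoinedCounts(
        records=tuple(records), system=karyotype.system, sample_id=table.sample_id
    )
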
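"""Domain types and readers/writers for sequences, epitope tables and group configs.

Coordinate convention: all epitope and region positions are 1-based
inclusive, matching the convention of published epitope tables
("1-15" is a 15-mer starting at the first residue). Converters to
0-based half-open indices exist only at internal slicing boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from epiconserve import _fixtures

ALLERGENS = ("TM", "AK", "MLC", "SCBP")
GROUPS = ("crustacean", "cockroach", "mite", "mollusc")
MOLLUSC_CLASSES = ("bivalve", "cephalopod", "gastropod")

#: the 20 standard residue letters; epitope peptides must use these only
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: protein sequences may additionally carry the ambiguity letter X,
#: which is always scored as a mismatch (conservative handling of
#: database ambiguity codes); other non-standard letters are rejected
SEQUENCE_AA = STANDARD_AA | frozenset("X")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FastaParseError(ValueError):
    """A FASTA file is malformed or carries an invalid sequence/tag."""


@dataclass(frozen=True)
class EpitopeRecord:
    """One IgE-binding epitope peptide with its source allergen and span.

    ``start``/``end`` are 1-based inclusive positions in the source
    allergen; when both are present, ``end - start + 1`` must equal the
    peptide length.
    """

    epitope_id: str
    allergen: str
    peptide: str
    start: int | None = None
    end: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", self.peptide.upper())
        if not self.epitope_id:
            raise ValidationError("epitope_id must be non-empty")
        if self.allergen not in ALLERGENS:
            raise ValidationError(
                f"epitope {self.epitope_id!r}: unknown allergen {self.allergen!r} "
                f"(expected one of {ALLERGENS})"
            )
        if len(self.peptide) < 1:
            raise ValidationError(f"epitope {self.epitope_id!r}: empty peptide")
        bad = set(self.peptide) - STANDARD_AA
        if bad:
            raise ValidationError(
                f"epitope {self.epitope_id!r}: non-standard residue letters {sorted(bad)}"
            )
        if (self.start is None) != (self.end is None):
            raise ValidationError(
                f"epitope {self.epitope_id!r}: start and end must be given together"
            )
        if self.start is not None:
            if self.start < 1:
                raise ValidationError(
                    f"epitope {self.epitope_id!r}: start must be >= 1, got {self.start}"
                )
            span = self.end - self.start + 1
            if span != len(self.peptide):
                raise ValidationError(
                    f"epitope {self.epitope_id!r}: span {self.start}-{self.end} "
                    f"covers {span} residues but peptide has {len(self.peptide)}"
                )

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class ProteinEntry:
    """One homolog sequence with species identity and group labels.

    ``mollusc_class`` must be present exactly when ``group`` is
    ``"mollusc"``. ``species`` defaults to the accession so that
    single-isoform inputs need no extra bookkeeping.
    """

    accession: str
    sequence: str
    species: str = ""
    group: str | None = None
    mollusc_class: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.species:
            object.__setattr__(self, "species", self.accession)
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"protein {self.accession!r}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_AA
        if bad:
            raise ValidationError(
                f"protein {self.accession!r}: invalid residue letters {sorted(bad)}"
            )
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(
                f"protein {self.accession!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.mollusc_class is not None and self.mollusc_class not in MOLLUSC_CLASSES:
            raise ValidationError(
                f"protein {self.accession!r}: unknown mollusc class "
                f"{self.mollusc_class!r} (expected one of {MOLLUSC_CLASSES})"
            )
        if (self.group == "mollusc") != (self.mollusc_class is not None):
            raise ValidationError(
                f"protein {self.accession!r}: mollusc_class must be present "
                "exactly when group == 'mollusc'"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GroupConfig:
    """Taxonomic group assignments for a homolog set.

    ``groups`` maps a group label to the species it contains;
    ``species_of`` maps accessions to species so that multiple isoforms
    of one species can be collapsed; ``mollusc_classes`` maps each
    mollusc class to its species.
    """

    groups: dict[str, list[str]]
    species_of: dict[str, str] = field(default_factory=dict)
    mollusc_classes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("GroupConfig: no groups defined")
        seen: dict[str, str] = {}
        for g, members in self.groups.items():
            if not members:
                raise ValidationError(f"GroupConfig: group {g!r} is empty")
            for sp in members:
                if sp in seen:
                    raise ValidationError(
                        f"GroupConfig: species {sp!r} assigned to both "
                        f"{seen[sp]!r} and {g!r}"
                    )
                seen[sp] = g

    def species(self, accession: str) -> str:
        return self.species_of.get(accession, accession)

    def group_of(self, species: str) -> str:
        for g, members in self.groups.items():
            if species in members:
                return g
        raise KeyError(f"species {species!r} not assigned to any group")

    def class_of(self, species: str) -> str | None:
        for c, members in self.mollusc_classes.items():
            if species in members:
                return c
        return None

    @classmethod
    def from_entries(cls, entries: Iterable[ProteinEntry]) -> "GroupConfig":
        """Build a config from group/class labels carried on the entries."""
        groups: dict[str, list[str]] = {}
        species_of: dict[str, str] = {}
        classes: dict[str, list[str]] = {}
        for e in entries:
            if e.group is None:
                raise ValidationError(
                    f"protein {e.accession!r} has no group label; supply a "
                    "GroupConfig explicitly"
                )
            species_of[e.accession] = e.species
            groups.setdefault(e.group, [])
            if e.species not in groups[e.group]:
                groups[e.group].append(e.species)
            if e.mollusc_class is not None:
                classes.setdefault(e.mollusc_class, [])
                if e.species not in classes[e.mollusc_class]:
                    classes[e.mollusc_class].append(e.species)
        return cls(groups=groups, species_of=species_of, mollusc_classes=classes)

    @classmethod
    def from_file(cls, path: str | Path) -> "GroupConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(data, dict) or "groups" not in data:
            raise ValidationError(f"{path}: expected a mapping with a 'groups' key")
        return cls(
            groups={g: list(m) for g, m in data["groups"].items()},
            species_of=dict(data.get("species_of", {})),
            mollusc_classes={
                c: list(m) for c, m in data.get("mollusc_classes", {}).items()
            },
        )

    def to_file(self, path: str | Path) -> None:
        data = {"groups": self.groups}
        if self.species_of:
            data["species_of"] = self.species_of
        if self.mollusc_classes:
            data["mollusc_classes"] = self.mollusc_classes
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class FixtureTable:
    """A packaged epitope table with its published presentation percentages."""

    name: str
    records: tuple[EpitopeRecord, ...]
    #: index = epitope_id, columns = the four invertebrate groups, values in [0, 100]
    presentation: pd.DataFrame

    def __post_init__(self) -> None:
        if ((self.presentation < 0) | (self.presentation > 100)).any().any():
            raise ValidationError(f"fixture {self.name!r}: percentage outside [0, 100]")


# ---------------------------------------------------------------------------
# FASTA

def _parse_header_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value
    return tags


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read homolog sequences from FASTA.

    Headers carry the accession as the record id plus optional
    ``species=…``, ``group=…`` and ``class=…`` key=value tags. Sequences
    are uppercased; record order is preserved. Malformed input raises
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    # line-aware pre-scan for diagnostics SeqIO cannot give
    saw_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            saw_header = True
            continue
        if not saw_header:
            raise FastaParseError(f"{path}: line {lineno}: sequence data before header")
        bad = set(stripped.upper()) - SEQUENCE_AA
        if bad:
            raise FastaParseError(
                f"{path}: line {lineno}: invalid sequence characters {sorted(bad)}"
            )
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        tags = _parse_header_tags(record.description)
        group = tags.get("group")
        if group is not None and group not in GROUPS:
            raise ValidationError(
                f"{path}: record {record.id!r}: unknown group tag {group!r}"
            )
        try:
            entries.append(
                ProteinEntry(
                    accession=record.id,
                    sequence=str(record.seq),
                    species=tags.get("species", ""),
                    group=group,
                    mollusc_class=tags.get("class"),
                )
            )
        except ValidationError as exc:
            raise FastaParseError(f"{path}: record {record.id!r}: {exc}") from exc
    return entries


def write_fasta(entries: Sequence[ProteinEntry], path: str | Path) -> None:
    """Write entries as FASTA with species/group/class key=value header tags."""
    records = []
    for e in entries:
        desc = [f"species={e.species}"]
        if e.group is not None:
            desc.append(f"group={e.group}")
        if e.mollusc_class is not None:
            desc.append(f"class={e.mollusc_class}")
        records.append(
            SeqRecord(Seq(e.sequence), id=e.accession, description=" ".join(desc))
        )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA as (id, gapped sequence) pairs, uppercased.

    Gap characters ``-`` and ``.`` are permitted; all sequences must
    have equal aligned length.
    """
    pairs = [
        (record.id, str(record.seq).upper())
        for record in SeqIO.parse(str(path), "fasta")
    ]
    if not pairs:
        return []
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise FastaParseError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    allowed = SEQUENCE_AA | frozenset("-.")
    for rid, seq in pairs:
        bad = set(seq) - allowed
        if bad:
            raise FastaParseError(
                f"{path}: record {rid!r}: invalid characters {sorted(bad)}"
            )
    return pairs


# ---------------------------------------------------------------------------
# Epitope tables

EPITOPE_COLUMNS = ("epitope_id", "allergen", "peptide", "start", "end")


def _records_from_frame(df: pd.DataFrame, origin: str) -> list[EpitopeRecord]:
    missing = [c for c in EPITOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{origin}: missing columns {missing}")
    records = []
    errors = []
    for i, row in df.iterrows():
        start = row["start"]
        end = row["end"]
        try:
            records.append(
                EpitopeRecord(
                    epitope_id=str(row["epitope_id"]),
                    allergen=str(row["allergen"]),
                    peptide=str(row["peptide"]),
                    start=None if pd.isna(start) else int(start),
                    end=None if pd.isna(end) else int(end),
                    source=(
                        ""
                        if "source" not in df.columns or pd.isna(row["source"])
                        else str(row["source"])
                    ),
                )
            )
        except ValidationError as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header line and 1-basing
    if errors:
        raise ValidationError(f"{origin}: " + "; ".join(errors))
    ids = [r.epitope_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"{origin}: duplicate epitope ids {dupes}")
    return records


def read_epitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read a TSV epitope table (columns epitope_id, allergen, peptide, start, end)."""
    df = pd.read_csv(path, sep="\t")
    return _records_from_frame(df, str(path))


def write_epitope_table(records: Sequence[EpitopeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "epitope_id": [r.epitope_id for r in records],
            "allergen": [r.allergen for r in records],
            "peptide": [r.peptide for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures

def load_fixture(name: str) -> FixtureTable:
    """Load a packaged epitope table (``table1_tm`` or ``table2_ak``).

    Returns the records together with the published per-group
    presentation percentages, exactly as printed. Pure function: calling
    twice returns identical content.
    """
    try:
        raw = _fixtures.FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_fixtures.FIXTURES)}"
        ) from None
    df = pd.read_csv(io.StringIO(raw), sep="\t")
    records = tuple(_records_from_frame(df, f"fixture {name}"))
    presentation = df.set_index("epitope_id")[list(GROUPS)].astype(float)
    return FixtureTable(name=name, records=records, presentation=presentation)
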
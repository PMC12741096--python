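"""Reading, validating and writing trio tables.

Trio data is the standard register/biobank pedigree encoding: one row per
individual listing their own ID together with the father's and mother's IDs.
Parents referenced without a row of their own are legal (registers routinely
truncate ascending lineages) and become founder nodes at graph build time.

Missing parents are represented in memory as ``None``; on ingest any ID
matching one of the configured missing codes (default ``"NA"``, ``""``,
``"0"``) is mapped to ``None``, and on output ``None`` is written as the
first configured missing code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

import pandas as pd

from .errors import AmbiguousParentError, TrioFormatError, TrioValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .pedigree_graph import PedigreeGraph

MISSING = None

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"
SEX_CODES = (FEMALE, MALE, UNKNOWN)

#: Order matters: the first code is the one written for missing parents.
DEFAULT_MISSING_CODES: tuple[str, ...] = ("NA", "", "0")

#: Default header names for delimited trio files.
DEFAULT_ID_COLUMNS: tuple[str, str, str] = ("id", "dad_id", "mom_id")
DEFAULT_SEX_COLUMN = "sex"

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "m": MALE, "male": MALE, "1": MALE,
    "u": UNKNOWN, "unknown": UNKNOWN, "0": UNKNOWN,
}

_PLINK_SEX = {"1": MALE, "2": FEMALE}
_PLINK_SEX_OUT = {MALE: "1", FEMALE: "2", UNKNOWN: "0", None: "0"}


@dataclass
class TrioRecord:
    """One individual's row: own ID, parent IDs, optional sex and attributes."""

    individual_id: str
    father_id: str | None = MISSING
    mother_id: str | None = MISSING
    sex: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.individual_id, str) or not self.individual_id:
            raise TrioValidationError(
                f"individual_id must be a non-empty string, got {self.individual_id!r}"
            )
        if self.individual_id in (self.father_id, self.mother_id):
            raise TrioValidationError(
                f"self-parentage: {self.individual_id!r} is listed as its own parent"
            )
        if self.father_id is not MISSING and self.father_id == self.mother_id:
            raise TrioValidationError(
                f"record {self.individual_id!r}: father_id equals mother_id "
                f"({self.father_id!r})"
            )
        if self.sex is not None and self.sex not in SEX_CODES:
            raise TrioValidationError(
                f"record {self.individual_id!r}: sex must be one of {SEX_CODES}, "
                f"got {self.sex!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is MISSING and self.mother_id is MISSING


@dataclass
class TrioTable:
    """An ordered collection of :class:`TrioRecord` with unique individual IDs."""

    records: list[TrioRecord]
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES

    def __post_init__(self) -> None:
        self.missing_codes = tuple(self.missing_codes)
        seen: set[str] = set()
        dupes: list[str] = []
        for rec in self.records:
            if rec.individual_id in seen:
                dupes.append(rec.individual_id)
            seen.add(rec.individual_id)
        if dupes:
            raise TrioValidationError("duplicate individual_id", sorted(set(dupes)))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrioRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [rec.individual_id for rec in self.records]

    def attribute_names(self) -> list[str]:
        names: dict[str, None] = {}
        for rec in self.records:
            for key in rec.attributes:
                names.setdefault(key)
        return list(names)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form view with one column per ID field, sex and attribute."""
        rows = []
        for rec in self.records:
            row = {
                "id": rec.individual_id,
                "dad_id": rec.father_id,
                "mom_id": rec.mother_id,
                "sex": rec.sex,
            }
            row.update(rec.attributes)
            rows.append(row)
        return pd.DataFrame(rows)


def _normalize_sex(value: str | None, missing: frozenset[str]) -> str | None:
    if value is None or value in missing:
        return None
    return _SEX_ALIASES.get(value.strip().lower(), None) or (
        value if value in SEX_CODES else UNKNOWN
    )


def read_trios(
    path: str | Path,
    format: str = "csv",
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    id_columns: tuple[str, str, str] = DEFAULT_ID_COLUMNS,
    sex_column: str | None = DEFAULT_SEX_COLUMN,
) -> TrioTable:
    """Read a trio table from delimited text or a PLINK ``.fam`` file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"csv"``, ``"tsv"`` (header with named columns) or ``"plink_fam"``
        (whitespace-delimited, headerless ``FID IID PAT MAT SEX PHENO``).
    missing_codes
        IDs matching any of these strings become missing parents.
    id_columns
        Names of the (individual, father, mother) columns for csv/tsv.
    sex_column
        Name of the sex column for csv/tsv, or ``None`` to ignore sex.
        Accepted encodings: female/f/2, male/m/1, unknown/u/0.

    All IDs are coerced to strings; every non-ID, non-sex column is carried
    verbatim as a per-individual attribute.
    """
    path = Path(path)
    missing_codes = tuple(missing_codes)
    missing = frozenset(missing_codes)

    if format == "plink_fam":
        return _read_plink_fam(path, missing_codes)
    if format not in ("csv", "tsv"):
        raise TrioFormatError(f"unknown trio format {format!r}")

    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in id_columns:
        if col not in df.columns:
            raise TrioFormatError(f"{path}: required column {col!r} not found")

    id_col, dad_col, mom_col = id_columns
    attr_cols = [
        c for c in df.columns if c not in (id_col, dad_col, mom_col, sex_column)
    ]
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        records.append(
            TrioRecord(
                individual_id=str(row[id_col]),
                father_id=_coerce_id(row[dad_col], missing),
                mother_id=_coerce_id(row[mom_col], missing),
                sex=_normalize_sex(row.get(sex_column), missing)
                if sex_column in df.columns
                else None,
                attributes={c: row[c] for c in attr_cols},
            )
        )
    return TrioTable(records, missing_codes)


def _coerce_id(value, missing: frozenset[str]) -> str | None:
    value = str(value)
    return MISSING if value in missing else value


def _read_plink_fam(path: Path, missing_codes: tuple[str, ...]) -> TrioTable:
    missing = frozenset(missing_codes) | {"0"}  # 0 is the PLINK missing-parent code
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise TrioFormatError(
                    f"{path}:{lineno}: expected 6 whitespace-delimited columns "
                    f"(FID IID PAT MAT SEX PHENO), got {len(fields)}"
                )
            fid, iid, pat, mat, sex, pheno = fields[:6]
            records.append(
                TrioRecord(
                    individual_id=iid,
                    father_id=_coerce_id(pat, missing),
                    mother_id=_coerce_id(mat, missing),
                    sex=_PLINK_SEX.get(sex, UNKNOWN),
                    attributes={"fid": fid, "phenotype": pheno},
                )
            )
    return TrioTable(records, missing_codes)


def write_trios(table: TrioTable, path: str | Path, format: str = "csv") -> Path:
    """Write a trio table; missing parents become the first configured
    missing code (``"0"`` in PLINK output regardless)."""
    path = Path(path)
    if format == "plink_fam":
        with open(path, "w") as fh:
            for rec in table:
                fh.write(
                    " ".join(
                        (
                            str(rec.attributes.get("fid", rec.individual_id)),
                            rec.individual_id,
                            rec.father_id or "0",
                            rec.mother_id or "0",
                            _PLINK_SEX_OUT.get(rec.sex, "0"),
                            str(rec.attributes.get("phenotype", "-9")),
                        )
                    )
                    + "\n"
                )
        return path
    if format not in ("csv", "tsv"):
        raise TrioFormatError(f"unknown trio format {format!r}")

    sep = "," if format == "csv" else "\t"
    na = table.missing_codes[0] if table.missing_codes else "NA"
    attr_names = table.attribute_names()
    header = list(DEFAULT_ID_COLUMNS) + [DEFAULT_SEX_COLUMN] + attr_names
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(header)
        for rec in table:
            writer.writerow(
                [
                    rec.individual_id,
                    rec.father_id if rec.father_id is not MISSING else na,
                    rec.mother_id if rec.mother_id is not MISSING else na,
                    rec.sex if rec.sex is not None else na,
                ]
                + [rec.attributes.get(a, na) for a in attr_names]
            )
    return path


def graph_to_trio(graph: "PedigreeGraph", on_ambiguity: str = "error") -> TrioTable:
    """Reconstruct the trio table that produced a pedigree graph.

    Father/mother roles are assigned from the ``sex`` attribute of each
    parent node, so the result is usable by pedigree packages that expect
    sexed trios. Sibling edges are ignored: they are derivable from the
    parental edges.

    Parameters
    ----------
    graph
        Any pedigree graph; nodes that are the source of a parental edge
        must carry ``sex`` in ``{"female", "male"}`` unless
        ``on_ambiguity="set_missing"``.
    on_ambiguity
        ``"error"`` (default): raise when a parent's sex is unknown.
        ``"set_missing"``: silently drop the unassignable parent reference.
    """
    if on_ambiguity not in ("error", "set_missing"):
        raise ValueError(f"on_ambiguity must be 'error' or 'set_missing', got {on_ambiguity!r}")
    records = []
    for node in graph.nodes:
        attrs = dict(graph.node_attributes(node))
        sex = attrs.pop("sex", None)
        father = mother = MISSING
        for parent in graph.parent_ids(node):
            psex = graph.node_attributes(parent).get("sex")
            if psex == MALE:
                if father is not MISSING:
                    raise AmbiguousParentError(
                        f"individual {node!r} has two male parents: {father!r}, {parent!r}"
                    )
                father = parent
            elif psex == FEMALE:
                if mother is not MISSING:
                    raise AmbiguousParentError(
                        f"individual {node!r} has two female parents: {mother!r}, {parent!r}"
                    )
                mother = parent
            elif on_ambiguity == "error":
                raise AmbiguousParentError(
                    f"parent {parent!r} has no usable sex attribute; cannot assign "
                    f"father/mother for {node!r} (use on_ambiguity='set_missing' to drop)"
                )
        records.append(
            TrioRecord(
                individual_id=node,
                father_id=father,
                mother_id=mother,
                sex=sex,
                attributes=attrs,
            )
        )
    return TrioTable(records)
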
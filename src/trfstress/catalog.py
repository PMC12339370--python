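"""tRF identity, tDR name parsing, cleavage classification and family keying.

tRNA fragments (tRFs) are 16-50 nt cleavage products of pre- and mature
tRNAs.  A *family* groups fragments that share genome origin (nuclear vs
mitochondrial), parental tRNA coded amino acid, and cleavage type; it is
the unit of the directional trend analysis in :mod:`trfstress.families`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The five cleavage types, ordered 5' -> 3' along the mature tRNA.
CLEAVAGE_TYPES = ("5p-tRF", "5p-half", "i-tRF", "3p-half", "3p-tRF")

#: Genome origins; nuclear first in the canonical ordering.
ORIGINS = ("Nuc", "MT")

MIN_TRF_LEN = 16
MAX_TRF_LEN = 50

_CLEAVAGE_RANK = {c: i for i, c in enumerate(CLEAVAGE_TYPES)}
_ORIGIN_RANK = {o: i for i, o in enumerate(ORIGINS)}

_TDR_RE = re.compile(
    r"^(?P<prefix>mtDR|tDR)-(?P<start>\d+):(?P<end>\d+)"
    r"-(?P<aa>[A-Z][a-z]{2})-(?P<anticodon>[A-Zacgtu]{3})-(?P<suffix>\S+)$"
)


class TDRNameError(ValueError):
    """Raised when a tDR-style identifier does not match the name grammar."""


class FamilyKey(NamedTuple):
    """Family identity: genome origin x amino acid x cleavage type."""

    genome_origin: str
    amino_acid: str
    cleavage_type: str

    @property
    def sort_key(self) -> tuple[int, str, int]:
        return (
            _ORIGIN_RANK[self.genome_origin],
            self.amino_acid,
            _CLEAVAGE_RANK[self.cleavage_type],
        )

    def __str__(self) -> str:  # e.g. "MT-Gly-i-tRF"
        return f"{self.genome_origin}-{self.amino_acid}-{self.cleavage_type}"


@dataclass
class TRFAnnotation:
    """One fragment's identity.

    ``length`` must be in [16, 50] and, when a sequence is present, equal its
    nucleotide count.  ``name_coords`` keeps the start:end coordinates from a
    tDR-style name; these are structural (Sprinzl-like) positions and are
    never used to derive the fragment length.
    """

    id: str
    length: int
    genome_origin: str
    amino_acid: str
    anticodon: str
    cleavage_type: str | None = None
    sequence: str | None = None
    parent_trnas: list[str] = field(default_factory=list)
    name_coords: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not MIN_TRF_LEN <= self.length <= MAX_TRF_LEN:
            raise ValueError(
                f"{self.id}: length {self.length} outside the tRF range "
                f"[{MIN_TRF_LEN}, {MAX_TRF_LEN}]"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.id}: sequence has {len(self.sequence)} nt but "
                f"length={self.length}"
            )
        if self.genome_origin not in ORIGINS:
            raise ValueError(f"{self.id}: unknown genome origin {self.genome_origin!r}")
        if self.cleavage_type is not None and self.cleavage_type not in CLEAVAGE_TYPES:
            raise ValueError(
                f"{self.id}: unknown cleavage type {self.cleavage_type!r}"
            )

    @property
    def family_key(self) -> FamilyKey:
        if self.cleavage_type is None:
            raise ValueError(f"{self.id}: cleavage type unset; cannot assign family")
        return FamilyKey(self.genome_origin, self.amino_acid, self.cleavage_type)


def parse_tdr_name(name: str) -> dict:
    """Parse a tDR-style identifier such as ``mtDR-36:57-Gly-TCC-1``.

    Returns a partial annotation dict with ``genome_origin`` (MT iff the
    prefix is ``mtDR``), ``amino_acid``, ``anticodon``, ``name_coords`` and
    ``suffix``.  Cleavage type is not encoded in the name and the coordinate
    span is *not* a length (structural numbering), so neither is set here.

    Raises :class:`TDRNameError` naming the offending token on malformed
    input; a parse is never silently partial.
    """
    m = _TDR_RE.match(name)
    if m is None:
        # Identify the first offending token for the error message.
        parts = name.split("-")
        if not parts or parts[0] not in ("tDR", "mtDR"):
            offender = parts[0] if parts else name
            raise TDRNameError(f"{name!r}: bad prefix token {offender!r}")
        if len(parts) < 2 or not re.fullmatch(r"\d+:\d+", parts[1]):
            offender = parts[1] if len(parts) > 1 else "<missing coords>"
            raise TDRNameError(f"{name!r}: bad coordinate token {offender!r}")
        raise TDRNameError(f"{name!r}: does not match tDR name grammar")
    start, end = int(m.group("start")), int(m.group("end"))
    if start <= 0 or end <= 0:
        raise TDRNameError(f"{name!r}: coordinates must be positive")
    return {
        "genome_origin": "MT" if m.group("prefix") == "mtDR" else "Nuc",
        "amino_acid": m.group("aa"),
        "anticodon": m.group("anticodon").upper(),
        "name_coords": (start, end),
        "suffix": m.group("suffix"),
    }


def format_tdr_name(
    genome_origin: str,
    name_coords: tuple[int, int],
    amino_acid: str,
    anticodon: str,
    suffix: str = "1",
) -> str:
    """Inverse of :func:`parse_tdr_name` on the grammar's domain."""
    prefix = "mtDR" if genome_origin == "MT" else "tDR"
    return f"{prefix}-{name_coords[0]}:{name_coords[1]}-{amino_acid}-{anticodon}-{suffix}"


def classify_cleavage(
    start: int, end: int, trna_len: int, anticodon_loop: tuple[int, int]
) -> str:
    """Assign a cleavage type from fragment coordinates on the mature tRNA.

    5'-halves end inside the anticodon loop and 3'-halves start inside it
    (angiogenin cleavage at the loop); 5'-tRFs/3'-tRFs stop short of the
    loop at the respective terminus; everything else is internal (i-tRF).
    """
    if not (1 <= start <= end <= trna_len):
        raise ValueError(
            f"coordinates ({start}, {end}) outside tRNA of length {trna_len}"
        )
    loop_start, loop_end = anticodon_loop
    if not (1 <= loop_start <= loop_end <= trna_len):
        raise ValueError(f"anticodon loop {anticodon_loop} outside [1, {trna_len}]")
    if start == 1:
        if loop_start <= end <= loop_end:
            return "5p-half"
        if end < loop_start:
            return "5p-tRF"
    if end == trna_len:
        if loop_start <= start <= loop_end:
            return "3p-half"
        if start > loop_end:
            return "3p-tRF"
    return "i-tRF"


@dataclass
class FamilyIndex:
    """Partition of annotated tRFs into families.

    Every annotated fragment appears in exactly one family.  Families with
    fewer than ``min_size`` members are retained for reporting but flagged
    untestable (a directional trend over a single member is uninformative).
    """

    members: dict[FamilyKey, list[str]]
    min_size: int = 2

    def __post_init__(self) -> None:
        self.members = dict(
            sorted(self.members.items(), key=lambda kv: kv[0].sort_key)
        )

    @property
    def families(self) -> list[FamilyKey]:
        return list(self.members)

    @property
    def n_features(self) -> int:
        return sum(len(v) for v in self.members.values())

    def size(self, key: FamilyKey) -> int:
        return len(self.members[key])

    def testable(self, key: FamilyKey) -> bool:
        return len(self.members[key]) >= self.min_size

    def family_of(self) -> dict[str, FamilyKey]:
        """Mapping feature id -> family key."""
        out: dict[str, FamilyKey] = {}
        for key, ids in self.members.items():
            for i in ids:
                out[i] = key
        return out

    def coarsen(self, by: str) -> "FamilyIndex":
        """Regroup under a coarser key: 'origin', 'cleavage' or 'amino_acid'.

        Super-family trends (all-MT vs all-Nuc, per-cleavage-type,
        per-amino-acid) use the same machinery with the coarser key filled
        with a placeholder in the unused slots.
        """
        coarse: dict[FamilyKey, list[str]] = {}
        for key, ids in self.members.items():
            # Placeholder slots keep the NamedTuple shape; only the grouping
            # slot is meaningful for a coarsened index.
            if by == "origin":
                ck = FamilyKey(key.genome_origin, "Any", "i-tRF")
            elif by == "cleavage":
                ck = FamilyKey("Nuc", "Any", key.cleavage_type)
            elif by == "amino_acid":
                ck = FamilyKey("Nuc", key.amino_acid, "i-tRF")
            else:
                raise ValueError(f"unknown grouping {by!r}")
            coarse.setdefault(ck, []).extend(ids)
        return FamilyIndex({k: sorted(v) for k, v in coarse.items()}, self.min_size)


def build_family_index(
    annotations: Sequence[TRFAnnotation], min_size: int = 2
) -> FamilyIndex:
    """Partition annotations into families; duplicate ids are an error."""
    seen: set[str] = set()
    members: dict[FamilyKey, list[str]] = {}
    for ann in annotations:
        if ann.id in seen:
            raise ValueError(f"duplicate tRF id {ann.id!r}")
        seen.add(ann.id)
        members.setdefault(ann.family_key, []).append(ann.id)
    return FamilyIndex({k: sorted(v) for k, v in members.items()}, min_size)


# ---------------------------------------------------------------------------
# Annotation table I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "id",
    "sequence",
    "length",
    "origin",
    "amino_acid",
    "anticodon",
    "cleavage_type",
    "parents",
]


def read_annotation_table(path) -> list[TRFAnnotation]:
    """Read the annotation TSV (header required).

    Columns: ``id, sequence, length, origin, amino_acid, anticodon,
    cleavage_type, parents``; ``parents`` is a comma-separated list, possibly
    empty.  Rows violating the tRF length range are rejected at load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TRFAnnotation(
                id=row.id,
                sequence=row.sequence or None,
                length=int(row.length),
                genome_origin=row.origin,
                amino_acid=row.amino_acid,
                anticodon=row.anticodon,
                cleavage_type=row.cleavage_type or None,
                parent_trnas=[p for p in row.parents.split(",") if p],
            )
        )
    return out


def write_annotation_table(annotations: Iterable[TRFAnnotation], path) -> None:
    rows = [
        {
            "id": a.id,
            "sequence": a.sequence or "",
            "length": a.length,
            "origin": a.genome_origin,
            "amino_acid": a.amino_acid,
            "anticodon": a.anticodon,
            "cleavage_type": a.cleavage_type or "",
            "parents": ",".join(a.parent_trnas),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)
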
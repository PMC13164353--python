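"""Protein sequences and bioactive-peptide occurrence statistics.

A protein is screened for encrypted bioactive fragments by exact substring
matching against a reference table of (activity, fragment) pairs.  The
summary statistic is the frequency of occurrence

    A = a / N

where ``a`` counts fragment matches (every (fragment, start) pair by
default, overlaps included) and ``N`` is the protein's residue count.  The
aggregate over all activity categories, sigma-A, measures how densely a
protein encodes bioactive fragments overall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "CANONICAL_RESIDUES",
    "ProteinRecord",
    "BioactiveReference",
    "OccurrenceProfile",
    "load_fasta",
    "load_reference",
    "default_ace_reference",
    "occurrence_frequency",
    "occurrence_profile",
]

#: The 20 canonical one-letter residue codes.  Ambiguity/rare codes
#: (B, J, O, U, X, Z) are rejected so that match statistics stay exact.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _validate_sequence(seq: str, owner: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{owner}: empty sequence")
    bad = sorted(set(seq) - CANONICAL_RESIDUES)
    if bad:
        raise ValueError(
            f"{owner}: non-canonical residue code(s) {''.join(bad)!r}; "
            "only the 20 standard one-letter codes are accepted"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One protein chain: accession, free-text description, residues."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record needs a non-empty id")
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence, f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.sequence)


class BioactiveReference:
    """Deduplicated set of (activity label, peptide fragment) pairs.

    Activity labels are matched case-insensitively after trimming; the
    first-seen spelling is kept for display.  Fragments must be canonical
    peptides of length >= 2.
    """

    def __init__(self, pairs) -> None:
        self._display: dict[str, str] = {}
        self._fragments: dict[str, frozenset[str]] = {}
        staged: dict[str, set[str]] = {}
        for activity, fragment in pairs:
            label = str(activity).strip()
            if not label:
                raise ValueError("empty activity label in reference")
            fragment = _validate_sequence(str(fragment).strip(), f"fragment for {label!r}")
            if len(fragment) < 2:
                raise ValueError(
                    f"reference fragment {fragment!r} ({label!r}) is shorter than 2 residues"
                )
            key = label.lower()
            self._display.setdefault(key, label)
            staged.setdefault(key, set()).add(fragment)
        self._fragments = {k: frozenset(v) for k, v in staged.items()}

    @property
    def activities(self) -> list[str]:
        """Display labels, sorted case-insensitively."""
        return [self._display[k] for k in sorted(self._fragments)]

    def fragments(self, activity: str) -> frozenset[str]:
        """Fragments for one activity; empty set if the activity is unknown."""
        return self._fragments.get(str(activity).strip().lower(), frozenset())

    @property
    def entries(self) -> set[tuple[str, str]]:
        return {
            (self._display[k], frag)
            for k, frags in self._fragments.items()
            for frag in frags
        }

    @property
    def min_fragment_length(self) -> int | None:
        lengths = [len(f) for frags in self._fragments.values() for f in frags]
        return min(lengths) if lengths else None

    def __len__(self) -> int:
        return sum(len(v) for v in self._fragments.values())

    def __contains__(self, activity: str) -> bool:
        return str(activity).strip().lower() in self._fragments


@dataclass
class OccurrenceProfile:
    """Per-activity occurrence frequencies of one protein and their sum."""

    protein_id: str
    per_activity_a: dict[str, float]
    sigma_a: float = field(init=False)

    def __post_init__(self) -> None:
        self.sigma_a = float(sum(self.per_activity_a.values()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "protein_id": self.protein_id,
                "per_activity_A": self.per_activity_a,
                "sigma_A": self.sigma_a,
            },
            indent=2,
        )


def load_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) FASTA file into validated records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        try:
            records.append(
                ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def load_reference(path) -> BioactiveReference:
    """Read a tab-separated ``activity<TAB>sequence`` table (``#`` comments ok)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if parts[0].strip().lower() == "activity":  # header
                continue
            pairs.append((parts[0], parts[1]))
    return BioactiveReference(pairs)


def default_ace_reference() -> BioactiveReference:
    """The bundled demonstration reference (curated literature peptides)."""
    with resources.as_file(
        resources.files("acepep.data").joinpath("ace_reference.tsv")
    ) as p:
        return load_reference(p)


def _count_matches(sequence: str, fragments, unique_fragments: bool) -> int:
    count = 0
    for frag in fragments:
        start = sequence.find(frag)
        if start < 0:
            continue
        if unique_fragments:
            count += 1
            continue
        while start >= 0:
            count += 1
            start = sequence.find(frag, start + 1)
    return count


def occurrence_frequency(
    protein: ProteinRecord,
    activity: str,
    ref: BioactiveReference,
    *,
    unique_fragments: bool = False,
) -> float:
    """Frequency of occurrence A = (fragment matches) / (protein length).

    Every (fragment, start-position) pair counts once and overlapping
    matches all count; with ``unique_fragments=True`` each distinct
    fragment counts at most once per protein.
    """
    return _count_matches(
        protein.sequence, ref.fragments(activity), unique_fragments
    ) / len(protein)


def occurrence_profile(
    protein: ProteinRecord,
    ref: BioactiveReference,
    *,
    unique_fragments: bool = False,
) -> OccurrenceProfile:
    """A for every activity in the reference, plus their sum sigma-A."""
    per = {
        activity: occurrence_frequency(
            protein, activity, ref, unique_fragments=unique_fragments
        )
        for activity in ref.activities
    }
    return OccurrenceProfile(protein_id=protein.id, per_activity_a=per)
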
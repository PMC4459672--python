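"""Alignment I/O, missing-character classification, and the direct site-count oracle.

An alignment column is *usable* at coverage threshold ``t`` when the fraction
of sequences carrying a resolved character (neither a gap nor an unresolved
placeholder such as ``N``/``X``/``?``) at that column is at least ``t``.
This module provides:

* :class:`Alignment` — a minimal in-memory MSA (names + equal-length rows),
* :class:`MissingSpec` — which characters count as missing,
* :func:`presence_matrix` — the 0/1 resolved-character indicator matrix that
  every downstream computation consumes,
* :func:`direct_site_count` — the brute-force, tree-free count of usable
  columns for an arbitrary kept subset.  This is the reference oracle the
  dynamic-programming engine is validated against.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    DomainError,
    FormatError,
    IdentityError,
    MsaPruneError,
)

logger = logging.getLogger(__name__)


class MsaIOError(MsaPruneError):
    """Unwritable or unreadable path."""

__all__ = [
    "Alphabet",
    "Alignment",
    "MissingSpec",
    "PresenceMatrix",
    "read_alignment",
    "write_alignment",
    "presence_matrix",
    "direct_site_count",
]


class Alphabet(str, Enum):
    nucleotide = "nucleotide"
    protein = "protein"


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: named rows over a common column count.

    Rows are plain strings; all rows must have identical length ``n >= 1``
    and names must be unique and non-empty.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: Alphabet = Alphabet.nucleotide

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError("names and rows differ in count")
        if len(self.rows) < 1:
            raise AlignmentError("alignment must contain at least one sequence")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment must have at least one column")
        if any(not n for n in self.names):
            raise IdentityError("empty sequence name")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise IdentityError(f"duplicate sequence names: {dupes}")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise IdentityError(f"unknown sequence name: {name!r}") from None

    def subset(self, names: Iterable[str]) -> "Alignment":
        """Restrict to ``names``, preserving the original row order."""
        wanted = set(names)
        unknown = wanted - set(self.names)
        if unknown:
            raise IdentityError(f"unknown sequence names: {sorted(unknown)}")
        keep = [(n, r) for n, r in zip(self.names, self.rows) if n in wanted]
        if not keep:
            raise DomainError("subset would be empty")
        return Alignment(
            names=tuple(n for n, _ in keep),
            rows=tuple(r for _, r in keep),
            alphabet=self.alphabet,
        )

    def char_matrix(self) -> np.ndarray:
        """Rows as a (n_seqs, n_cols) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="<U1")


def _default_unresolved(alphabet: Alphabet) -> frozenset[str]:
    if alphabet is Alphabet.protein:
        return frozenset({"X", "?"})
    return frozenset({"N", "?"})


@dataclass(frozen=True)
class MissingSpec:
    """Which characters are treated as missing data.

    ``gap_chars`` and ``unresolved_chars`` are both scored as missing; the
    distinction is kept only so reports can break the two classes down.
    With ``case_sensitive=False`` (the default), classification is performed
    on upper-cased characters.
    """

    gap_chars: frozenset[str] = frozenset({"-"})
    unresolved_chars: frozenset[str] = field(default_factory=lambda: frozenset({"N", "?"}))
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gap_chars", frozenset(self.gap_chars))
        object.__setattr__(self, "unresolved_chars", frozenset(self.unresolved_chars))
        if self.gap_chars & self.unresolved_chars:
            raise DomainError("gap_chars and unresolved_chars must be disjoint")

    @classmethod
    def for_alphabet(cls, alphabet: Alphabet) -> "MissingSpec":
        return cls(unresolved_chars=_default_unresolved(alphabet))

    def missing_chars(self) -> frozenset[str]:
        chars = self.gap_chars | self.unresolved_chars
        if not self.case_sensitive:
            chars = frozenset({c.upper() for c in chars} | {c.lower() for c in chars})
        return chars


@dataclass(frozen=True)
class PresenceMatrix:
    """Per-sequence, per-column indicator of resolved characters (1 = resolved)."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        v = np.asarray(self.values, dtype=np.int64)
        if v.ndim != 2 or v.shape[0] != len(self.names):
            raise AlignmentError("presence matrix shape does not match names")
        if not np.isin(v, (0, 1)).all():
            raise DomainError("presence matrix entries must be 0 or 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def index(self, name: str) -> int:
        try:
            return self._index[name]  # type: ignore[attr-defined]
        except KeyError:
            raise IdentityError(f"unknown sequence name: {name!r}") from None

    def row(self, name: str) -> np.ndarray:
        return self.values[self.index(name)]


_FORMAT_ALIASES = {"fasta": "fasta", "phylip": "phylip", "clustal": "clustal"}


def read_alignment(path: str | Path, format: str = "fasta",
                   alphabet: Alphabet = Alphabet.nucleotide) -> Alignment:
    """Read an alignment file (FASTA, strict Phylip, or Clustal).

    FASTA names are taken from the header up to the first whitespace.
    Unequal sequence lengths raise :class:`AlignmentError`; duplicate names
    raise :class:`IdentityError`; parse failures raise :class:`FormatError`.
    """
    path = Path(path)
    fmt = _FORMAT_ALIASES.get(str(format).lower())
    if fmt is None:
        raise FormatError(f"unsupported alignment format: {format!r}")
    alphabet = Alphabet(alphabet)
    try:
        if fmt == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), fmt))
    except IdentityError:
        raise
    except Exception as exc:  # Biopython raises a mix of ValueError subclasses
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequence records found in {path}")
    names = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    for name, row in zip(names, rows):
        if len(row) != len(rows[0]):
            raise AlignmentError(
                f"sequence {name!r} has length {len(row)}, expected {len(rows[0])}"
            )
    return Alignment(names=tuple(names), rows=tuple(rows), alphabet=alphabet)


def _sanitize_phylip_names(names: Sequence[str]) -> list[str]:
    """Strict Phylip: <=10 chars, no whitespace; disambiguate collisions."""
    out: list[str] = []
    seen: set[str] = set()
    for name in names:
        clean = re.sub(r"\s+", "_", name)[:10]
        base, k = clean, 1
        while clean in seen:
            suffix = f"_{k}"
            clean = base[: 10 - len(suffix)] + suffix
            k += 1
        if clean != name:
            logger.warning("phylip output: renaming %r -> %r", name, clean)
        seen.add(clean)
        out.append(clean)
    return out


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment; FASTA round-trips names, rows and order exactly."""
    path = Path(path)
    fmt = _FORMAT_ALIASES.get(str(format).lower())
    if fmt is None:
        raise FormatError(f"unsupported alignment format: {format!r}")
    names = list(aln.names)
    if fmt == "phylip":
        names = _sanitize_phylip_names(names)
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(names, aln.rows)
    ]
    try:
        if fmt == "fasta":
            with open(path, "w") as handle:
                SeqIO.write(records, handle, "fasta")
        else:
            AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)
    except OSError as exc:
        raise MsaIOError(f"cannot write {path}: {exc}") from exc


def presence_matrix(aln: Alignment, spec: MissingSpec | None = None) -> PresenceMatrix:
    """Classify every character as resolved (1) or missing (0).

    A character is missing when it belongs to ``spec.gap_chars`` or
    ``spec.unresolved_chars`` (case-insensitively unless
    ``spec.case_sensitive``); everything else — including ambiguity codes
    such as R/Y/B — is resolved.
    """
    if spec is None:
        spec = MissingSpec.for_alphabet(aln.alphabet)
    missing = spec.missing_chars()
    chars = aln.char_matrix()
    values = (~np.isin(chars, sorted(missing))).astype(np.int64)
    return PresenceMatrix(values=values, names=aln.names)


def direct_site_count(pm: PresenceMatrix, kept: Iterable[str], t: float) -> int:
    """Brute-force count of columns whose resolved fraction over ``kept`` is >= t.

    This scans columns directly with no tree structure; it is the oracle the
    tree dynamic programming must agree with.  The comparison is closed
    (ties at the threshold count as usable).
    """
    kept = list(kept)
    if not kept:
        raise DomainError("kept set must be non-empty")
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"threshold t must be in [0, 1], got {t}")
    idx = [pm.index(name) for name in kept]
    counts = pm.values[idx].sum(axis=0)
    frac = counts / len(idx)
    return int(np.count_nonzero(frac >= t))
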
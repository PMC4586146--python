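"""Alignment and haplotype-table containers and I/O.

Published mtDNA phylogeography datasets are usually distributed not as raw
alignments but as haplotype tables: one row per distinct haplotype, one
column per variable site (1-based coordinates on a reference mitogenome),
plus per-locality frequency counts.  This module holds both representations
and converts losslessly between them:

* :class:`Alignment` — one row per individual, variable columns only, with a
  declared total locus length ``L`` (needed for per-site diversity).
* :class:`HaplotypeTable` — distinct haplotypes x variable sites with a
  haplotype x locality count matrix.

Alphabet is ``{A, C, G, T, -, ?}`` where ``-`` is an alignment gap (an indel
state observed in the data) and ``?`` is missing/unresolved.  IUPAC ambiguity
codes are mapped to ``?`` on input.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "SiteClassification",
    "read_alignment",
    "collapse_haplotypes",
    "expand_table",
    "haplotype_alignment",
    "classify_sites",
    "read_haplotype_table",
    "write_haplotype_table",
]

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT-?")
GAP = "-"
MISSING = "?"

MissingPolicy = Literal["strict", "ignore_missing"]


class AlignmentError(ValueError):
    """Raised on malformed alignments or haplotype tables."""


@dataclass(frozen=True)
class Alignment:
    """Aligned haploid sequences restricted to their variable columns.

    ``sites`` are 1-based coordinates on the reference mitogenome; ``matrix``
    holds one string of states per sample, column order matching ``sites``.
    ``length`` is the total aligned locus length in bp, of which only the
    listed columns are stored (the rest are invariant).
    """

    sample_ids: tuple[str, ...]
    localities: tuple[str, ...]
    sites: tuple[int, ...]
    matrix: tuple[str, ...]
    length: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise AlignmentError("duplicate sample ids")
        if len(self.localities) != len(self.sample_ids):
            raise AlignmentError("one locality label required per sample")
        if len(self.matrix) != len(self.sample_ids):
            raise AlignmentError("one matrix row required per sample")
        for sid, row in zip(self.sample_ids, self.matrix):
            if len(row) != len(self.sites):
                raise AlignmentError(
                    f"row for {sid!r} has {len(row)} states, expected {len(self.sites)}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlignmentError(f"row for {sid!r} has invalid states {sorted(bad)}")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise AlignmentError("site coordinates must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: Sequence[bool] | Sequence[int]) -> "Alignment":
        """Row subset; ``keep`` is a boolean mask or index sequence."""
        if keep and isinstance(keep[0], bool):
            idx = [i for i, k in enumerate(keep) if k]
        else:
            idx = list(keep)  # type: ignore[arg-type]
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            localities=tuple(self.localities[i] for i in idx),
            matrix=tuple(self.matrix[i] for i in idx),
        )

    def drop_columns(self, sites_to_drop: Iterable[int]) -> "Alignment":
        drop = set(sites_to_drop)
        keep = [j for j, s in enumerate(self.sites) if s not in drop]
        return replace(
            self,
            sites=tuple(self.sites[j] for j in keep),
            matrix=tuple("".join(row[j] for j in keep) for row in self.matrix),
        )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes x variable sites, with per-locality counts."""

    haplotype_ids: tuple[str, ...]
    sites: tuple[int, ...]
    states: tuple[str, ...]
    localities: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]  # haplotype x locality

    def __post_init__(self) -> None:
        if len(self.haplotype_ids) != len(set(self.haplotype_ids)):
            raise AlignmentError("duplicate haplotype ids")
        if len(self.states) != len(self.haplotype_ids):
            raise AlignmentError("one state row per haplotype required")
        for hid, row in zip(self.haplotype_ids, self.states):
            if len(row) != len(self.sites):
                raise AlignmentError(f"state row for {hid!r} has wrong length")
        if len(self.counts) != len(self.haplotype_ids):
            raise AlignmentError("one count row per haplotype required")
        for hid, row in zip(self.haplotype_ids, self.counts):
            if len(row) != len(self.localities):
                raise AlignmentError(f"count row for {hid!r} has wrong length")
            if any(c < 0 for c in row):
                raise AlignmentError(f"negative count for {hid!r}")
            if sum(row) < 1:
                raise AlignmentError(f"haplotype {hid!r} has zero total count")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def total_counts(self) -> tuple[int, ...]:
        """Total count per haplotype, summed over localities."""
        return tuple(sum(row) for row in self.counts)

    @property
    def n(self) -> int:
        return sum(self.total_counts)

    def locality_total(self, locality: str) -> int:
        j = self.localities.index(locality)
        return sum(row[j] for row in self.counts)


@dataclass(frozen=True)
class SiteClassification:
    """Partition of alignment columns by variability and indel content.

    A site is ``substitution_variable`` when at least two distinct non-gap,
    non-missing states occur; ``indel_containing`` when any sampled state is
    a gap.  The two flags are independent; invariant = neither.
    """

    sites: tuple[int, ...]
    substitution_variable: frozenset[int]
    indel_containing: frozenset[int]

    @property
    def invariant(self) -> frozenset[int]:
        return frozenset(self.sites) - self.substitution_variable - self.indel_containing


_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


def read_alignment(
    path,
    locality_map: dict[str, str] | None = None,
    length: int | None = None,
) -> Alignment:
    """Read a pre-aligned FASTA file into an :class:`Alignment`.

    All records must have equal length.  IUPAC ambiguity codes are stored as
    ``?`` (logged).  Sample order follows file order.  ``locality_map`` maps
    record ids to locality labels (default ``"unknown"``).  All columns are
    retained; ``length`` defaults to the record length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    L = len(records[0].seq)
    rows = []
    ids = []
    for rec in records:
        if len(rec.seq) != L:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {L} (ragged alignment)"
            )
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in ALPHABET:
                cleaned.append(ch)
            elif ch in _IUPAC_AMBIGUOUS or ch == ".":
                cleaned.append(MISSING)
            else:
                raise AlignmentError(f"record {rec.id!r} contains invalid character {ch!r}")
        if MISSING in cleaned and MISSING not in seq:
            logger.warning("record %s: ambiguity codes stored as '?'", rec.id)
        ids.append(rec.id)
        rows.append("".join(cleaned))
    locs = tuple((locality_map or {}).get(i, "unknown") for i in ids)
    return Alignment(
        sample_ids=tuple(ids),
        localities=locs,
        sites=tuple(range(1, L + 1)),
        matrix=tuple(rows),
        length=length if length is not None else L,
    )


def _rows_match_ignore_missing(a: str, b: str) -> bool:
    return all(x == y or x == MISSING or y == MISSING for x, y in zip(a, b))


def collapse_haplotypes(
    aln: Alignment,
    missing_policy: MissingPolicy = "strict",
    haplotype_ids: dict[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with locality counts.

    ``strict``: any character difference separates haplotypes.
    ``ignore_missing``: ``?`` matches any state; rows are merged greedily into
    the first compatible haplotype in input order (the representative row
    keeps the first-seen states, with ``?`` filled from later members when a
    member resolves it).

    Haplotype ids are zero-padded serials in first-occurrence order (``H01``,
    ``H02``, ...) unless ``haplotype_ids`` maps representative sample ids to
    names.
    """
    if aln.n == 0:
        raise AlignmentError("cannot collapse an empty alignment")
    localities = tuple(OrderedDict.fromkeys(aln.localities))
    loc_index = {l: j for j, l in enumerate(localities)}
    reps: list[str] = []  # representative states per haplotype
    rep_sample: list[str] = []
    counts: list[list[int]] = []
    for sid, loc, row in zip(aln.sample_ids, aln.localities, aln.matrix):
        hit = None
        for i, rep in enumerate(reps):
            if row == rep or (
                missing_policy == "ignore_missing" and _rows_match_ignore_missing(row, rep)
            ):
                hit = i
                break
        if hit is None:
            reps.append(row)
            rep_sample.append(sid)
            counts.append([0] * len(localities))
            hit = len(reps) - 1
        elif missing_policy == "ignore_missing":
            # resolve '?' in the representative from this member
            merged = "".join(
                y if x == MISSING and y != MISSING else x for x, y in zip(reps[hit], row)
            )
            reps[hit] = merged
        counts[hit][loc_index[loc]] += 1
    width = max(2, len(str(len(reps))))
    if haplotype_ids is not None:
        ids = tuple(
            haplotype_ids.get(rep_sample[i], f"H{i + 1:0{width}d}") for i in range(len(reps))
        )
    else:
        ids = tuple(f"H{i + 1:0{width}d}" for i in range(len(reps)))
    return HaplotypeTable(
        haplotype_ids=ids,
        sites=aln.sites,
        states=tuple(reps),
        localities=localities,
        counts=tuple(tuple(c) for c in counts),
    )


def expand_table(
    tbl: HaplotypeTable,
    locality_filter: set[str] | None = None,
    length: int = 0,
) -> Alignment:
    """Expand a haplotype table into a per-individual alignment.

    Each haplotype is replicated by its count in each retained locality;
    sample ids are ``<haplotype_id>_<locality>_<serial>``.  Inverse of
    :func:`collapse_haplotypes` up to haplotype naming.
    """
    if locality_filter is not None:
        unknown = locality_filter - set(tbl.localities)
        if unknown:
            raise AlignmentError(f"unknown localities in filter: {sorted(unknown)}")
    ids, locs, rows = [], [], []
    for hid, states, count_row in zip(tbl.haplotype_ids, tbl.states, tbl.counts):
        for loc, c in zip(tbl.localities, count_row):
            if locality_filter is not None and loc not in locality_filter:
                continue
            for serial in range(1, c + 1):
                ids.append(f"{hid}_{loc}_{serial}")
                locs.append(loc)
                rows.append(states)
    if not ids:
        raise AlignmentError("no individuals after applying locality filter")
    return Alignment(
        sample_ids=tuple(ids),
        localities=tuple(locs),
        sites=tbl.sites,
        matrix=tuple(rows),
        length=length,
    )


def haplotype_alignment(
    tbl: HaplotypeTable,
    locality_filter: set[str] | None = None,
    length: int = 0,
) -> Alignment:
    """One row per *distinct* haplotype (frequency-unweighted).

    With a ``locality_filter``, only haplotypes observed at least once in
    the retained localities are kept.  The locality label of each row is the
    first locality (in table order) where the haplotype occurs.
    """
    if locality_filter is not None:
        unknown = locality_filter - set(tbl.localities)
        if unknown:
            raise AlignmentError(f"unknown localities in filter: {sorted(unknown)}")
    keep_loc = [
        j
        for j, l in enumerate(tbl.localities)
        if locality_filter is None or l in locality_filter
    ]
    ids, locs, rows = [], [], []
    for hid, states, count_row in zip(tbl.haplotype_ids, tbl.states, tbl.counts):
        hit = [j for j in keep_loc if count_row[j] > 0]
        if hit:
            ids.append(hid)
            locs.append(tbl.localities[hit[0]])
            rows.append(states)
    if not ids:
        raise AlignmentError("no haplotypes after applying locality filter")
    return Alignment(
        sample_ids=tuple(ids),
        localities=tuple(locs),
        sites=tbl.sites,
        matrix=tuple(rows),
        length=length,
    )


def classify_sites(aln: Alignment) -> SiteClassification:
    """Classify each column as invariant / substitution-variable / indel-containing.

    ``?`` never makes a site variable on its own; the indel flag is
    independent of substitution variability.
    """
    variable = set()
    indel = set()
    for j, site in enumerate(aln.sites):
        col = [row[j] for row in aln.matrix]
        if GAP in col:
            indel.add(site)
        nucs = {c for c in col if c not in (GAP, MISSING)}
        if len(nucs) >= 2:
            variable.add(site)
    return SiteClassification(
        sites=aln.sites,
        substitution_variable=frozenset(variable),
        indel_containing=frozenset(indel),
    )


def write_haplotype_table(tbl: HaplotypeTable, path) -> None:
    """Write the TSV dialect: per-site ``site:<pos>`` and per-locality
    ``count:<label>`` columns, single-character states, LF line endings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = (
            ["haplotype_id"]
            + [f"site:{s}" for s in tbl.sites]
            + [f"count:{l}" for l in tbl.localities]
        )
        fh.write("\t".join(header) + "\n")
        for hid, states, count_row in zip(tbl.haplotype_ids, tbl.states, tbl.counts):
            fh.write("\t".join([hid, *states, *map(str, count_row)]) + "\n")


def read_haplotype_table(path) -> HaplotypeTable:
    """Read the TSV dialect written by :func:`write_haplotype_table`."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise AlignmentError(f"{path}: empty haplotype table")
    header = lines[0].split("\t")
    if header[:1] != ["haplotype_id"]:
        raise AlignmentError(f"{path}:1: header must start with 'haplotype_id'")
    sites, localities = [], []
    for col in header[1:]:
        if col.startswith("site:"):
            if localities:
                raise AlignmentError(f"{path}:1: site column after count columns")
            try:
                sites.append(int(col[5:].replace(",", "")))
            except ValueError as exc:
                raise AlignmentError(f"{path}:1: bad site column {col!r}") from exc
        elif col.startswith("count:"):
            localities.append(col[6:])
        else:
            raise AlignmentError(f"{path}:1: unrecognized column {col!r}")
    if not localities:
        raise AlignmentError(f"{path}:1: no count columns")
    ids, states, counts = [], [], []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 1 + len(sites) + len(localities):
            raise AlignmentError(f"{path}:{ln}: expected {1 + len(sites) + len(localities)} fields")
        hid = fields[0]
        if hid in seen:
            raise AlignmentError(f"{path}:{ln}: duplicate haplotype id {hid!r}")
        seen.add(hid)
        ids.append(hid)
        states.append("".join(fields[1 : 1 + len(sites)]))
        try:
            counts.append(tuple(int(x) for x in fields[1 + len(sites) :]))
        except ValueError as exc:
            raise AlignmentError(f"{path}:{ln}: non-integer count") from exc
    return HaplotypeTable(
        haplotype_ids=tuple(ids),
        sites=tuple(sites),
        states=tuple(states),
        localities=tuple(localities),
        counts=tuple(counts),
    )
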
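"""Core sequence types, I/O, global alignment and marker-site calling.

The typing pipeline works on Sanger consensus reads of two amplicons: the
3' half of the mitochondrial COI gene (COIB, primers c891F/c1472R) and a
Z-linked Tpi segment spanning exon 4 and the adjacent intron (primers
t412F/t1140R).  Reads are globally aligned to an annotated reference
amplicon and diagnostic positions are read off through the alignment.

Coordinates are 1-based and fully closed.  Each reference carries an
explicit ``coordinate_offset`` so that marker positions can be stored in
the gene-level numbering their names use (e.g. mCOI1164D at position 1164)
without any arithmetic tied to primer names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .iupac import IUPAC_TO_STATES, decode, first_invalid_position

Gene = Literal["COI", "Tpi"]

GAP = "-"


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC alphabet."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSite:
    """A named diagnostic position on a reference amplicon.

    ``allowed_states`` are the unambiguous bases expected at the site (the
    empirically observed alleles); a read state outside this set is not an
    error but yields an unknown combination downstream.
    """

    name: str
    gene: Gene
    ref_position: int  # 1-based, in the gene-level numbering
    allowed_states: frozenset[str]
    role: Literal["strain-diagnostic", "h-haplotype-defining", "consistency-check"]

    def __post_init__(self) -> None:
        if not self.allowed_states:
            raise ValueError(f"site {self.name}: allowed_states empty")
        if not self.allowed_states <= frozenset("ACGT"):
            raise ValueError(f"site {self.name}: allowed_states must be unambiguous bases")


@dataclass
class ReferenceAmplicon:
    """An annotated reference amplicon (A/C/G/T only) with marker sites.

    For the Tpi amplicon, ``intron_boundary`` is the 1-based position *on
    the amplicon sequence* at which the fourth intron starts and
    ``intron_length`` its length on the reference.  The first two intron
    bases are checked against the canonical splice donor "GT"; a mismatch
    is recorded as a warning, not an error.
    """

    gene: Gene
    sequence: str
    coordinate_offset: int  # gene-level position of the first base
    sites: list[MarkerSite] = field(default_factory=list)
    intron_boundary: int | None = None
    intron_length: int | None = None
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence must contain only A/C/G/T")
        for site in self.sites:
            idx = self.site_index(site)
            if not 0 <= idx < len(self.sequence):
                raise ValueError(
                    f"site {site.name} at position {site.ref_position} falls outside "
                    f"the amplicon (offset {self.coordinate_offset}, "
                    f"length {len(self.sequence)})"
                )
        if self.intron_boundary is not None:
            if self.intron_length is None:
                raise ValueError("intron_boundary set without intron_length")
            if self.intron_boundary + self.intron_length - 1 > len(self.sequence):
                raise ValueError("intron extends past the end of the amplicon")
            donor = self.sequence[self.intron_boundary - 1 : self.intron_boundary + 1]
            if donor != "GT":
                msg = f"intron does not start with canonical splice donor GT (found {donor})"
                self.warnings.append(msg)
                warnings.warn(msg, stacklevel=2)

    def site_index(self, site: MarkerSite) -> int:
        """0-based index of a site on ``sequence``."""
        return site.ref_position - self.coordinate_offset

    def site_by_name(self, name: str) -> MarkerSite:
        for site in self.sites:
            if site.name == name:
                return site
        raise KeyError(f"no site named {name!r} on this {self.gene} reference")

    def sites_by_role(self, role: str) -> list[MarkerSite]:
        return [s for s in self.sites if s.role == role]


@dataclass(frozen=True)
class SangerRead:
    """A directly sequenced amplicon consensus over the IUPAC alphabet.

    Heterozygosity between the two Z alleles of a male shows up as
    ambiguity letters (overlapping chromatogram peaks); the read itself is
    a single merged consensus, not a phased pair.
    """

    id: str
    seq: str
    gene: Gene

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id}: empty sequence")
        pos = first_invalid_position(self.seq)
        if pos is not None:
            raise SequenceValidationError(
                f"read {self.id}: non-IUPAC character {self.seq[pos - 1]!r} at position {pos}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    def reverse_complement(self) -> "SangerRead":
        return SangerRead(self.id, str(Seq(self.seq).reverse_complement()), self.gene)


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    population: str
    year: int
    habitat: str
    collection_type: Literal["T", "C", "L"]  # trap / colony / larval collection

    def __post_init__(self) -> None:
        if self.collection_type not in ("T", "C", "L"):
            raise ValueError(
                f"{self.specimen_id}: collection_type must be T, C or L, "
                f"got {self.collection_type!r}"
            )


SiteStatus = Literal["unambiguous", "ambiguous", "gap", "uncovered"]


@dataclass(frozen=True)
class SiteCall:
    """Observed state set at one marker site of one read."""

    site_name: str
    observed_states: frozenset[str]
    status: SiteStatus

    def __post_init__(self) -> None:
        if self.status == "unambiguous" and len(self.observed_states) != 1:
            raise ValueError("unambiguous call must have exactly one state")
        if self.status in ("gap", "uncovered") and self.observed_states:
            raise ValueError(f"{self.status} call must have no observed states")

    @property
    def base(self) -> str | None:
        """The single base, for unambiguous calls."""
        if self.status == "unambiguous":
            return next(iter(self.observed_states))
        return None


@dataclass(frozen=True)
class Alignment:
    """A gapped global alignment of one read against one reference."""

    aligned_ref: str
    aligned_read: str
    score: float
    orientation: Literal["forward", "reverse-complement"] = "forward"

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_read):
            raise ValueError("aligned strings differ in length")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def read(self) -> str:
        return self.aligned_read.replace(GAP, "")

    def ref_column(self, ref_index: int) -> int:
        """Alignment column (0-based) holding the 0-based reference index."""
        seen = -1
        for col, c in enumerate(self.aligned_ref):
            if c != GAP:
                seen += 1
                if seen == ref_index:
                    return col
        raise IndexError(f"reference index {ref_index} outside alignment")

    def read_span(self) -> tuple[int, int]:
        """First and last alignment columns covered by the read (inclusive)."""
        first = next(i for i, c in enumerate(self.aligned_read) if c != GAP)
        last = len(self.aligned_read) - 1 - next(
            i for i, c in enumerate(reversed(self.aligned_read)) if c != GAP
        )
        return first, last


@dataclass(frozen=True)
class AlignmentScoring:
    """Match/mismatch/affine-gap parameters.

    Defaults suit high-identity Sanger amplicons.  A gap run of length L
    costs ``gap_open + (L - 1) * gap_extend``.  Two IUPAC letters score as
    a match whenever their state sets intersect, so a heterozygous overlap
    never penalises the alignment against either allele.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


# ---------------------------------------------------------------------------
# FASTA / metadata I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, gene: Gene = "COI") -> list[SangerRead]:
    """Read a FASTA file into SangerReads (header token before whitespace = id).

    Raises :class:`FastaParseError` naming the offending line for malformed
    input and :class:`SequenceValidationError` naming record and position
    for non-IUPAC characters.
    """
    path = Path(path)
    reads: list[SangerRead] = []
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}: record {current_id!r} (line {header_line}) has no sequence")
        reads.append(SangerRead(current_id, seq, gene))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
                header_line = lineno
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    return reads


def write_fasta(reads: Iterable[SangerRead], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.id}\n")
            for i in range(0, len(read.seq), width):
                handle.write(read.seq[i : i + width] + "\n")


METADATA_COLUMNS = ["specimen_id", "population", "year", "habitat", "collection_type"]


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV (specimen_id, population, year, habitat, collection_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    return [
        SpecimenRecord(
            specimen_id=row.specimen_id,
            population=row.population,
            year=int(row.year),
            habitat=row.habitat,
            collection_type=row.collection_type,
        )
        for row in df.itertuples()
    ]


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.specimen_id, r.population, r.year, r.habitat, r.collection_type)
            for r in records
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference annotation sidecar TSV
# ---------------------------------------------------------------------------


def read_reference(fasta_path: str | Path, annotation_path: str | Path) -> ReferenceAmplicon:
    """Load a reference amplicon from FASTA + sidecar annotation TSV.

    The sidecar has one ``meta`` row (gene, coordinate_offset, intron
    boundary/length) and one ``site`` row per marker site.
    """
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one reference sequence")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    meta = ann[ann["record"] == "meta"]
    if len(meta) != 1:
        raise ValueError(f"{annotation_path}: expected exactly one 'meta' row")
    meta = meta.iloc[0]
    sites = [
        MarkerSite(
            name=row.name_,
            gene=meta.gene,
            ref_position=int(row.position),
            allowed_states=frozenset(row.allowed_states),
            role=row.role,
        )
        for row in ann[ann["record"] == "site"]
        .rename(columns={"name": "name_"})
        .itertuples()
    ]
    ib = meta.get("intron_boundary")
    il = meta.get("intron_length")
    return ReferenceAmplicon(
        gene=meta.gene,
        sequence=seqs[0].seq,
        coordinate_offset=int(meta.coordinate_offset),
        sites=sites,
        intron_boundary=int(ib) if ib and ib == ib else None,
        intron_length=int(il) if il and il == il else None,
        provenance=str(meta.get("provenance", "")),
    )


def write_reference(
    ref: ReferenceAmplicon, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    write_fasta([SangerRead(f"{ref.gene}_reference", ref.sequence, ref.gene)], fasta_path)
    rows = [
        {
            "record": "meta",
            "gene": ref.gene,
            "name": "",
            "position": "",
            "allowed_states": "",
            "role": "",
            "coordinate_offset": ref.coordinate_offset,
            "intron_boundary": ref.intron_boundary if ref.intron_boundary else "",
            "intron_length": ref.intron_length if ref.intron_length else "",
            "provenance": ref.provenance,
        }
    ]
    for s in ref.sites:
        rows.append(
            {
                "record": "site",
                "gene": s.gene,
                "name": s.name,
                "position": s.ref_position,
                "allowed_states": "".join(sorted(s.allowed_states)),
                "role": s.role,
                "coordinate_offset": "",
                "intron_boundary": "",
                "intron_length": "",
                "provenance": "",
            }
        )
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------

_ALPHABET = "ACGTRYSWKMBDHVN"


def _substitution_matrix(scoring: AlignmentScoring):
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            hit = IUPAC_TO_STATES[a] & IUPAC_TO_STATES[b]
            m[a, b] = scoring.match if hit else scoring.mismatch
    return m


_aligner_cache: dict[AlignmentScoring, Align.PairwiseAligner] = {}


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = _aligner_cache.get(scoring)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _substitution_matrix(scoring)
        aligner.open_gap_score = scoring.gap_open
        aligner.extend_gap_score = scoring.gap_extend
        _aligner_cache[scoring] = aligner
    return aligner


DEFAULT_SCORING = AlignmentScoring()


def global_align(
    read: SangerRead | str,
    ref: ReferenceAmplicon | str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    orientation: Literal["forward", "reverse-complement"] = "forward",
) -> Alignment:
    """Optimal global alignment of a read against a reference.

    Affine gap penalties; IUPAC-aware matching (intersecting state sets
    score as a match, so N matches any base).  Among co-optimal alignments
    a fixed deterministic traceback is returned.
    """
    read_seq = read.seq if isinstance(read, SangerRead) else read.upper()
    ref_seq = ref.sequence if isinstance(ref, ReferenceAmplicon) else ref.upper()
    if not read_seq or not ref_seq:
        raise ValueError("cannot align empty sequences")
    best = _aligner(scoring).align(ref_seq, read_seq)[0]
    return Alignment(
        aligned_ref=str(best[0]),
        aligned_read=str(best[1]),
        score=float(best.score),
        orientation=orientation,
    )


def orient_read(
    read: SangerRead,
    ref: ReferenceAmplicon,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[SangerRead, Alignment]:
    """Align a read in both orientations and keep the better one.

    Ties go to forward.  The returned read is already in reference
    orientation (i.e. reverse-complemented if needed).
    """
    fwd = global_align(read, ref, scoring, orientation="forward")
    rc_read = read.reverse_complement()
    rev = global_align(rc_read, ref, scoring, orientation="reverse-complement")
    if rev.score > fwd.score:
        return rc_read, rev
    return read, fwd


def call_site(alignment: Alignment, ref: ReferenceAmplicon, site: MarkerSite) -> SiteCall:
    """Read off the state set at a marker site through an alignment.

    A read gap at the site column gives status ``gap``; a site column
    outside the read's aligned span gives ``uncovered``; an ambiguity
    letter (including N) gives ``ambiguous``.
    """
    if site not in ref.sites:
        raise ValueError(f"site {site.name} does not belong to this {ref.gene} reference")
    col = alignment.ref_column(ref.site_index(site))
    first, last = alignment.read_span()
    if col < first or col > last:
        return SiteCall(site.name, frozenset(), "uncovered")
    letter = alignment.aligned_read[col]
    if letter == GAP:
        return SiteCall(site.name, frozenset(), "gap")
    states = decode(letter)
    status: SiteStatus = "unambiguous" if len(states) == 1 else "ambiguous"
    return SiteCall(site.name, states, status)


def extract_span(
    alignment: Alignment,
    ref: ReferenceAmplicon,
    start: int,
    end: int,
) -> tuple[str, bool]:
    """Read subsequence aligned to reference positions [start, end] (gene coords).

    Includes read insertions strictly inside the window; insertions
    immediately before the first or after the last window column are
    excluded.  Returns ``(segment, covered)`` where ``covered`` is False if
    the read's aligned span does not reach across the whole window.
    Segment is degapped (read deletions shorten it).
    """
    i0 = start - ref.coordinate_offset
    i1 = end - ref.coordinate_offset
    if i0 < 0 or i1 >= len(ref.sequence) or i0 > i1:
        raise ValueError(
            f"span {start}-{end} not covered by the {ref.gene} reference "
            f"(offset {ref.coordinate_offset}, length {len(ref.sequence)})"
        )
    col0 = alignment.ref_column(i0)
    col1 = alignment.ref_column(i1)
    first, last = alignment.read_span()
    if col0 < first or col1 > last:
        return "", False
    segment = alignment.aligned_read[col0 : col1 + 1].replace(GAP, "")
    return segment, True
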
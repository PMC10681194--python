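"""Canonical haplotype registries: exact sequence -> label maps.

Dereplication collapses identical sequences over a fixed comparison span
into named haplotype classes.  Two naming schemes are used in fall
armyworm work:

* COIB variants: lettered within their h-haplotype category, e.g.
  ``CSh2[e]`` is the fifth variant discovered within CSh2;
* TpiI4a200 intron haplotypes: two-digit serial labels ``iC01``, ``iC02``, ...

A registry is an ordered exact-match map.  Lookup never mutates; minting a
label for a novel sequence appends it.  Loading a canonical registry built
from deposited reference variants stabilises labels across datasets; with
an empty registry, labels are minted in discovery order.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import pandas as pd

from .sequence_core import SangerRead, read_fasta, write_fasta

Marker = Literal["COIB", "TpiI4a200"]


@dataclass
class RegistryEntry:
    label: str
    sequence: str
    category: str = ""  # CSh1..CSh4 for COIB variants; empty for intron haplotypes
    provenance: str = ""


@dataclass
class HaplotypeRegistry:
    marker: Marker
    entries: list[RegistryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_seq: dict[str, RegistryEntry] = {}
        self._by_label: dict[str, RegistryEntry] = {}
        for e in list(self.entries):
            self._index(e)

    def _index(self, entry: RegistryEntry) -> None:
        if entry.sequence in self._by_seq:
            raise ValueError(
                f"duplicate registry sequence for labels "
                f"{self._by_seq[entry.sequence].label!r} and {entry.label!r}"
            )
        if entry.label in self._by_label:
            raise ValueError(f"duplicate registry label {entry.label!r}")
        self._by_seq[entry.sequence] = entry
        self._by_label[entry.label] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RegistryEntry]:
        return iter(self.entries)

    def lookup(self, sequence: str) -> RegistryEntry | None:
        return self._by_seq.get(sequence.upper())

    def label_of(self, sequence: str) -> str | None:
        e = self.lookup(sequence)
        return e.label if e else None

    def add(self, entry: RegistryEntry) -> RegistryEntry:
        entry.sequence = entry.sequence.upper()
        self._index(entry)
        self.entries.append(entry)
        return entry

    # -- label minting -----------------------------------------------------

    def next_coib_label(self, category: str) -> str:
        """Next unused variant letter within a CSh category (a, b, ... z, aa, ...).

        Letters already present in the registry for that category are
        skipped, so canonical labels from a loaded registry are preserved.
        """
        pattern = re.compile(re.escape(category) + r"\[([a-z]+)\]$")
        used = {
            m.group(1)
            for e in self.entries
            if (m := pattern.match(e.label)) is not None
        }
        for letter in _letter_series():
            if letter not in used:
                return f"{category}[{letter}]"
        raise RuntimeError("exhausted variant letter space")  # pragma: no cover

    def next_intron_label(self) -> str:
        """Next unused two-digit serial label iCnn."""
        used = set()
        for e in self.entries:
            m = re.match(r"iC(\d+)$", e.label)
            if m:
                used.add(int(m.group(1)))
        n = 1
        while n in used:
            n += 1
        return f"iC{n:02d}"

    def mint(self, sequence: str, category: str = "", provenance: str = "novel") -> RegistryEntry:
        """Assign a new label to a novel sequence and register it."""
        if self.marker == "COIB":
            if not category:
                raise ValueError("COIB variant minting requires a CSh category")
            label = self.next_coib_label(category)
        else:
            label = self.next_intron_label()
        return self.add(RegistryEntry(label, sequence.upper(), category, provenance))


def _letter_series() -> Iterator[str]:
    for c in string.ascii_lowercase:
        yield c
    for c1 in string.ascii_lowercase:  # pragma: no cover - beyond 26 variants
        for c2 in string.ascii_lowercase:
            yield c1 + c2


# ---------------------------------------------------------------------------
# serialization: FASTA (sequences) + TSV (label, category, provenance)
# ---------------------------------------------------------------------------


def save_registry(registry: HaplotypeRegistry, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gene = "COI" if registry.marker == "COIB" else "Tpi"
    write_fasta(
        [SangerRead(e.label, e.sequence, gene) for e in registry.entries],
        directory / "registry.fasta",
    )
    pd.DataFrame(
        [(e.label, registry.marker, e.category, e.provenance) for e in registry.entries],
        columns=["label", "marker", "category", "provenance"],
    ).to_csv(directory / "registry.tsv", sep="\t", index=False)


def load_registry(directory: str | Path) -> HaplotypeRegistry:
    directory = Path(directory)
    meta = pd.read_csv(directory / "registry.tsv", sep="\t", dtype=str).fillna("")
    markers = set(meta["marker"])
    if len(markers) != 1:
        raise ValueError(f"{directory}: registry TSV must carry exactly one marker, got {markers}")
    marker = markers.pop()
    reads = read_fasta(directory / "registry.fasta")
    seq_by_label = {r.id: r.seq for r in reads}
    entries = [
        RegistryEntry(
            label=row.label,
            sequence=seq_by_label[row.label],
            category=row.category,
            provenance=row.provenance,
        )
        for row in meta.itertuples()
    ]
    return HaplotypeRegistry(marker=marker, entries=entries)
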
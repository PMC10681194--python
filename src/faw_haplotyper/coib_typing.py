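"""COIB h-haplotype classification and variant dereplication.

The 3' half of the mitochondrial COI gene (COIB) carries two polymorphic
sites, mCOI1164D and mCOI1287R, whose joint configuration defines the
marker categories used to compare fall armyworm populations:

====================  =========
(base1164, base1287)  category
====================  =========
(T, A)                R_COIB  (R-strain marker)
(A, A)                CSh1
(A, G)                CSh2
(G, A)                CSh3    (rare, but first-class)
(G, G)                CSh4
====================  =========

Other unambiguous pairs have not been observed in the field and are
reported as ``unknown_combo`` rather than rejected.  Because COIB is
mitochondrial (haploid, maternally inherited), ambiguity at a defining
site indicates a technical problem rather than heterozygosity and the read
is set aside as ``ambiguous``; a site outside the read's aligned span
yields ``no_call``.

Within each CSh category, additional polymorphisms elsewhere in the
segment define lettered sequence variants (CSh2[e], ...) obtained by exact
dereplication over a fixed comparison span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .registry import HaplotypeRegistry
from .sequence_core import (
    Alignment,
    ReferenceAmplicon,
    SiteCall,
    call_site,
    extract_span,
)

#: defining-site table: (state at 1164, state at 1287) -> category
COIB_TABLE: dict[tuple[str, str], str] = {
    ("T", "A"): "R_COIB",
    ("A", "A"): "CSh1",
    ("A", "G"): "CSh2",
    ("G", "A"): "CSh3",
    ("G", "G"): "CSh4",
}

CSH_CATEGORIES = ("CSh1", "CSh2", "CSh3", "CSh4")
#: collective label for the C-strain COIB categories
C_COIB = CSH_CATEGORIES

SITE_1164 = "mCOI1164D"
SITE_1287 = "mCOI1287R"


@dataclass
class CoibCall:
    specimen_id: str
    category: str  # R_COIB, CSh1..4, unknown_combo, ambiguous, no_call
    site_calls: tuple[SiteCall, SiteCall] | None = None
    variant_label: str | None = None

    @property
    def is_typed(self) -> bool:
        return self.category in COIB_TABLE.values()


def classify_coib(call1164: SiteCall, call1287: SiteCall) -> str:
    """Category from the two defining-site calls.

    Uncovered sites dominate (``no_call``), then any ambiguity or gap
    (``ambiguous``); unambiguous pairs are looked up in the fixed table,
    falling back to ``unknown_combo``.
    """
    for c in (call1164, call1287):
        if c.site_name not in (SITE_1164, SITE_1287):
            raise ValueError(f"not a COIB defining-site call: {c.site_name}")
    if "uncovered" in (call1164.status, call1287.status):
        return "no_call"
    if call1164.status != "unambiguous" or call1287.status != "unambiguous":
        return "ambiguous"
    return COIB_TABLE.get((call1164.base, call1287.base), "unknown_combo")


def classify_read(
    specimen_id: str, alignment: Alignment, ref: ReferenceAmplicon
) -> CoibCall:
    """Classify one aligned COIB read."""
    c1164 = call_site(alignment, ref, ref.site_by_name(SITE_1164))
    c1287 = call_site(alignment, ref, ref.site_by_name(SITE_1287))
    return CoibCall(
        specimen_id=specimen_id,
        category=classify_coib(c1164, c1287),
        site_calls=(c1164, c1287),
    )


def default_span(ref: ReferenceAmplicon) -> tuple[int, int]:
    """Full inter-primer comparison span, in gene coordinates."""
    return ref.coordinate_offset, ref.coordinate_offset + len(ref.sequence) - 1


def dereplicate_variants(
    calls: Sequence[CoibCall],
    alignments: Sequence[Alignment],
    ref: ReferenceAmplicon,
    registry: HaplotypeRegistry,
    span: tuple[int, int] | None = None,
) -> list[CoibCall]:
    """Assign lettered variant labels within each CSh category.

    Each read already classified to a CSh category is compared exact-match
    over ``span`` (default: the whole amplicon).  A known sequence gets its
    canonical label; a novel one is minted the next unused letter within
    its category, in discovery order.  Reads with any ambiguity letter
    inside the span, or not covering it fully, keep ``variant_label=None``.
    The registry is updated in place.
    """
    if registry.marker != "COIB":
        raise ValueError("variant dereplication needs a COIB registry")
    if span is None:
        span = default_span(ref)
    if len(calls) != len(alignments):
        raise ValueError("calls and alignments must be parallel")
    out: list[CoibCall] = []
    for call, aln in zip(calls, alignments):
        label = None
        if call.category in CSH_CATEGORIES:
            segment, covered = extract_span(aln, ref, span[0], span[1])
            if covered and set(segment) <= set("ACGT"):
                entry = registry.lookup(segment)
                if entry is None:
                    entry = registry.mint(segment, category=call.category)
                label = entry.label
        out.append(
            CoibCall(
                specimen_id=call.specimen_id,
                category=call.category,
                site_calls=call.site_calls,
                variant_label=label,
            )
        )
    return out
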
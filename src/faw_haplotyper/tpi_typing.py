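"""Tpi-based strain identification and TpiI4a200 intron haplotyping.

The Z-linked Tpi gene carries three strain-biased polymorphic sites in its
fourth exon (gTpi165Y, gTpi168Y, gTpi183Y).  gTpi183Y corresponds most
consistently with host plant and is the diagnostic marker:

* C at 183 -> C_Tpi (corn-strain)
* T at 183 -> R_Tpi (rice-strain)
* C/T overlap (IUPAC Y) -> H_Tpi, an inter-strain hybrid male whose two Z
  alleles disagree at the site
* any other state set -> undetermined

gTpi165Y and gTpi168Y are consistency checks only: disagreements are
flagged but never override the 183-based call.

The adjacent fourth intron (TpiI4) is hypervariable with frequent indels.
Because males carry two Z alleles and the PCR product is sequenced
directly, heterozygous specimens give ambiguous intron traces and are
excluded from intron haplotyping; only reads that are clean A/C/G/T across
the analysis window are dereplicated into iC haplotypes.  The window is
the first 60% of the reference intron (~200 bp), a compromise that keeps
enough variation to separate haplotypes while discarding the downstream
region where indel-induced ambiguity accumulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .registry import HaplotypeRegistry
from .sequence_core import (
    Alignment,
    ReferenceAmplicon,
    SiteCall,
    call_site,
    extract_span,
)

SITE_183 = "gTpi183Y"
CONSISTENCY_SITES = ("gTpi165Y", "gTpi168Y")

#: diagnostic-state table at gTpi183Y
STRAIN_TABLE: dict[frozenset[str], str] = {
    frozenset("C"): "C_Tpi",
    frozenset("T"): "R_Tpi",
    frozenset("CT"): "H_Tpi",
}

#: base expected at the consistency sites for each pure-strain call
_EXPECTED_CONSISTENT = {"C_Tpi": frozenset("C"), "R_Tpi": frozenset("T"), "H_Tpi": frozenset("CT")}

ExclusionReason = Literal["ambiguous-base", "incomplete-coverage", "strain-mismatch-policy"]


@dataclass
class TpiStrainCall:
    specimen_id: str
    strain: str  # C_Tpi, R_Tpi, H_Tpi, undetermined
    site183: SiteCall | None = None
    consistency_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def is_typed(self) -> bool:
        return self.strain in ("C_Tpi", "R_Tpi", "H_Tpi")


@dataclass
class IntronHaplotypeCall:
    specimen_id: str
    usable: bool
    segment: str = ""
    haplotype_label: str | None = None
    exclusion_reason: ExclusionReason | None = None


def strain_from_site(call183: SiteCall) -> str:
    """Strain from the observed state set at gTpi183Y."""
    if call183.status in ("gap", "uncovered"):
        return "undetermined"
    return STRAIN_TABLE.get(call183.observed_states, "undetermined")


def call_strain(
    alignment: Alignment, ref: ReferenceAmplicon, specimen_id: str = ""
) -> TpiStrainCall:
    """Strain call for one aligned Tpi read, with 165/168 consistency flags.

    A flag is True when the consistency site's observed states equal those
    expected for the 183-based strain (C for C_Tpi, T for R_Tpi, the C/T
    overlap for H_Tpi).  Flags are informative only.
    """
    call183 = call_site(alignment, ref, ref.site_by_name(SITE_183))
    strain = strain_from_site(call183)
    flags: dict[str, bool] = {}
    if strain in _EXPECTED_CONSISTENT:
        expected = _EXPECTED_CONSISTENT[strain]
        for name in CONSISTENCY_SITES:
            sc = call_site(alignment, ref, ref.site_by_name(name))
            flags[name] = sc.observed_states == expected
    return TpiStrainCall(specimen_id, strain, call183, flags)


def intron_window(ref: ReferenceAmplicon, fraction: float = 0.6) -> tuple[int, int, int]:
    """(start, end, length) of the analysis window in gene coordinates.

    The window covers the first ``round(fraction * intron_length)``
    reference columns of the intron, inclusive on both ends.
    """
    if ref.intron_boundary is None or ref.intron_length is None:
        raise ValueError("reference has no intron annotation")
    length = int(math.floor(fraction * ref.intron_length + 0.5))
    start = ref.coordinate_offset + ref.intron_boundary - 1
    return start, start + length - 1, length


def extract_intron_segment(
    alignment: Alignment,
    ref: ReferenceAmplicon,
    specimen_id: str = "",
    fraction: float = 0.6,
) -> IntronHaplotypeCall:
    """Pull the TpiI4a200 segment out of one aligned read.

    The segment consists of the read bases aligned to the window's
    reference columns plus read insertions strictly inside the window
    (insertions at the right edge are excluded).  Usability requires full
    coverage of the window and a clean A/C/G/T segment; an ambiguity letter
    anywhere inside marks the specimen heterozygous and unusable.
    """
    start, end, _ = intron_window(ref, fraction)
    segment, covered = extract_span(alignment, ref, start, end)
    if not covered:
        return IntronHaplotypeCall(specimen_id, False, "", None, "incomplete-coverage")
    if set(segment) - set("ACGT"):
        return IntronHaplotypeCall(specimen_id, False, "", None, "ambiguous-base")
    if not segment:
        return IntronHaplotypeCall(specimen_id, False, "", None, "incomplete-coverage")
    return IntronHaplotypeCall(specimen_id, True, segment)


def classify_intron_haplotype(
    call: IntronHaplotypeCall, registry: HaplotypeRegistry
) -> IntronHaplotypeCall:
    """Exact-match lookup of a usable segment; novel segments mint iCnn labels.

    The registry is updated in place.
    """
    if not call.usable:
        raise ValueError(f"{call.specimen_id}: cannot haplotype an unusable intron call")
    if registry.marker != "TpiI4a200":
        raise ValueError("intron haplotyping needs a TpiI4a200 registry")
    entry = registry.lookup(call.segment)
    if entry is None:
        entry = registry.mint(call.segment)
    return IntronHaplotypeCall(call.specimen_id, True, call.segment, entry.label)


def exclude_by_strain_policy(
    call: IntronHaplotypeCall, strain_call: TpiStrainCall
) -> IntronHaplotypeCall:
    """Apply the hybrid policy: H_Tpi specimens are never intron-haplotyped.

    H_Tpi males are heterozygous by construction (their two Z alleles come
    from different strains), so even a specimen whose alleles happen to
    coincide across the window is excluded, to keep the haplotype pool
    within-strain.  This is the one place strain identity feeds back into
    intron usability.
    """
    if strain_call.strain == "H_Tpi" and call.usable:
        return IntronHaplotypeCall(
            call.specimen_id, False, "", None, "strain-mismatch-policy"
        )
    return call
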
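"""Built-in synthetic reference amplicons.

The typing logic only needs an annotated coordinate frame: a reference
sequence, the marker-site positions on it, and (for Tpi) the exon/intron
boundary.  The references bundled here are synthetic stand-ins carrying
the field-standard site annotations (mCOI1164D/mCOI1287R on COIB;
gTpi165Y/gTpi168Y/gTpi183Y and the TpiI4 intron on Tpi); their backbone
sequence is randomly generated once with a fixed seed, so they are fully
reproducible and ship as code, not data.

For analysis of real specimens, references derived from annotated GenBank
amplicons can be loaded with :func:`faw_haplotyper.sequence_core.read_reference`
from a FASTA + sidecar annotation TSV with the same site names.
"""

from __future__ import annotations

import numpy as np

from .sequence_core import MarkerSite, ReferenceAmplicon

# fixed internal seed: the synthetic backbones are constants of the package
_BACKBONE_SEED = 730201

#: COIB amplicon span in gene coordinates (primer-to-primer, 1-based closed)
COIB_OFFSET = 891
COIB_LENGTH = 603

#: Tpi amplicon layout (amplicon-local coordinates, offset 1)
TPI_OFFSET = 1
TPI_EXON4_LENGTH = 280
TPI_INTRON_LENGTH = 333
TPI_EXON5_STUB = 80
TPI_LENGTH = TPI_EXON4_LENGTH + TPI_INTRON_LENGTH + TPI_EXON5_STUB
TPI_INTRON_BOUNDARY = TPI_EXON4_LENGTH + 1


def _random_backbone(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def coib_reference() -> ReferenceAmplicon:
    """Synthetic COIB reference with the two h-haplotype defining sites.

    The reference carries A at 1164 and G at 1287 (the CSh2 configuration,
    the majority category in Texas-like collections).
    """
    rng = np.random.default_rng([_BACKBONE_SEED, 1])
    seq = _random_backbone(rng, COIB_LENGTH)
    seq[1164 - COIB_OFFSET] = "A"
    seq[1287 - COIB_OFFSET] = "G"
    sites = [
        MarkerSite("mCOI1164D", "COI", 1164, frozenset("AGT"), "h-haplotype-defining"),
        MarkerSite("mCOI1287R", "COI", 1287, frozenset("AG"), "h-haplotype-defining"),
    ]
    return ReferenceAmplicon(
        gene="COI",
        sequence="".join(seq),
        coordinate_offset=COIB_OFFSET,
        sites=sites,
        provenance="synthetic backbone with COIB site annotations",
    )


def tpi_reference() -> ReferenceAmplicon:
    """Synthetic Tpi exon4+intron reference (C-strain states at the exon sites).

    Layout: exon 4 (positions 1-280, diagnostic sites at 165/168/183),
    TpiI4 intron (281-613, 333 bp, canonical GT donor), exon 5 stub
    (614-693).  The 60% analysis window is therefore 200 reference columns
    (281-480).
    """
    rng = np.random.default_rng([_BACKBONE_SEED, 2])
    seq = _random_backbone(rng, TPI_LENGTH)
    for pos in (165, 168, 183):
        seq[pos - TPI_OFFSET] = "C"
    b = TPI_INTRON_BOUNDARY - TPI_OFFSET
    seq[b] = "G"
    seq[b + 1] = "T"
    sites = [
        MarkerSite("gTpi165Y", "Tpi", 165, frozenset("CT"), "consistency-check"),
        MarkerSite("gTpi168Y", "Tpi", 168, frozenset("CT"), "consistency-check"),
        MarkerSite("gTpi183Y", "Tpi", 183, frozenset("CT"), "strain-diagnostic"),
    ]
    return ReferenceAmplicon(
        gene="Tpi",
        sequence="".join(seq),
        coordinate_offset=TPI_OFFSET,
        sites=sites,
        intron_boundary=TPI_INTRON_BOUNDARY,
        intron_length=TPI_INTRON_LENGTH,
        provenance="synthetic backbone with Tpi exon/intron annotations",
    )
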
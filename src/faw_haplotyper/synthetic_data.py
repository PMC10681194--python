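"""Synthetic study generator: populations of Sanger-typed specimens.

Emulates the data-generating process the typing pipeline assumes:

* each specimen is a male moth carrying one maternal (mitochondrial) COIB
  allele and **two** Z-linked Tpi alleles;
* the COIB read is the single maternal allele, drawn from a per-population
  h-haplotype category profile and a within-category lettered-variant
  profile;
* the Tpi read is the *merge* of the two alleles, as produced by directly
  sequencing a diploid PCR product: positions where the alleles agree give
  a plain base, substitution differences give the IUPAC overlap letter,
  and an indel difference frame-shifts the double trace, rendering every
  merged position downstream of the first indel unreadable (N);
* with probability ``hybrid_rate`` the two Z alleles come from different
  host strains (an inter-strain hybrid), producing the diagnostic C/T
  overlap at gTpi183Y; otherwise, with probability ``heterozygosity`` the
  two same-strain alleles differ by one substitution or (with probability
  ``indel_het_fraction``) one indel inside the intron analysis window;
* the COIB category is linked to the maternal strain: an R-strain mother
  transmits R_COIB, a C-strain mother one of CSh1-4.

Every draw is made from a per-specimen RNG stream derived from
``(seed, population index, specimen index)``, so adding a population or a
specimen never perturbs earlier draws and studies are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .coib_typing import COIB_TABLE, CSH_CATEGORIES
from .iupac import merge_letters
from .references import coib_reference, tpi_reference
from .registry import HaplotypeRegistry, save_registry
from .sequence_core import (
    DEFAULT_SCORING,
    ReferenceAmplicon,
    SangerRead,
    SpecimenRecord,
    global_align,
    write_fasta,
    write_metadata,
)
from .tpi_typing import extract_intron_segment, intron_window

HetKind = Literal["hom", "sub", "indel", "hybrid"]

#: positions near window edges and the splice donor are kept free of planted
#: edits so that gap placement can never slide across a boundary
EDIT_MARGIN = 8


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _check_profile(name: str, values) -> None:
    total = float(np.sum(list(values)))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities sum to {total}, expected 1")
    if any(v < 0 for v in values):
        raise ValueError(f"{name}: negative probability")


@dataclass
class PopulationConfig:
    """Per-population sampling parameters.

    Variant/haplotype profiles are probability vectors over pool members in
    pool order (index 0 is the predominant, unedited variant).
    """

    name: str
    n_specimens: int
    coib_category_profile: dict[str, float]
    coib_variant_profiles: dict[str, list[float]]
    intron_haplotype_profile: list[float]
    strain_profile: dict[str, float]
    hybrid_rate: float = 0.0
    heterozygosity: float = 0.0
    indel_het_fraction: float = 0.5
    noise_rate: float = 0.0
    year: int = 2021
    habitat: str = "corn"
    collection_type: str = "T"

    def __post_init__(self) -> None:
        if self.n_specimens < 0:
            raise ValueError("n_specimens must be non-negative")
        bad = set(self.coib_category_profile) - set(CSH_CATEGORIES)
        if bad:
            raise ValueError(f"coib_category_profile has unknown categories {bad}")
        _check_profile(f"{self.name}.coib_category_profile", self.coib_category_profile.values())
        for cat, prof in self.coib_variant_profiles.items():
            _check_profile(f"{self.name}.coib_variant_profiles[{cat}]", prof)
        _check_profile(f"{self.name}.intron_haplotype_profile", self.intron_haplotype_profile)
        if set(self.strain_profile) != {"C", "R"}:
            raise ValueError("strain_profile must have exactly the keys C and R")
        _check_profile(f"{self.name}.strain_profile", self.strain_profile.values())
        for rate_name in ("hybrid_rate", "heterozygosity", "indel_het_fraction", "noise_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{self.name}.{rate_name}={rate} outside [0, 1]")


@dataclass
class SimulationConfig:
    seed: int
    populations: list[PopulationConfig]
    #: variant profile for the R_COIB pool (R-strain mothers)
    r_coib_variant_profile: list[float] = field(default_factory=lambda: [1.0])
    #: per-base substitution rate used when generating pool variants
    pool_substitution_rate: float = 0.01
    #: per-base indel rate for intron pool variants
    pool_indel_rate: float = 0.01

    def __post_init__(self) -> None:
        _check_profile("r_coib_variant_profile", self.r_coib_variant_profile)
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        pops = [PopulationConfig(**p) for p in data["populations"]]
        rest = {k: v for k, v in data.items() if k != "populations"}
        return cls(populations=pops, **rest)

    def to_dict(self) -> dict:
        return asdict(self)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as handle:
        return SimulationConfig.from_dict(yaml.safe_load(handle))


def example_config(seed: int = 1) -> SimulationConfig:
    """A three-population study with qualitatively realistic profiles.

    The profiles mimic the broad pattern seen in North American fall
    armyworm collections — a CSh2-majority "TX-like" population, a
    CSh4-majority "FL-like" one, and a CSh2-dominated "AZ-like" one with no
    R-strain — but they are synthetic settings, not field estimates.
    """
    base_variants = {
        "CSh1": [0.70, 0.20, 0.10],
        "CSh2": [0.77, 0.13, 0.10],
        "CSh3": [1.00],
        "CSh4": [0.91, 0.09],
    }
    pops = [
        PopulationConfig(
            name="TX-like",
            n_specimens=150,
            coib_category_profile={"CSh1": 0.20, "CSh2": 0.65, "CSh3": 0.01, "CSh4": 0.14},
            coib_variant_profiles=base_variants,
            intron_haplotype_profile=[0.60, 0.20, 0.10, 0.06, 0.04],
            strain_profile={"C": 0.8, "R": 0.2},
            hybrid_rate=0.10,
            heterozygosity=0.50,
        ),
        PopulationConfig(
            name="FL-like",
            n_specimens=150,
            coib_category_profile={"CSh1": 0.10, "CSh2": 0.15, "CSh3": 0.01, "CSh4": 0.74},
            coib_variant_profiles=base_variants,
            intron_haplotype_profile=[0.45, 0.10, 0.25, 0.10, 0.10],
            strain_profile={"C": 0.8, "R": 0.2},
            hybrid_rate=0.10,
            heterozygosity=0.50,
        ),
        PopulationConfig(
            name="AZ-like",
            n_specimens=150,
            coib_category_profile={"CSh1": 0.18, "CSh2": 0.68, "CSh3": 0.0, "CSh4": 0.14},
            coib_variant_profiles=base_variants,
            intron_haplotype_profile=[0.70, 0.15, 0.10, 0.05, 0.0],
            strain_profile={"C": 1.0, "R": 0.0},
            hybrid_rate=0.0,
            heterozygosity=0.50,
        ),
    ]
    return SimulationConfig(seed=seed, populations=pops)


# ---------------------------------------------------------------------------
# variant pools
# ---------------------------------------------------------------------------


@dataclass
class StudyPools:
    coib_ref: ReferenceAmplicon
    tpi_ref: ReferenceAmplicon
    #: category -> list of full COIB amplicon sequences (index = variant)
    coib: dict[str, list[str]]
    #: canonical COIB variant registry (labels CSh1[a], ... in pool order)
    coib_registry: HaplotypeRegistry
    #: list of full intron sequences (index = haplotype)
    introns: list[str]
    #: canonical TpiI4a200 registry of window segments (iC01, ... in pool order)
    intron_registry: HaplotypeRegistry
    #: strain -> full Tpi allele per intron haplotype index
    tpi_alleles: dict[str, list[str]]
    #: intron label per haplotype index
    intron_labels: list[str]
    #: variant profile over the R_COIB pool
    r_coib_profile: list[float] = field(default_factory=lambda: [1.0])


_DEFINING_STATES = {cat: pair for pair, cat in COIB_TABLE.items()}


def make_variant_pool(
    ref: ReferenceAmplicon,
    site_edits: dict[int, str],
    n_variants: int,
    rng: np.random.Generator,
    substitution_rate: float = 0.01,
    editable: tuple[int, int] | None = None,
    max_attempts: int = 200,
) -> list[str]:
    """Distinct full-amplicon variants sharing fixed defining-site states.

    ``site_edits`` maps gene-coordinate positions to the base every pool
    member must carry.  Variant 0 is the plain edited reference; each
    further variant adds ``1 + Binomial(L, substitution_rate)`` random
    substitutions inside the editable span (defaults to the amplicon minus
    a short end margin), avoiding the defining sites.  Deterministic given
    the RNG state.
    """
    base = list(ref.sequence)
    for pos, state in site_edits.items():
        base[pos - ref.coordinate_offset] = state
    if editable is None:
        editable = (
            ref.coordinate_offset + EDIT_MARGIN,
            ref.coordinate_offset + len(ref.sequence) - 1 - EDIT_MARGIN,
        )
    lo = editable[0] - ref.coordinate_offset
    hi = editable[1] - ref.coordinate_offset
    candidates = np.array(
        [i for i in range(lo, hi + 1) if i + ref.coordinate_offset not in site_edits]
    )
    pool = ["".join(base)]
    seen = {pool[0]}
    while len(pool) < n_variants:
        for attempt in range(max_attempts):
            n_subs = 1 + rng.binomial(len(candidates), substitution_rate)
            positions = rng.choice(candidates, size=min(n_subs, len(candidates)), replace=False)
            variant = list(pool[0])
            for p in positions:
                current = variant[p]
                variant[p] = str(rng.choice([b for b in "ACGT" if b != current]))
            s = "".join(variant)
            if s not in seen:
                pool.append(s)
                seen.add(s)
                break
        else:
            raise RuntimeError(
                f"could not generate {n_variants} distinct variants in {max_attempts} attempts"
            )
    return pool


def _window_zone(tpi_ref: ReferenceAmplicon) -> tuple[int, int]:
    """Editable gene-coordinate span inside the intron analysis window."""
    start, end, _ = intron_window(tpi_ref)
    return start + EDIT_MARGIN, end - EDIT_MARGIN


def make_intron_pool(
    tpi_ref: ReferenceAmplicon,
    n_variants: int,
    rng: np.random.Generator,
    substitution_rate: float = 0.01,
    indel_rate: float = 0.01,
    max_attempts: int = 200,
) -> list[str]:
    """Distinct full intron sequences differing inside the analysis window.

    Variant 0 is the reference intron.  Further variants carry random
    substitutions and short (1-3 bp) indels confined to the window interior,
    so every pair of pool members is distinguishable by its extracted
    TpiI4a200 segment.
    """
    b = tpi_ref.intron_boundary - 1
    ref_intron = tpi_ref.sequence[b : b + tpi_ref.intron_length]
    zone_start, zone_end, _ = intron_window(tpi_ref)
    # indices within the intron string, clear of the donor and window edges
    lo = max(EDIT_MARGIN, 2)
    hi = (zone_end - zone_start + 1) - EDIT_MARGIN
    zone = np.arange(lo, hi)
    pool = [ref_intron]
    seen = {ref_intron[: hi + EDIT_MARGIN]}
    while len(pool) < n_variants:
        for attempt in range(max_attempts):
            variant = list(ref_intron)
            n_subs = 1 + rng.binomial(len(zone), substitution_rate)
            positions = rng.choice(zone, size=min(n_subs, len(zone)), replace=False)
            for p in positions:
                current = variant[p]
                variant[p] = str(rng.choice([b2 for b2 in "ACGT" if b2 != current]))
            n_indels = rng.binomial(len(zone), indel_rate)
            for _ in range(n_indels):
                p = int(rng.choice(zone))
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5 and len(variant) > size + p:
                    del variant[p : p + size]
                else:
                    insert = "".join(rng.choice(list("ACGT"), size=size))
                    variant[p:p] = list(insert)
            s = "".join(variant)
            key = s[: hi + EDIT_MARGIN]  # window-region prefix decides distinctness
            if key not in seen:
                pool.append(s)
                seen.add(key)
                break
        else:
            raise RuntimeError(
                f"could not generate {n_variants} distinct intron variants "
                f"in {max_attempts} attempts"
            )
    return pool


def _tpi_allele(tpi_ref: ReferenceAmplicon, strain: str, intron: str) -> str:
    """Full Tpi amplicon: exon 4 with strain states, intron variant, exon 5 stub."""
    b = tpi_ref.intron_boundary - 1
    exon4 = list(tpi_ref.sequence[:b])
    state = "C" if strain == "C" else "T"
    for site in tpi_ref.sites:
        exon4[site.ref_position - tpi_ref.coordinate_offset] = state
    stub = tpi_ref.sequence[b + tpi_ref.intron_length :]
    return "".join(exon4) + intron + stub


def build_pools(config: SimulationConfig) -> StudyPools:
    """Build all variant pools and canonical registries for one study."""
    coib_ref = coib_reference()
    tpi_ref = tpi_reference()
    rng = np.random.default_rng([config.seed, 0])

    n_by_cat: dict[str, int] = {}
    for pop in config.populations:
        for cat, prof in pop.coib_variant_profiles.items():
            n_by_cat[cat] = max(n_by_cat.get(cat, 0), len(prof))
    coib_pools: dict[str, list[str]] = {}
    coib_registry = HaplotypeRegistry(marker="COIB")
    for cat in CSH_CATEGORIES:
        if cat not in n_by_cat:
            continue
        s1164, s1287 = _DEFINING_STATES[cat]
        pool = make_variant_pool(
            coib_ref,
            {1164: s1164, 1287: s1287},
            n_by_cat[cat],
            rng,
            substitution_rate=config.pool_substitution_rate,
        )
        coib_pools[cat] = pool
        for seq in pool:
            coib_registry.mint(seq, category=cat, provenance="synthetic pool")
    s1164, s1287 = _DEFINING_STATES["R_COIB"]
    coib_pools["R_COIB"] = make_variant_pool(
        coib_ref,
        {1164: s1164, 1287: s1287},
        len(config.r_coib_variant_profile),
        rng,
        substitution_rate=config.pool_substitution_rate,
    )

    n_intron = max(len(p.intron_haplotype_profile) for p in config.populations)
    introns = make_intron_pool(
        tpi_ref,
        n_intron,
        rng,
        substitution_rate=config.pool_substitution_rate,
        indel_rate=config.pool_indel_rate,
    )
    tpi_alleles = {
        strain: [_tpi_allele(tpi_ref, strain, intron) for intron in introns]
        for strain in ("C", "R")
    }
    intron_registry = HaplotypeRegistry(marker="TpiI4a200")
    intron_labels: list[str] = []
    for idx in range(n_intron):
        # canonical segment: what extraction yields on a clean homozygous read
        allele = tpi_alleles["C"][idx]
        aln = global_align(allele, tpi_ref, DEFAULT_SCORING)
        call = extract_intron_segment(aln, tpi_ref, specimen_id=f"pool{idx}")
        if not call.usable:  # pragma: no cover - pool construction guarantees this
            raise RuntimeError(f"pool intron {idx} yields unusable segment")
        entry = intron_registry.mint(call.segment, provenance="synthetic pool")
        intron_labels.append(entry.label)

    return StudyPools(
        coib_ref=coib_ref,
        tpi_ref=tpi_ref,
        coib=coib_pools,
        coib_registry=coib_registry,
        introns=introns,
        intron_registry=intron_registry,
        tpi_alleles=tpi_alleles,
        intron_labels=intron_labels,
        r_coib_profile=list(config.r_coib_variant_profile),
    )


# ---------------------------------------------------------------------------
# specimen simulation
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    specimen_id: str
    population: str
    maternal_strain: str
    coib_category: str
    coib_variant: str
    allele1_strain: str
    allele2_strain: str
    allele1_intron: str
    allele2_intron: str
    het_kind: HetKind
    expected_strain: str
    expected_intron_usable: bool
    expected_intron_haplotype: str
    expected_exclusion_reason: str


def merge_alleles(allele1: str, allele2: str) -> str:
    """Merge two Tpi alleles into the read a direct Sanger run would give.

    Identical alleles merge to themselves; substitution differences become
    IUPAC overlap letters; at the first indel difference the superimposed
    traces fall out of register, so every merged position from that column
    on is N.
    """
    if allele1 == allele2:
        return allele1
    aln = global_align(allele2, allele1)  # ref=allele1, read=allele2
    out: list[str] = []
    shifted = False
    for a, b in zip(aln.aligned_ref, aln.aligned_read):
        if a == "-" or b == "-":
            shifted = True
        out.append("N" if shifted else (a if a == b else merge_letters(a, b)))
    return "".join(out)


def _mutate_partner(
    allele: str, kind: HetKind, zone: tuple[int, int], rng: np.random.Generator
) -> str:
    """Second Z allele for a within-strain heterozygote: one edit in the window.

    ``zone`` is a 0-based index span on the allele string; pool indels
    shift positions by at most a few bases, which the window edit margin
    absorbs, so the edit always lands strictly inside the analysis window.
    """
    p = int(rng.integers(zone[0], zone[1] + 1))
    variant = list(allele)
    if kind == "sub":
        variant[p] = str(rng.choice([b for b in "ACGT" if b != variant[p]]))
    else:
        if rng.random() < 0.5:
            del variant[p]
        else:
            variant[p:p] = [str(rng.choice(list("ACGT")))]
    return "".join(variant)


def _apply_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def _choice(rng: np.random.Generator, options: list, probs: list[float]):
    return options[int(rng.choice(len(options), p=np.asarray(probs, dtype=float)))]


def simulate_specimen(
    pools: StudyPools,
    pop: PopulationConfig,
    specimen_id: str,
    rng: np.random.Generator,
) -> tuple[SangerRead, SangerRead, TruthRecord]:
    """Draw one specimen: COIB read, merged Tpi read, and its truth record."""
    maternal = _choice(rng, ["C", "R"], [pop.strain_profile["C"], pop.strain_profile["R"]])

    # --- COIB (haploid, maternally inherited) ---
    if maternal == "R":
        category = "R_COIB"
        idx = _choice(rng, list(range(len(pools.coib["R_COIB"]))), pools.r_coib_profile)
        coib_seq = pools.coib["R_COIB"][idx]
        coib_variant = ""
    else:
        cats = sorted(pop.coib_category_profile)
        category = _choice(rng, cats, [pop.coib_category_profile[c] for c in cats])
        prof = pop.coib_variant_profiles[category]
        idx = _choice(rng, list(range(len(prof))), prof)
        coib_seq = pools.coib[category][idx]
        coib_variant = pools.coib_registry.label_of(coib_seq) or ""

    # --- Tpi allele pair ---
    gz = _window_zone(pools.tpi_ref)
    window_zone = (
        gz[0] - pools.tpi_ref.coordinate_offset,
        gz[1] - pools.tpi_ref.coordinate_offset,
    )
    prof = pop.intron_haplotype_profile
    indices = list(range(len(prof)))
    u_hybrid = rng.random()
    u_het = rng.random()
    if u_hybrid < pop.hybrid_rate:
        het_kind: HetKind = "hybrid"
        other = "R" if maternal == "C" else "C"
        idx1 = _choice(rng, indices, prof)
        idx2 = _choice(rng, indices, prof)
        allele1 = pools.tpi_alleles[maternal][idx1]
        allele2 = pools.tpi_alleles[other][idx2]
        strains = (maternal, other)
        labels = (pools.intron_labels[idx1], pools.intron_labels[idx2])
    else:
        idx1 = idx2 = _choice(rng, indices, prof)
        allele1 = pools.tpi_alleles[maternal][idx1]
        strains = (maternal, maternal)
        labels = (pools.intron_labels[idx1], pools.intron_labels[idx1])
        if u_het < pop.heterozygosity:
            het_kind = "indel" if rng.random() < pop.indel_het_fraction else "sub"
            allele2 = _mutate_partner(allele1, het_kind, window_zone, rng)
            labels = (labels[0], f"{labels[0]}*")  # ad-hoc partner, not a pool member
        else:
            het_kind = "hom"
            allele2 = allele1

    tpi_seq = merge_alleles(allele1, allele2)
    coib_seq = _apply_noise(coib_seq, pop.noise_rate, rng)
    tpi_seq = _apply_noise(tpi_seq, pop.noise_rate, rng)

    # --- expected outcomes under the typing rules (noise-free assumptions) ---
    if het_kind == "hybrid":
        expected_strain = "H_Tpi"
        if labels[0] == labels[1]:
            expected_usable, expected_label, reason = False, "", "strain-mismatch-policy"
        else:
            expected_usable, expected_label, reason = False, "", "ambiguous-base"
    else:
        expected_strain = "C_Tpi" if maternal == "C" else "R_Tpi"
        if het_kind == "hom":
            expected_usable, expected_label, reason = True, labels[0], ""
        else:
            expected_usable, expected_label, reason = False, "", "ambiguous-base"

    truth = TruthRecord(
        specimen_id=specimen_id,
        population=pop.name,
        maternal_strain=maternal,
        coib_category=category,
        coib_variant=coib_variant,
        allele1_strain=strains[0],
        allele2_strain=strains[1],
        allele1_intron=labels[0],
        allele2_intron=labels[1],
        het_kind=het_kind,
        expected_strain=expected_strain,
        expected_intron_usable=expected_usable,
        expected_intron_haplotype=expected_label,
        expected_exclusion_reason=reason,
    )
    return (
        SangerRead(specimen_id, coib_seq, "COI"),
        SangerRead(specimen_id, tpi_seq, "Tpi"),
        truth,
    )


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    pools: StudyPools
    coib_reads: list[SangerRead]
    tpi_reads: list[SangerRead]
    metadata: list[SpecimenRecord]
    truth: list[TruthRecord]


def simulate_study(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedStudy:
    """Generate a full study; optionally write FASTA/TSV outputs.

    Outputs (when ``out_dir`` is given): ``coib.fasta``, ``tpi.fasta``,
    ``metadata.tsv``, ``truth.tsv`` plus the canonical variant registries
    under ``coib_registry/`` and ``tpi_registry/``.  Byte-identical across
    runs with the same config.
    """
    pools = build_pools(config)
    coib_reads: list[SangerRead] = []
    tpi_reads: list[SangerRead] = []
    metadata: list[SpecimenRecord] = []
    truth: list[TruthRecord] = []
    for pi, pop in enumerate(config.populations):
        for si in range(pop.n_specimens):
            rng = np.random.default_rng([config.seed, pi + 1, si])
            specimen_id = f"{pop.name}_{si:04d}"
            coib, tpi, rec = simulate_specimen(pools, pop, specimen_id, rng)
            coib_reads.append(coib)
            tpi_reads.append(tpi)
            truth.append(rec)
            metadata.append(
                SpecimenRecord(
                    specimen_id, pop.name, pop.year, pop.habitat, pop.collection_type
                )
            )
    study = SimulatedStudy(config, pools, coib_reads, tpi_reads, metadata, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(coib_reads, out / "coib.fasta")
        write_fasta(tpi_reads, out / "tpi.fasta")
        write_metadata(metadata, out / "metadata.tsv")
        write_truth(truth, out / "truth.tsv")
        save_registry(pools.coib_registry, out / "coib_registry")
        save_registry(pools.intron_registry, out / "tpi_registry")
    return study


TRUTH_COLUMNS = [f.name for f in TruthRecord.__dataclass_fields__.values()]


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in truth], columns=TRUTH_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(TRUTH_COLUMNS, row))
        d["expected_intron_usable"] = d["expected_intron_usable"] == "True"
        records.append(TruthRecord(**d))
    return records
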
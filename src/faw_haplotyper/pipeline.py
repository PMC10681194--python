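"""End-to-end typing pipeline: simulate/load -> type -> profile -> compare -> tree.

Each stage keeps a full accounting: every specimen in the metadata appears
exactly once per marker, either typed or excluded with an enumerated
reason.  Results go to TSV files; structured progress logging goes to
standard error.  A run summary (config snapshot, per-stage counts, seed,
version) is serialised next to the outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .coib_typing import CoibCall, classify_read, dereplicate_variants
from .popgen_profiles import (
    PopulationProfile,
    ProfileComparison,
    build_profile,
    nj_tree,
    pairwise_comparisons,
    pdistance_matrix,
    reference_joint_alignment,
)
from .references import coib_reference, tpi_reference
from .registry import HaplotypeRegistry, load_registry, save_registry
from .sequence_core import (
    DEFAULT_SCORING,
    Alignment,
    AlignmentScoring,
    ReferenceAmplicon,
    SangerRead,
    orient_read,
    read_fasta,
    read_metadata,
)
from .synthetic_data import SimulationConfig, simulate_study
from .tpi_typing import (
    IntronHaplotypeCall,
    TpiStrainCall,
    call_strain,
    classify_intron_haplotype,
    exclude_by_strain_policy,
    extract_intron_segment,
    intron_window,
)

logger = logging.getLogger("faw_haplotyper")


def _setup_logging() -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# typing stages
# ---------------------------------------------------------------------------


def type_coib(
    reads: Sequence[SangerRead],
    ref: ReferenceAmplicon | None = None,
    registry: HaplotypeRegistry | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[list[CoibCall], HaplotypeRegistry]:
    """Orient, align and classify COIB reads; dereplicate CSh variants."""
    ref = ref or coib_reference()
    registry = registry if registry is not None else HaplotypeRegistry(marker="COIB")
    calls: list[CoibCall] = []
    alignments: list[Alignment] = []
    for read in reads:
        _, aln = orient_read(read, ref, scoring)
        calls.append(classify_read(read.id, aln, ref))
        alignments.append(aln)
    calls = dereplicate_variants(calls, alignments, ref, registry)
    return calls, registry


def type_tpi(
    reads: Sequence[SangerRead],
    ref: ReferenceAmplicon | None = None,
    registry: HaplotypeRegistry | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[list[TpiStrainCall], list[IntronHaplotypeCall], HaplotypeRegistry]:
    """Strain-call Tpi reads and haplotype the TpiI4a200 segment.

    H_Tpi specimens are excluded from intron haplotyping by policy; all
    other exclusions are ambiguity- or coverage-driven.
    """
    ref = ref or tpi_reference()
    registry = registry if registry is not None else HaplotypeRegistry(marker="TpiI4a200")
    strain_calls: list[TpiStrainCall] = []
    intron_calls: list[IntronHaplotypeCall] = []
    for read in reads:
        _, aln = orient_read(read, ref, scoring)
        sc = call_strain(aln, ref, specimen_id=read.id)
        ic = extract_intron_segment(aln, ref, specimen_id=read.id)
        ic = exclude_by_strain_policy(ic, sc)
        if ic.usable:
            ic = classify_intron_haplotype(ic, registry)
        strain_calls.append(sc)
        intron_calls.append(ic)
    return strain_calls, intron_calls, registry


# ---------------------------------------------------------------------------
# run configuration and accounting
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Declarative run description (YAML).

    Either a ``simulate`` block (a :class:`SimulationConfig` mapping) or an
    ``inputs`` block with ``coib_fasta``, ``tpi_fasta`` and ``metadata``
    paths must be present.
    """

    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    coib_registry: str | None = None
    tpi_registry: str | None = None
    group_by: list[str] = field(default_factory=lambda: ["population"])
    compare_replicates: int = 10_000

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return PipelineConfig(**data)


@dataclass
class MarkerAccounting:
    input: int = 0
    typed: int = 0
    excluded: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.input != self.typed + sum(self.excluded.values()):
            raise AssertionError("accounting mismatch: input != typed + excluded")


@dataclass
class PipelineRun:
    config: dict
    seed: int
    version: str
    counts: dict[str, MarkerAccounting]
    output_paths: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _account_coib(calls: Sequence[CoibCall]) -> MarkerAccounting:
    acc = MarkerAccounting(input=len(calls))
    reasons: Counter[str] = Counter()
    for c in calls:
        if c.is_typed:
            acc.typed += 1
        else:
            reasons[c.category] += 1
    acc.excluded = dict(sorted(reasons.items()))
    acc.check()
    return acc


def _account_strain(calls: Sequence[TpiStrainCall]) -> MarkerAccounting:
    acc = MarkerAccounting(input=len(calls))
    reasons: Counter[str] = Counter()
    for c in calls:
        if c.is_typed:
            acc.typed += 1
        else:
            reasons[c.strain] += 1
    acc.excluded = dict(sorted(reasons.items()))
    acc.check()
    return acc


def _account_intron(calls: Sequence[IntronHaplotypeCall]) -> MarkerAccounting:
    acc = MarkerAccounting(input=len(calls))
    reasons: Counter[str] = Counter()
    for c in calls:
        if c.usable:
            acc.typed += 1
        else:
            reasons[c.exclusion_reason or "unknown"] += 1
    acc.excluded = dict(sorted(reasons.items()))
    acc.check()
    return acc


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def write_coib_calls(calls: Sequence[CoibCall], path: Path) -> None:
    rows = []
    for c in calls:
        s = c.site_calls or (None, None)
        rows.append(
            {
                "specimen_id": c.specimen_id,
                "category": c.category,
                "variant_label": c.variant_label or "",
                "state_1164": "".join(sorted(s[0].observed_states)) if s[0] else "",
                "state_1287": "".join(sorted(s[1].observed_states)) if s[1] else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tpi_calls(
    strain_calls: Sequence[TpiStrainCall],
    intron_calls: Sequence[IntronHaplotypeCall],
    path: Path,
) -> None:
    rows = []
    for sc, ic in zip(strain_calls, intron_calls):
        rows.append(
            {
                "specimen_id": sc.specimen_id,
                "strain": sc.strain,
                "state_183": "".join(sorted(sc.site183.observed_states)) if sc.site183 else "",
                "consistency_flags": ";".join(
                    f"{k}={'ok' if v else 'disagree'}" for k, v in sc.consistency_flags.items()
                ),
                "intron_usable": ic.usable,
                "intron_haplotype": ic.haplotype_label or "",
                "exclusion_reason": ic.exclusion_reason or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: Sequence[PopulationProfile], path: Path) -> None:
    rows = []
    for p in profiles:
        freqs = p.frequencies
        for cat, count in p.counts.items():
            rows.append(
                {
                    "population": p.population,
                    "marker": p.marker,
                    "category": cat,
                    "count": count,
                    "frequency": f"{freqs[cat]:.6f}",
                    "n_total": p.total,
                    "n_excluded": p.n_excluded,
                }
            )
        if not p.counts:
            rows.append(
                {
                    "population": p.population,
                    "marker": p.marker,
                    "category": "",
                    "count": 0,
                    "frequency": "",
                    "n_total": 0,
                    "n_excluded": p.n_excluded,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_comparisons(
    comparisons: Sequence[tuple[ProfileComparison, float]], path: Path
) -> None:
    rows = []
    for comp, p_holm in comparisons:
        rows.append(
            {
                "population_1": comp.populations[0],
                "population_2": comp.populations[1],
                "marker_categories": len(comp.categories),
                "G": f"{comp.statistic:.6f}",
                "df": comp.df,
                "p_asymptotic": f"{comp.p_asymptotic:.6g}",
                "p_permutation": f"{comp.p_permutation:.6g}",
                "p_permutation_holm": f"{p_holm:.6g}",
                "replicates": comp.n_replicates,
                "computable": comp.computable,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> PipelineRun:
    """Execute the full pipeline and write all stage outputs under ``out_dir``."""
    _setup_logging()
    if not isinstance(config, PipelineConfig):
        config = load_pipeline_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coib_ref = coib_reference()
    tpi_ref = tpi_reference()

    if config.simulate is not None:
        sim_config = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
        logger.info("stage=simulate populations=%d seed=%d", len(sim_config.populations), config.seed)
        study = simulate_study(sim_config, out / "simulated")
        coib_reads, tpi_reads, metadata = study.coib_reads, study.tpi_reads, study.metadata
    else:
        inputs = config.inputs
        for key in ("coib_fasta", "tpi_fasta", "metadata"):
            if key not in inputs:
                raise ValueError(f"inputs block missing {key!r}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input {key} not found: {inputs[key]}")
        coib_reads = read_fasta(inputs["coib_fasta"], gene="COI")
        tpi_reads = read_fasta(inputs["tpi_fasta"], gene="Tpi")
        metadata = read_metadata(inputs["metadata"])

    coib_registry = (
        load_registry(config.coib_registry)
        if config.coib_registry
        else HaplotypeRegistry(marker="COIB")
    )
    tpi_registry = (
        load_registry(config.tpi_registry)
        if config.tpi_registry
        else HaplotypeRegistry(marker="TpiI4a200")
    )

    logger.info("stage=type-coib reads=%d", len(coib_reads))
    coib_calls, coib_registry = type_coib(coib_reads, coib_ref, coib_registry)
    logger.info("stage=type-tpi reads=%d", len(tpi_reads))
    strain_calls, intron_calls, tpi_registry = type_tpi(tpi_reads, tpi_ref, tpi_registry)

    counts = {
        "COIB-category": _account_coib(coib_calls),
        "Tpi-strain": _account_strain(strain_calls),
        "TpiI4a200": _account_intron(intron_calls),
    }
    for marker, acc in counts.items():
        logger.info(
            "stage=accounting marker=%s input=%d typed=%d excluded=%s",
            marker, acc.input, acc.typed, acc.excluded,
        )

    keys = tuple(config.group_by)
    profiles = {
        "COIB-category": build_profile(coib_calls, metadata, "COIB-category", keys),
        "COIB-variant": build_profile(coib_calls, metadata, "COIB-variant", keys),
        "Tpi-strain": build_profile(strain_calls, metadata, "Tpi-strain", keys),
        "TpiI4a200": build_profile(intron_calls, metadata, "TpiI4a200", keys),
    }

    paths: dict[str, str] = {}

    def record(name: str, path: Path) -> Path:
        paths[name] = str(path)
        return path

    write_coib_calls(coib_calls, record("coib_calls", out / "coib_calls.tsv"))
    write_tpi_calls(strain_calls, intron_calls, record("tpi_calls", out / "tpi_calls.tsv"))
    for marker, profs in profiles.items():
        slug = marker.lower().replace("-", "_")
        write_profiles(profs, record(f"profiles_{slug}", out / f"profiles_{slug}.tsv"))

    logger.info("stage=compare marker=COIB-category replicates=%d", config.compare_replicates)
    comps = pairwise_comparisons(
        profiles["COIB-category"], replicates=config.compare_replicates, seed=config.seed
    )
    write_comparisons(comps, record("comparisons", out / "comparisons_coib_category.tsv"))

    # NJ tree of the observed intron haplotypes on p-distances
    if len(tpi_registry) >= 3:
        start, end, _ = intron_window(tpi_ref)
        anchor = tpi_ref.sequence[start - tpi_ref.coordinate_offset : end - tpi_ref.coordinate_offset + 1]
        joint = reference_joint_alignment({e.label: e.sequence for e in tpi_registry}, anchor)
        tree = nj_tree(pdistance_matrix(joint))
        tree_path = record("tree", out / "tpi_haplotypes.nwk")
        tree_path.write_text(tree.to_newick() + "\n")
        logger.info("stage=tree taxa=%d", len(tpi_registry))

    save_registry(coib_registry, out / "coib_registry")
    save_registry(tpi_registry, out / "tpi_registry")

    run = PipelineRun(
        config={
            "seed": config.seed,
            "simulate": config.simulate,
            "inputs": config.inputs,
            "group_by": list(config.group_by),
            "compare_replicates": config.compare_replicates,
        },
        seed=config.seed,
        version=__version__,
        counts=counts,
        output_paths=paths,
    )
    (out / "run.json").write_text(run.to_json() + "\n")
    logger.info("stage=done outputs=%d", len(paths))
    return run
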
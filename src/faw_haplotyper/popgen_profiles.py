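"""Population-level frequency profiles, profile comparison, and NJ trees.

Marker category counts per population (COIB h-haplotype categories, COIB
lettered variants, Tpi strains, TpiI4a200 intron haplotypes, SNP C
genotypes) are summarised as frequency profiles.  Profiles are compared
with a G-test (log-likelihood ratio over the 2 x k contingency table) whose
null distribution is obtained by Monte-Carlo permutation of specimens
between the two populations with fixed margins — exact under small counts,
no asymptotic reliance.  Haplotype relatedness is summarised by a
Neighbor-Joining tree on p-distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .sequence_core import AlignmentScoring, DEFAULT_SCORING, SpecimenRecord, global_align

# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

MARKERS = ("COIB-category", "COIB-variant", "TpiI4a200", "Tpi-strain", "SNP-C")


@dataclass
class PopulationProfile:
    population: str
    marker: str
    counts: dict[str, int] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative category count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.total
        if n == 0:
            return {}
        return {k: v / n for k, v in self.counts.items()}


def _category_of(call, marker: str) -> str | None:
    """Typed category of a per-specimen call under a marker, or None if excluded."""
    if marker == "COIB-category":
        return call.category if call.is_typed else None
    if marker == "COIB-variant":
        return call.variant_label
    if marker == "Tpi-strain":
        return call.strain if call.is_typed else None
    if marker == "TpiI4a200":
        return call.haplotype_label if call.usable else None
    raise ValueError(f"unknown marker {marker!r}")


def build_profile(
    calls: Sequence,
    metadata: Sequence[SpecimenRecord],
    marker: str,
    keys: Sequence[str] = ("population",),
) -> list[PopulationProfile]:
    """Group per-specimen calls into per-population frequency profiles.

    ``keys`` selects the metadata fields used for grouping (population,
    year, habitat, ...).  Ambiguous/no-call specimens are tallied in
    ``n_excluded`` and never enter the frequencies.
    """
    meta_by_id = {m.specimen_id: m for m in metadata}
    unknown = [c.specimen_id for c in calls if c.specimen_id not in meta_by_id]
    if unknown:
        raise ValueError(f"specimen ids missing from metadata: {unknown}")
    groups: dict[str, list] = {}
    for call in calls:
        rec = meta_by_id[call.specimen_id]
        key = "/".join(str(getattr(rec, k)) for k in keys)
        groups.setdefault(key, []).append(call)
    profiles = []
    for key in sorted(groups):
        counts: Counter[str] = Counter()
        excluded = 0
        for call in groups[key]:
            cat = _category_of(call, marker)
            if cat is None:
                excluded += 1
            else:
                counts[cat] += 1
        profiles.append(
            PopulationProfile(key, marker, dict(sorted(counts.items())), excluded)
        )
    return profiles


def snp_strain_composition(
    genotypes: Mapping[str, str], population: str = "all"
) -> PopulationProfile:
    """Strain composition from a SNP C diploid genotype table.

    The SNP C TaqMan assay scores each specimen C/C, C/R or R/R on the
    Z chromosome; no-calls are excluded.
    """
    mapping = {"C/C": "C-strain", "C/R": "heterozygote", "R/R": "R-strain"}
    counts: Counter[str] = Counter()
    excluded = 0
    bad = []
    for specimen, geno in genotypes.items():
        if geno == "no-call":
            excluded += 1
        elif geno in mapping:
            counts[mapping[geno]] += 1
        else:
            bad.append(f"{specimen}={geno!r}")
    if bad:
        raise ValueError(f"unknown SNP C genotypes: {', '.join(bad)}")
    return PopulationProfile(population, "SNP-C", dict(sorted(counts.items())), excluded)


# ---------------------------------------------------------------------------
# profile comparison (G-test with permutation null)
# ---------------------------------------------------------------------------


@dataclass
class ProfileComparison:
    populations: tuple[str, str]
    statistic: float
    df: int
    p_asymptotic: float
    p_permutation: float
    n_replicates: int
    seed: int | None
    computable: bool = True
    categories: tuple[str, ...] = ()


def g_statistic(table: np.ndarray) -> float:
    """G = 2 * sum O * ln(O/E) over a 2 x k table; O = 0 terms contribute 0."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def compare_profiles(
    p1: PopulationProfile,
    p2: PopulationProfile,
    replicates: int = 10_000,
    seed: int | None = None,
) -> ProfileComparison:
    """G-test of homogeneity between two frequency profiles.

    The permutation p-value reshuffles specimens between the populations
    with fixed margins (multivariate hypergeometric), using the
    add-one estimator (1 + #{G* >= G}) / (1 + R).
    """
    if p1.marker != p2.marker:
        raise ValueError(f"profiles compare different markers: {p1.marker} vs {p2.marker}")
    cats = sorted(set(p1.counts) | set(p2.counts))
    cats = [c for c in cats if p1.counts.get(c, 0) + p2.counts.get(c, 0) > 0]
    row1 = np.array([p1.counts.get(c, 0) for c in cats], dtype=np.int64)
    row2 = np.array([p2.counts.get(c, 0) for c in cats], dtype=np.int64)
    pops = (p1.population, p2.population)
    if len(cats) < 2 or row1.sum() == 0 or row2.sum() == 0:
        return ProfileComparison(
            pops, 0.0, 0, 1.0, 1.0, 0, seed, computable=False, categories=tuple(cats)
        )
    observed = g_statistic(np.vstack([row1, row2]))
    df = len(cats) - 1
    p_asym = float(chi2.sf(observed, df))

    rng = np.random.default_rng(seed)
    colsums = row1 + row2
    n1 = int(row1.sum())
    perm1 = rng.multivariate_hypergeometric(colsums, n1, size=replicates).astype(float)
    perm2 = colsums.astype(float) - perm1
    # vectorised G over all permuted tables
    n = float(colsums.sum())
    e1 = n1 / n * colsums
    e2 = (n - n1) / n * colsums
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(perm1 > 0, perm1 * np.log(perm1 / e1), 0.0)
        t2 = np.where(perm2 > 0, perm2 * np.log(perm2 / e2), 0.0)
    g_perm = 2.0 * (t1.sum(axis=1) + t2.sum(axis=1))
    p_perm = (1.0 + np.count_nonzero(g_perm >= observed - 1e-12)) / (1.0 + replicates)
    return ProfileComparison(
        pops, observed, df, p_asym, float(p_perm), replicates, seed, True, tuple(cats)
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    if len(p_values) == 0:
        return []
    from statsmodels.stats.multitest import multipletests

    return multipletests(p_values, method="holm")[1].tolist()


def pairwise_comparisons(
    profiles: Sequence[PopulationProfile],
    replicates: int = 10_000,
    seed: int | None = None,
) -> list[tuple[ProfileComparison, float]]:
    """All pairwise G-tests with Holm-adjusted permutation p-values."""
    comps = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            pair_seed = None if seed is None else (seed + 1000 * i + j) % (2**31)
            comps.append(compare_profiles(profiles[i], profiles[j], replicates, pair_seed))
    adj = holm_adjust([c.p_permutation for c in comps])
    return list(zip(comps, adj))


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def pdistance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distances over a joint alignment.

    p = mismatches / compared columns, with pairwise deletion of columns
    where either sequence has a gap or an ambiguity letter.  A pair with no
    comparable columns is an error.
    """
    labels = list(sequences)
    seqs = [sequences[l].upper() for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must come from a joint alignment (equal lengths)")
    arrays = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    clean = [np.isin(a, np.array([b"A", b"C", b"G", b"T"])) for a in arrays]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = clean[i] & clean[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((arrays[i][ok] != arrays[j][ok]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(labels, d)


def reference_joint_alignment(
    sequences: Mapping[str, str],
    anchor: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> dict[str, str]:
    """Reference-anchored joint alignment of a haplotype set.

    Each sequence is globally aligned to the anchor; insertion columns
    relative to the anchor are merged across sequences (left-justified,
    padded with gaps).  Adequate for high-identity haplotypes that all
    derive from one reference segment; not a general-purpose MSA.
    """
    per_seq: dict[str, tuple[list[str], dict[int, str]]] = {}
    ins_len: dict[int, int] = {}
    L = len(anchor)
    for label, seq in sequences.items():
        aln = global_align(seq, anchor, scoring)
        cols: list[str] = []  # read char over each anchor position
        inserts: dict[int, str] = {}  # junction index -> inserted read bases
        anchor_pos = -1  # 0-based index of last consumed anchor base
        for a, r in zip(aln.aligned_ref, aln.aligned_read):
            if a == "-":
                inserts[anchor_pos] = inserts.get(anchor_pos, "") + r
            else:
                anchor_pos += 1
                cols.append(r)
        per_seq[label] = (cols, inserts)
        for junction, chunk in inserts.items():
            ins_len[junction] = max(ins_len.get(junction, 0), len(chunk))
    out: dict[str, str] = {}
    for label, (cols, inserts) in per_seq.items():
        parts: list[str] = []
        for junction in range(-1, L):
            if junction >= 0:
                parts.append(cols[junction])
            width = ins_len.get(junction, 0)
            if width:
                chunk = inserts.get(junction, "")
                parts.append(chunk.ljust(width, "-"))
        out[label] = "".join(parts)
    return out


def plot_profiles(profiles: Sequence[PopulationProfile], path: str | Path) -> None:
    """Stacked-bar chart of category frequencies per population (optional).

    Requires matplotlib (the ``plot`` extra).  One bar per population,
    stacked by category, with the typed sample size above each bar.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    categories = sorted({c for p in profiles for c in p.counts})
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(profiles)), 4))
    x = np.arange(len(profiles))
    bottom = np.zeros(len(profiles))
    for cat in categories:
        heights = np.array([p.frequencies.get(cat, 0.0) for p in profiles])
        ax.bar(x, heights, bottom=bottom, label=cat)
        bottom += heights
    for i, p in enumerate(profiles):
        ax.text(i, 1.02, f"[{p.total}]", ha="center", fontsize=8)
    ax.set_xticks(x, [p.population for p in profiles], rotation=45, ha="right")
    ax.set_ylabel("frequency")
    ax.set_ylim(0, 1.1)
    ax.legend(fontsize=8, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class HaplotypeTree:
    """Unrooted NJ tree, stored with a trifurcating root node."""

    root: _Node
    labels: list[str]

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: _Node) -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(
                f"{fmt(child)}:{length:.{decimals}f}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def tip_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all pairs of tips."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        tips: dict[str, int] = {}

        def walk(node: _Node) -> int:
            nid = id(node)
            adjacency.setdefault(nid, [])
            if node.is_leaf:
                tips[node.label] = nid
            for child, length in node.children:
                cid = walk(child)
                adjacency[nid].append((cid, length))
                adjacency[cid].append((nid, length))
            return nid

        walk(self.root)
        n = len(self.labels)
        d = np.zeros((n, n))
        for i, label in enumerate(self.labels):
            dist = {tips[label]: 0.0}
            stack = [tips[label]]
            while stack:
                u = stack.pop()
                for v, w in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, other in enumerate(self.labels):
                d[i, j] = dist[tips[other]]
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(self.labels), d)


def nj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> HaplotypeTree:
    """Canonical Neighbor-Joining (Q-criterion, Studier–Keppler update).

    Ties in the Q matrix are broken by the lexicographically smallest index
    pair, making the output deterministic.  Negative branch lengths are
    reported as computed unless ``clamp_negative`` is set.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    dist = d.matrix.astype(float).copy()
    nodes: list[_Node] = [_Node(label=l) for l in d.labels]

    def maybe_clamp(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first occurrence in row-major order of the upper triangle = smallest (i, j)
        iu, ju = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu, ju]))
        i, j = int(iu[k]), int(ju[k])
        dij = dist[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = _Node(
            children=[(nodes[i], maybe_clamp(li)), (nodes[j], maybe_clamp(lj))]
        )
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_row[keep]])
        dist = np.hstack([dist, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = _Node(
        children=[(a, maybe_clamp(la)), (b, maybe_clamp(lb)), (c, maybe_clamp(lc))]
    )
    return HaplotypeTree(root=root, labels=list(d.labels))
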
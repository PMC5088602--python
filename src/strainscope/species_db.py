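"""Species delineation and per-species pan-genome construction.

Genomes are clustered into species by average-linkage (UPGMA) hierarchical
clustering on distances averaged over a panel of universal marker gene
families, with the tree cut at a distance of 0.035 (96.5% nucleotide
identity) — the cutoff at which marker-gene clusters best agree with the
95% genome-wide ANI species definition. Each species then gets a
representative genome (maximal mean marker identity to the other members)
and a pan-genome: the non-redundant set of gene clusters at 99% identity
across all member genomes, optionally aggregated into coarser families at
75-95% identity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import percent_identity

AGGREGATION_LEVELS = (75, 80, 85, 90, 95)


# ---------------------------------------------------------------------------
# distances


@dataclass
class MarkerGeneSet:
    """Marker gene sequences of one genome: at most one gene per family."""

    genome_id: str
    genes: dict[str, str]  # family_id -> sequence


@dataclass
class DistanceMatrix:
    """Symmetric genome-by-genome distance matrix with a defined-entry mask."""

    ids: list[str]
    values: np.ndarray   # (n, n) float
    defined: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n) and self.defined.shape == (n, n)


def marker_percent_identity(seq_a: str, seq_b: str, min_coverage: float = 0.70) -> float | None:
    """Percent identity of two marker genes; None if the best alignment
    covers <70% of either sequence."""
    return percent_identity(seq_a, seq_b, min_coverage=min_coverage)


def percent_identity_to_distance(pid: float) -> float:
    """D = (100 - P) / 100."""
    if not 0.0 <= pid <= 100.0:
        raise ValueError(f"percent identity {pid} outside [0, 100]")
    return (100.0 - pid) / 100.0


def family_distance_matrix(
    marker_sets: list[MarkerGeneSet], family_id: str, min_coverage: float = 0.70
) -> DistanceMatrix:
    """All-vs-all distances for one marker family; genomes lacking the
    family (or failing the coverage filter) get masked entries."""
    ids = [m.genome_id for m in marker_sets]
    n = len(ids)
    values = np.zeros((n, n))
    defined = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            a = marker_sets[i].genes.get(family_id)
            b = marker_sets[j].genes.get(family_id)
            if a is None or b is None:
                continue
            pid = marker_percent_identity(a, b, min_coverage)
            if pid is None:
                continue
            d = percent_identity_to_distance(pid)
            values[i, j] = values[j, i] = d
            defined[i, j] = defined[j, i] = True
    return DistanceMatrix(ids, values, defined)


def average_marker_distance(matrices: list[DistanceMatrix]) -> DistanceMatrix:
    """Mean of defined per-family distances; masked where no family is defined."""
    if not matrices:
        raise ValueError("no family distance matrices supplied")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValueError("family matrices cover different genome sets")
    n = len(ids)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for m in matrices:
        total += np.where(m.defined, m.values, 0.0)
        count += m.defined
    defined = count > 0
    values = np.divide(total, count, out=np.zeros((n, n)), where=defined)
    return DistanceMatrix(ids, values, defined)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class SpeciesAssignment:
    """Genome -> species map produced by cutting the UPGMA tree."""

    genome_to_species: dict[str, str]
    cutoff: float
    species_names: dict[str, str] = field(default_factory=dict)

    @property
    def species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for g, s in sorted(self.genome_to_species.items()):
            out[s].append(g)
        return dict(out)

    def n_species(self) -> int:
        return len(set(self.genome_to_species.values()))

    def same_species(self, a: str, b: str) -> bool:
        return self.genome_to_species[a] == self.genome_to_species[b]


def average_linkage_cluster(dm: DistanceMatrix, cutoff: float) -> SpeciesAssignment:
    """UPGMA clustering of genomes, cutting where the inter-cluster average
    distance exceeds the cutoff.

    Masked entries are treated as distance 1.0 (never mergeable on their
    own). Species ids are stable under input reordering: clusters are
    labelled in order of their lexicographically smallest member.
    """
    if not dm.ids:
        raise ValueError("no genomes to cluster")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    n = len(dm.ids)
    if n == 1:
        labels = np.ones(1, dtype=int)
    else:
        full = np.where(dm.defined, dm.values, 1.0)
        np.fill_diagonal(full, 0.0)
        condensed = squareform(full, checks=False)
        tree = linkage(condensed, method="average")
        labels = fcluster(tree, t=cutoff, criterion="distance")
    clusters: dict[int, list[str]] = defaultdict(list)
    for gid, lab in zip(dm.ids, labels):
        clusters[int(lab)].append(gid)
    ordered = sorted(clusters.values(), key=min)
    width = len(str(len(ordered)))
    mapping = {}
    for k, members in enumerate(ordered, 1):
        sid = f"sp{k:0{width}d}"
        for g in members:
            mapping[g] = sid
    return SpeciesAssignment(mapping, cutoff)


def evaluate_against_ani(
    assignment: SpeciesAssignment,
    ani_labels: list[tuple[str, str, float]],
    ani_cutoff: float = 95.0,
) -> dict:
    """Score clustered/split genome pairs against ANI >= 95% labels.

    TP: clustered pair with ANI >= 95; FP: clustered, ANI < 95;
    FN: split, ANI >= 95; TN: split, ANI < 95.
    """
    if not ani_labels:
        raise ValueError("no labelled genome pairs")
    tp = fp = fn = tn = 0
    for a, b, ani in ani_labels:
        same = assignment.same_species(a, b)
        positive = ani >= ani_cutoff
        if same and positive:
            tp += 1
        elif same and not positive:
            fp += 1
        elif not same and positive:
            fn += 1
        else:
            tn += 1
    tpr = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tpr * ppv / (tpr + ppv) if tpr + ppv else 0.0
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn, "TPR": tpr, "PPV": ppv, "F1": f1}


def select_representative(members: list[str], identity: DistanceMatrix) -> str:
    """Member genome with maximal mean marker identity (minimal mean
    distance) to the other members; ties break to the smallest id."""
    if not members:
        raise ValueError("empty species")
    if len(members) == 1:
        return members[0]
    idx = {g: i for i, g in enumerate(identity.ids)}
    best_id, best_mean = None, None
    for g in sorted(members):
        others = [m for m in members if m != g]
        dists = [
            identity.values[idx[g], idx[m]] if identity.defined[idx[g], idx[m]] else 1.0
            for m in others
        ]
        mean_d = float(np.mean(dists))
        if best_mean is None or mean_d < best_mean:
            best_id, best_mean = g, mean_d
    return best_id


def consensus_name(labels: list[str], species_id: str) -> str:
    """Modal non-empty label; ties lexicographic; all empty -> unnamed."""
    nonempty = [x for x in labels if x]
    if not nonempty:
        return f"unnamed_{species_id}"
    counts = Counter(nonempty)
    top = max(counts.values())
    return min(name for name, c in counts.items() if c == top)


# ---------------------------------------------------------------------------
# pan-genomes


@dataclass
class GeneCluster:
    cluster_id: str
    centroid_id: str
    centroid_seq: str
    members: list[str]

    @property
    def length(self) -> int:
        return len(self.centroid_seq)


@dataclass
class PanGenome:
    """Non-redundant gene clusters (99% identity) of one species."""

    species_id: str
    clusters: list[GeneCluster]
    # cluster_id -> USCG family id, for clusters holding single-copy markers
    uscg_families: dict[str, str] = field(default_factory=dict)
    # gene_id -> genome_id of origin
    gene_origin: dict[str, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[str]:
        return [c.cluster_id for c in self.clusters]

    def membership(self) -> dict[str, str]:
        return {g: c.cluster_id for c in self.clusters for g in c.members}


def _greedy_cluster(
    seqs: list[tuple[str, str]], identity_cutoff: float, min_coverage: float = 0.70
) -> list[tuple[str, str, list[str]]]:
    """Greedy centroid clustering: sequences sorted by decreasing length
    (ties lexicographic by id) each join the first centroid at
    >= identity_cutoff with >= min_coverage mutual coverage, else found a
    new cluster. Returns (centroid_id, centroid_seq, member_ids) tuples."""
    order = sorted(seqs, key=lambda t: (-len(t[1]), t[0]))
    centroids: list[tuple[str, str, list[str]]] = []
    for gid, seq in order:
        placed = False
        for cid, cseq, members in centroids:
            pid = percent_identity(seq, cseq, min_coverage=min_coverage)
            if pid is not None and pid >= identity_cutoff:
                members.append(gid)
                placed = True
                break
        if not placed:
            centroids.append((gid, seq, [gid]))
    return centroids


def build_pangenome(
    genes: list[tuple[str, str, str]],
    species_id: str,
    identity: float = 99.0,
    marker_families: dict[str, str] | None = None,
) -> PanGenome:
    """Cluster all (gene_id, genome_id, sequence) of a species at 99%.

    Clusters containing a known single-copy marker gene are flagged with
    that family so downstream copy-number normalization can find them.
    """
    if not genes:
        raise ValueError(f"no genes supplied for species {species_id}")
    raw = _greedy_cluster([(gid, seq) for gid, _, seq in genes], identity)
    width = len(str(len(raw)))
    clusters = [
        GeneCluster(f"{species_id}.c{k:0{width}d}", cid, cseq, members)
        for k, (cid, cseq, members) in enumerate(raw, 1)
    ]
    uscg: dict[str, str] = {}
    if marker_families:
        for cl in clusters:
            fams = sorted({marker_families[m] for m in cl.members if m in marker_families})
            if fams:
                uscg[cl.cluster_id] = fams[0]
    origin = {gid: genome for gid, genome, _ in genes}
    return PanGenome(species_id, clusters, uscg, origin)


def aggregate_families(pangenome: PanGenome, level: int) -> dict[str, str]:
    """Map 99% clusters onto coarser families by re-clustering centroids
    at `level` percent identity (75-95)."""
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"level {level} not in {AGGREGATION_LEVELS}")
    seqs = [(c.cluster_id, c.centroid_seq) for c in pangenome.clusters]
    raw = _greedy_cluster(seqs, float(level))
    width = len(str(len(raw)))
    mapping = {}
    for k, (_cid, _seq, members) in enumerate(raw, 1):
        fam = f"{pangenome.species_id}.f{level}_{k:0{width}d}"
        for m in members:
            mapping[m] = fam
    return mapping
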
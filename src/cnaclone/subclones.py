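"""Genetic subclone detection from the inferred CNA matrix.

Cells are overclustered on a denoised version of the CNA matrix (the top
2/3 of genome positions by mean absolute CNA), a chromosome-arm event
profile is called per cluster (arm mean < -0.15 -> deletion, > 0.15 ->
amplification), and clusters with identical profiles are merged
iteratively until every remaining pair of clusters differs on at least
one arm. Overclustering deliberately over-segments; the merge loop is
what defines the genetic subclones, so the particular embedding used for
clustering only has to keep distinct clones apart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import CNAMatrix

DELETION = "deletion"
AMPLIFICATION = "amplification"
NONE = "none"


@dataclass
class SubcloneResult:
    cell_ids: np.ndarray
    labels: np.ndarray  # final cluster id per cell
    profiles: dict[int, dict[str, str]]  # cluster -> arm -> call
    merge_history: list[dict] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.profiles)

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "subclone": self.labels})


def select_top_positions(cna: CNAMatrix, fraction: float = 2 / 3) -> CNAMatrix:
    """Keep the genome positions with the highest mean |CNA| across cells.

    ``ceil(fraction * n_positions)`` positions are kept; ties are broken
    in favour of earlier genome positions, and genome order is preserved
    in the output.
    """
    if cna.n_positions == 0:
        raise ValueError("empty CNA matrix")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * cna.n_positions)
    score = np.abs(cna.values).mean(axis=0)
    # stable sort on -score keeps genome order among ties
    ranked = np.argsort(-score, kind="stable")[:k]
    keep = np.sort(ranked)
    return CNAMatrix(
        values=cna.values[:, keep].copy(),
        cell_ids=cna.cell_ids.copy(),
        gene_ids=cna.gene_ids[keep].copy(),
        provenance=dict(cna.provenance, top_fraction=fraction),
    )


def overcluster_cells(
    cna: CNAMatrix,
    k_neighbors: int = 15,
    seed: int = 0,
    resolution: float = 0.5,
    n_components: int = 20,
) -> np.ndarray:
    """Initial fine-grained clustering of cells on the reduced CNA matrix.

    A PCA embedding of the reduced matrix feeds a k-nearest-neighbour
    graph on which Leiden community detection is run. The clustering is
    intentionally finer than the clone structure; downstream merging by
    identical arm-event profiles recovers the clones. Deterministic for
    a fixed seed.
    """
    n = cna.n_cells
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least {k_neighbors + 1} cells for k={k_neighbors} graph"
        )
    X = cna.values
    n_comp = min(n_components, n - 1, X.shape[1])
    if n_comp >= 2 and X.shape[1] > n_comp:
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, indices = nn.kneighbors(X)
    edges = {
        (min(i, j), max(i, j))
        for i, row in enumerate(indices)
        for j in row[1:]
    }
    graph = igraph.Graph(n=n, edges=sorted(edges))
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(partition.membership, dtype=int)


def _arm_positions(cna: CNAMatrix, annotation: pd.DataFrame) -> dict[str, np.ndarray]:
    arm_of = annotation.set_index("gene_id")["arm"]
    arms: dict[str, list[int]] = {arm: [] for arm in annotation["arm"].unique()}
    for i, g in enumerate(cna.gene_ids):
        if g in arm_of.index:
            arms[arm_of[g]].append(i)
    return {arm: np.asarray(idx, dtype=int) for arm, idx in arms.items()}


def call_arm_events(
    cna: CNAMatrix,
    cells: list[str] | np.ndarray,
    annotation: pd.DataFrame,
    threshold: float = 0.15,
) -> dict[str, str]:
    """Call deletion/amplification/none per chromosome arm for a cell set.

    The call uses the mean CNA over (cells x arm positions): strictly
    below ``-threshold`` is a deletion, strictly above ``threshold`` an
    amplification. Arms with no positions left in the matrix (e.g.
    filtered-out acrocentric arms) are called ``none`` with a warning.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell set")
    idx = cna.cell_index(cells)
    profile: dict[str, str] = {}
    for arm, positions in sorted(_arm_positions(cna, annotation).items()):
        if len(positions) == 0:
            warnings.warn(f"arm {arm} has no positions in the CNA matrix")
            profile[arm] = NONE
            continue
        mean = cna.values[np.ix_(idx, positions)].mean()
        if mean < -threshold:
            profile[arm] = DELETION
        elif mean > threshold:
            profile[arm] = AMPLIFICATION
        else:
            profile[arm] = NONE
    return profile


def merge_identical_clusters(
    labels: np.ndarray,
    cna: CNAMatrix,
    annotation: pd.DataFrame,
    threshold: float = 0.15,
) -> SubcloneResult:
    """Iteratively merge clusters whose arm-event profiles are identical.

    Each round recomputes per-cluster profiles on the merged clusters;
    the loop ends when all pairwise profiles differ. The cluster count
    strictly decreases every merging round, so at most
    ``initial_clusters - 1`` rounds run.
    """
    labels = np.asarray(labels, dtype=int).copy()
    history: list[dict] = []
    while True:
        clusters = sorted(set(labels.tolist()))
        profiles = {
            c: call_arm_events(cna, list(cna.cell_ids[labels == c]), annotation, threshold)
            for c in clusters
        }
        signature = {c: tuple(sorted(profiles[c].items())) for c in clusters}
        groups: dict[tuple, list[int]] = {}
        for c in clusters:
            groups.setdefault(signature[c], []).append(c)
        merges = {sig: cs for sig, cs in groups.items() if len(cs) > 1}
        if not merges:
            break
        mapping = {}
        for cs in merges.values():
            target = min(cs)
            for c in cs:
                mapping[c] = target
        labels = np.array([mapping.get(c, c) for c in labels])
        history.append(
            {
                "round": len(history) + 1,
                "merged_groups": [sorted(cs) for cs in merges.values()],
                "n_clusters_after": len(set(labels.tolist())),
            }
        )
    # relabel to consecutive ids in order of first appearance
    remap = {}
    for c in labels:
        if c not in remap:
            remap[c] = len(remap)
    final = np.array([remap[c] for c in labels])
    final_profiles = {
        remap[c]: profiles[c] for c in sorted(set(labels.tolist()))
    }
    return SubcloneResult(
        cell_ids=cna.cell_ids.copy(),
        labels=final,
        profiles=final_profiles,
        merge_history=history,
    )


def detect_subclones(
    cna: CNAMatrix,
    annotation: pd.DataFrame,
    fraction: float = 2 / 3,
    k_neighbors: int = 15,
    threshold: float = 0.15,
    seed: int = 0,
    resolution: float = 0.5,
) -> SubcloneResult:
    """End-to-end subclone detection: denoise, overcluster, merge.

    Position selection and clustering run on the reduced matrix; arm
    events are always called on the full CNA matrix so that every arm
    retains its complete position set.
    """
    reduced = select_top_positions(cna, fraction)
    labels = overcluster_cells(reduced, k_neighbors=k_neighbors, seed=seed, resolution=resolution)
    return merge_identical_clusters(labels, cna, annotation, threshold)
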
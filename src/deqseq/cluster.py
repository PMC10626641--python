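"""Greedy centroid clustering of extracted UMIs at a fixed identity threshold.

Reads carrying noisy copies of the same 50-nt barcode are grouped so that
genotype and phenotype can be called per variant.  Clustering is a single
greedy pass in input order: the first UMI founds cluster 0; every later UMI
joins the best-identity centroid at identity >= threshold (ties go to the
lowest cluster id) or founds a new cluster.  Centroids are the founding
read's UMI and are never recomputed — at barcode length 50 the families are
far apart and this simple rule separates them cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import expand_cigar, ops_identity

#: edit-distance band for the centroid prescreen; identity >= 0.7 on
#: ~50-column alignments implies distance well below this.
_SCREEN_K = 25
#: exact identities are computed for centroids within this distance of the
#: best prescreened one
_SCREEN_MARGIN = 3


@dataclass
class UmiCluster:
    cluster_id: int
    centroid_umi: str
    member_read_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


def umi_identity(a: str, b: str) -> float:
    """Global-alignment identity: matching columns / alignment columns,
    terminal gaps excluded from the denominator."""
    if not a or not b:
        raise ValueError("umi_identity requires non-empty strings")
    if b < a:  # canonical order: the tie-breaking of the path search can
        a, b = b, a  # otherwise differ between (a,b) and (b,a)
    res = edlib.align(a, b, mode="NW", task="path")
    return ops_identity(expand_cigar(res["cigar"]))


def cluster_umis(
    umis: list[tuple[str, str]], threshold: float = 0.7
) -> list[UmiCluster]:
    """Greedy single-pass clustering of (read_id, umi) pairs.

    Returns clusters in creation order; every input read lands in exactly
    one cluster.  Assignment is by best identity (>= threshold) against the
    founding centroids, with a fast edit-distance prescreen that never
    changes the outcome for barcodes this far apart.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    clusters: list[UmiCluster] = []
    memo: dict[str, int] = {}  # umi string -> cluster assigned at first sight
    for read_id, umi in umis:
        cid = memo.get(umi)
        if cid is None:
            cid = _assign(umi, clusters, threshold)
            if cid is None:
                cid = len(clusters)
                clusters.append(UmiCluster(cluster_id=cid, centroid_umi=umi))
            memo[umi] = cid
        clusters[cid].member_read_ids.append(read_id)
    return clusters


def _assign(umi: str, clusters: list[UmiCluster], threshold: float) -> int | None:
    if not clusters:
        return None
    dists = []
    for c in clusters:
        res = edlib.align(umi, c.centroid_umi, mode="NW", task="distance", k=_SCREEN_K)
        if res["editDistance"] >= 0:
            dists.append((res["editDistance"], c.cluster_id))
    if not dists:
        return None
    best_d = min(d for d, _ in dists)
    best_cid, best_ident = None, -1.0
    for d, cid in dists:
        if d <= best_d + _SCREEN_MARGIN:
            ident = umi_identity(umi, clusters[cid].centroid_umi)
            if ident > best_ident:  # strict: ties keep the lowest cluster_id
                best_ident, best_cid = ident, cid
    if best_ident >= threshold:
        return best_cid
    return None


def filter_clusters(clusters: list[UmiCluster], min_size: int = 50) -> list[UmiCluster]:
    """Keep clusters with at least min_size member reads (inclusive)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in clusters if c.size >= min_size]
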
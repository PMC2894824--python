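"""Sample profiles and between-sample comparison.

Assigned reads are clustered by the pair (reference id, floor of the
average similarity in integer percent): two reads land in the same cluster
exactly when they hit the same reference species within the same 1%
similarity band. A cluster key present in both samples is a *common
cluster*; the partition into shared and sample-specific keys feeds three
community similarity indices — the incidence-based Jaccard and Lennon
indices over cluster counts, and the abundance-based Yue–Clayton theta
over relative-abundance vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

ClusterKey = tuple[str, int]  # (ref_id, floored similarity percent)


@dataclass(frozen=True)
class Cluster:
    ref_id: str
    sim_floor: int
    count: int
    rel_abundance: float

    @property
    def key(self) -> ClusterKey:
        return (self.ref_id, self.sim_floor)


@dataclass
class SampleProfile:
    sample_name: str
    clusters: dict[ClusterKey, Cluster]
    total_assigned: int

    def __post_init__(self):
        if self.total_assigned < 1:
            raise ValueError("profile must contain at least one read")
        tot = sum(c.rel_abundance for c in self.clusters.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {tot}, not 1")

    @property
    def keys(self) -> set[ClusterKey]:
        return set(self.clusters)

    def abundance(self, key: ClusterKey) -> float:
        c = self.clusters.get(key)
        return c.rel_abundance if c else 0.0

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_id\tsim_floor\tcount\trel_abundance\n")
            for key in sorted(self.clusters):
                c = self.clusters[key]
                fh.write(f"{c.ref_id}\t{c.sim_floor}\t{c.count}\t"
                         f"{c.rel_abundance!r}\n")


@dataclass
class ComparisonResult:
    sample_a: str
    sample_b: str
    shared_keys: set[ClusterKey]
    unique_to_a: set[ClusterKey]
    unique_to_b: set[ClusterKey]
    jaccard: float | None = None
    lennon: float | None = None
    theta: float | None = None

    @property
    def S_A(self) -> int:
        return len(self.shared_keys) + len(self.unique_to_a)

    @property
    def S_B(self) -> int:
        return len(self.shared_keys) + len(self.unique_to_b)

    @property
    def S_AB(self) -> int:
        return len(self.shared_keys)


def cluster_assignments(assignments, sample_name: str) -> SampleProfile:
    """Cluster assigned reads by (reference, floored similarity).

    Two reads assigned to one reference at, say, 98.8% and 98.1% both fall
    in that reference's 98% cluster. Relative abundances are fractions of
    *assigned* reads (unassigned reads carry no cluster key).
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments to cluster")
    counts: dict[ClusterKey, int] = {}
    for a in assignments:
        key = (a.nearest_ref_id, math.floor(a.avg_similarity))
        counts[key] = counts.get(key, 0) + 1
    total = len(assignments)
    clusters = {
        key: Cluster(ref_id=key[0], sim_floor=key[1], count=n,
                     rel_abundance=n / total)
        for key, n in counts.items()
    }
    return SampleProfile(sample_name=sample_name, clusters=clusters,
                         total_assigned=total)


def common_clusters(a: SampleProfile, b: SampleProfile) -> ComparisonResult:
    """Partition the two samples' cluster keys into shared and unique."""
    shared = a.keys & b.keys
    return ComparisonResult(
        sample_a=a.sample_name, sample_b=b.sample_name,
        shared_keys=shared,
        unique_to_a=a.keys - shared,
        unique_to_b=b.keys - shared,
    )


def jaccard_index(S_A: int, S_B: int, S_AB: int) -> float:
    """S_AB / (S_A + S_B - S_AB): shared fraction of the cluster union."""
    _check_counts(S_A, S_B, S_AB)
    denom = S_A + S_B - S_AB
    if denom == 0:
        raise ValueError("Jaccard undefined: no clusters in either sample")
    return S_AB / denom


def lennon_index(S_A: int, S_B: int, S_AB: int) -> float:
    """S_AB / (S_AB + min(S_A - S_AB, S_B - S_AB)).

    Measures overlap relative to the less diverse sample, so a subset
    community scores 1 against its superset.
    """
    _check_counts(S_A, S_B, S_AB)
    denom = S_AB + min(S_A - S_AB, S_B - S_AB)
    if denom == 0:
        raise ValueError("Lennon undefined for these cluster counts")
    return S_AB / denom


def _check_counts(S_A, S_B, S_AB):
    if S_A < 1 or S_B < 1:
        raise ValueError("both samples must contain at least one cluster")
    if S_AB > min(S_A, S_B):
        raise ValueError("shared count exceeds a sample's cluster count")


def yue_clayton_theta(a: SampleProfile, b: SampleProfile) -> float:
    """Yue–Clayton theta over relative abundances.

    theta = sum(a_i b_i) / (sum(a_i^2) + sum(b_i^2) - sum(a_i b_i)) with
    the vectors taken over the union of cluster keys (zero where absent).
    1 for identical compositions, 0 for disjoint supports.
    """
    keys = a.keys | b.keys
    if not keys:
        raise ValueError("theta undefined: no clusters")
    cross = sq_a = sq_b = 0.0
    for key in keys:
        ai, bi = a.abundance(key), b.abundance(key)
        cross += ai * bi
        sq_a += ai * ai
        sq_b += bi * bi
    return cross / (sq_a + sq_b - cross)


def compare_samples(a: SampleProfile, b: SampleProfile) -> ComparisonResult:
    """Full comparison: key partition plus all three indices."""
    result = common_clusters(a, b)
    result.jaccard = jaccard_index(result.S_A, result.S_B, result.S_AB)
    result.lennon = lennon_index(result.S_A, result.S_B, result.S_AB)
    result.theta = yue_clayton_theta(a, b)
    return result


def write_comparison(result: ComparisonResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_a\tsample_b\tS_A\tS_B\tS_AB\t"
                 "jaccard\tlennon\ttheta\n")
        fh.write(f"{result.sample_a}\t{result.sample_b}\t{result.S_A}\t"
                 f"{result.S_B}\t{result.S_AB}\t{result.jaccard!r}\t"
                 f"{result.lennon!r}\t{result.theta!r}\n")


def load_profile(path: str | Path, sample_name: str | None = None
                 ) -> SampleProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"ref_id": str})
    clusters = {}
    total = int(df["count"].sum())
    for r in df.itertuples(index=False):
        key = (r.ref_id, int(r.sim_floor))
        clusters[key] = Cluster(ref_id=r.ref_id, sim_floor=int(r.sim_floor),
                                count=int(r.count),
                                rel_abundance=int(r.count) / total)
    name = sample_name or Path(path).stem
    return SampleProfile(sample_name=name, clusters=clusters,
                         total_assigned=total)
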
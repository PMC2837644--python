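"""Greedy identity-based redundancy removal with an inter-species screen.

Sequence sets assembled by keyword download are highly redundant: the same
protein is deposited many times per species.  Redundancy is removed by
greedy incremental clustering at a percent-identity threshold (95 % by
default), then the clusters are screened so that (near-)identical proteins
from *different* species are not collapsed — cross-species conservation is
signal, not redundancy.

Identity between two sequences is computed from an exact global
(Needleman-Wunsch) alignment with match +1, mismatch 0 and linear gap -1;
the identity denominator is the length of the shorter sequence, following
CD-HIT's convention.  A shared-k-mer prefilter (k = 5) skips alignments
that provably cannot reach the threshold.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from math import ceil

from Bio import Align

from fyvepx.io import ProteinRecord

_KMER = 5


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(a: str, b: str) -> float:
    """Percent identity between two sequences in [0, 100].

    Identity is the number of identical aligned positions in the optimal
    global alignment divided by the length of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return 100.0 * identities / min(len(a), len(b))


def _kmers(seq: str) -> Counter:
    if len(seq) < _KMER:
        return Counter()
    return Counter(seq[i : i + _KMER] for i in range(len(seq) - _KMER + 1))


def _required_shared_kmers(short_len: int, threshold: float) -> int:
    # A pair at >= threshold identity keeps at least
    # (L - k + 1) - k * ((1 - t) * L + slack) of the shorter sequence's
    # k-mers intact; the slack term absorbs a few alignment gaps.
    bound = (short_len - _KMER + 1) - _KMER * ((1.0 - threshold / 100.0) * short_len + 3)
    return max(0, ceil(bound))


@dataclass
class Cluster:
    """One redundancy cluster: a representative and its members.

    The representative is the longest member (ties broken by input order);
    ``identities`` maps each non-representative member to its percent
    identity with the representative.
    """

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def cluster(records: list[ProteinRecord], threshold: float = 95.0) -> list[Cluster]:
    """Greedy incremental clustering at a percent-identity threshold.

    Sequences are processed longest-first (stable for equal lengths); each
    joins the first existing cluster whose representative it matches at
    >= ``threshold`` percent identity, otherwise it founds a new cluster.
    Deterministic for a fixed input order.
    """
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
        raise ValueError(f"duplicate protein ids: {dupes}")

    order = sorted(range(len(records)), key=lambda i: -len(records[i].sequence))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_kmer_counts: list[Counter] = []
    # inverted index: k-mer -> cluster indices whose representative holds it
    index: dict[str, list[int]] = defaultdict(list)

    for i in order:
        rec = records[i]
        seq = rec.sequence
        qkmers = _kmers(seq)
        placed = False

        required_floor = _required_shared_kmers(len(seq), threshold)
        if required_floor <= 0 or len(seq) < _KMER:
            candidates = range(len(clusters))
        else:
            shared: Counter = Counter()
            for kmer, mult in qkmers.items():
                for ci in index.get(kmer, ()):
                    shared[ci] += min(mult, rep_kmer_counts[ci][kmer])
            candidates = sorted(
                ci
                for ci, n in shared.items()
                # the representative may be the shorter sequence of the pair
                if n >= _required_shared_kmers(min(len(seq), len(rep_seqs[ci])), threshold)
            )

        for ci in candidates:
            ident = percent_identity(seq, rep_seqs[ci])
            if ident >= threshold:
                clusters[ci].member_ids.append(rec.protein_id)
                clusters[ci].identities[rec.protein_id] = ident
                placed = True
                break

        if not placed:
            ci = len(clusters)
            clusters.append(
                Cluster(representative_id=rec.protein_id, member_ids=[rec.protein_id])
            )
            rep_seqs.append(seq)
            counts = qkmers
            rep_kmer_counts.append(counts)
            for kmer in counts:
                index[kmer].append(ci)

    return clusters


def cluster_brute_force(
    records: list[ProteinRecord], threshold: float = 95.0
) -> list[Cluster]:
    """Reference clustering from the full pairwise identity matrix.

    Applies the same greedy rule as :func:`cluster` but computes every
    pairwise identity up front with no prefilter.  Used as an independent
    oracle in tests; quadratic in alignments, so keep n small.
    """
    order = sorted(range(len(records)), key=lambda i: -len(records[i].sequence))
    matrix: dict[tuple[int, int], float] = {}
    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            matrix[(a, b)] = matrix[(b, a)] = percent_identity(
                records[a].sequence, records[b].sequence
            )
    clusters: list[Cluster] = []
    rep_idx: list[int] = []
    for i in order:
        for ci, r in enumerate(rep_idx):
            ident = 100.0 if i == r else matrix[(i, r)]
            if ident >= threshold:
                clusters[ci].member_ids.append(records[i].protein_id)
                clusters[ci].identities[records[i].protein_id] = ident
                break
        else:
            clusters.append(
                Cluster(
                    representative_id=records[i].protein_id,
                    member_ids=[records[i].protein_id],
                )
            )
            rep_idx.append(i)
    return clusters


def retained_ids(
    clusters: list[Cluster], records: list[ProteinRecord]
) -> set[str]:
    """Ids surviving dereplication, honouring the inter-species screen.

    Each cluster keeps its representative plus, for every other species
    present in the cluster, that species' longest member — so identical or
    near-identical proteins from different species all survive.
    """
    by_id = {r.protein_id: r for r in records}
    input_rank = {r.protein_id: i for i, r in enumerate(records)}
    keep: set[str] = set()
    for cl in clusters:
        rep = by_id[cl.representative_id]
        keep.add(rep.protein_id)
        per_species: dict[str, str] = {}
        for mid in cl.member_ids:
            rec = by_id[mid]
            if rec.species == rep.species:
                continue
            best = per_species.get(rec.species)
            if best is None:
                per_species[rec.species] = mid
            else:
                brec = by_id[best]
                if len(rec.sequence) > len(brec.sequence) or (
                    len(rec.sequence) == len(brec.sequence)
                    and input_rank[mid] < input_rank[best]
                ):
                    per_species[rec.species] = mid
        keep.update(per_species.values())
    return keep


def dereplicate(
    records: list[ProteinRecord], threshold: float = 95.0
) -> tuple[list[ProteinRecord], list[Cluster]]:
    """Cluster at ``threshold`` and return the non-redundant record set.

    Returns the retained records in input order together with the clusters
    (for reporting).
    """
    clusters = cluster(records, threshold)
    keep = retained_ids(clusters, records)
    return [r for r in records if r.protein_id in keep], clusters


def clusters_to_frame(clusters: list[Cluster], records: list[ProteinRecord]):
    """Flat TSV-ready table: cluster_id, representative, member, identity, retained."""
    import pandas as pd

    keep = retained_ids(clusters, records)
    rows = []
    for ci, cl in enumerate(clusters):
        for mid in cl.member_ids:
            rows.append(
                {
                    "cluster_id": ci,
                    "representative": cl.representative_id,
                    "member": mid,
                    "identity": round(cl.identities.get(mid, 100.0), 2),
                    "retained": "yes" if mid in keep else "no",
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "representative", "member", "identity", "retained"]
    )
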
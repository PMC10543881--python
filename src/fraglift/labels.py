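"""Tumour-content training labels from panel-sequencing variant calls.

A heterozygous clonal point mutation in a copy-number-neutral region has a
variant allele frequency (VAF) of half the tumour fraction. Mutations are
therefore clustered by allele frequency with a Dirichlet-process binomial
mixture (a Chinese-restaurant-process prior over partitions with a
Binomial(alt | depth, v) likelihood and a Beta(1, 1) base measure on each
cluster VAF v), and the tumour content is twice the VAF of the clonal
cluster — the cluster at the largest allele frequency, unless that cluster
is supported only by non-annotated variants, in which case the next one is
used. Samples without usable panel evidence fall back to surrogate labels
produced by an external copy-number tool, consumed here as a plain file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationCall:
    """A single somatic SNV with read-count evidence."""

    sample_id: str
    chrom: str
    pos: int
    alt_count: int
    depth: int
    cn_neutral: bool
    annotated: bool

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt_count must lie in [0, depth]")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class VafClustering:
    """MAP partition of mutations by allele frequency."""

    assignments: np.ndarray          # cluster id per clustered mutation
    cluster_vafs: dict[int, float]   # posterior mean VAF per cluster
    cluster_members: dict[int, list[int]]
    n_iterations: int
    seed: int
    log_score: float                 # log CRP prior + log marginal likelihood


@dataclass(frozen=True)
class TumourContentLabel:
    """Curated training response in the open interval (0, 1)."""

    sample_id: str
    value: float
    source: str                      # "panel" or "surrogate"
    chosen_cluster: int | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise ValueError("label must lie strictly inside (0, 1)")
        if self.source not in ("panel", "surrogate"):
            raise ValueError(f"unknown label source {self.source!r}")


class NoPanelEvidenceError(ValueError):
    """No copy-number-neutral mutations: the sample needs a surrogate label."""


def _cluster_log_marginal(alt_sum: int, ref_sum: int) -> float:
    """Log marginal likelihood of a cluster's counts under Beta(1,1) on VAF.

    Per-item binomial coefficients are omitted: they are constant across
    partitions and cancel in every comparison made here.
    """
    return betaln(1 + alt_sum, 1 + ref_sum) - betaln(1, 1)


def partition_log_score(
    partition: list[list[int]],
    alts: np.ndarray,
    refs: np.ndarray,
    alpha: float,
) -> float:
    """Log joint score of a partition: CRP prior times cluster marginals.

    Used both by the Gibbs sampler (to rank sampled states) and by the
    exhaustive small-n oracle in the test suite.
    """
    from scipy.special import gammaln

    score = 0.0
    for block in partition:
        block = list(block)
        score += np.log(alpha) + gammaln(len(block))
        score += _cluster_log_marginal(
            int(alts[block].sum()), int(refs[block].sum())
        )
    return float(score)


def cluster_vafs(
    mutations: list[MutationCall],
    alpha: float = 1.0,
    iters: int = 2000,
    seed: int = 0,
) -> VafClustering:
    """Cluster copy-number-neutral mutations by VAF via collapsed Gibbs.

    Runs a collapsed Gibbs sampler over the Dirichlet-process binomial
    mixture and returns the sampled assignment state with the highest joint
    posterior score (MAP among visited states). Cluster VAFs are the
    posterior means ``(1 + sum alt) / (2 + sum depth)`` given that partition.
    Deterministic for a fixed seed.
    """
    usable_idx = [i for i, m in enumerate(mutations) if m.cn_neutral]
    if not usable_idx:
        raise NoPanelEvidenceError(
            "no copy-number-neutral mutations: cohort-B sample, "
            "use a surrogate label"
        )
    usable = [mutations[i] for i in usable_idx]
    alts = np.array([m.alt_count for m in usable], dtype=np.int64)
    depths = np.array([m.depth for m in usable], dtype=np.int64)
    refs = depths - alts
    n = len(usable)

    rng = np.random.default_rng(seed)
    # start from the one-cluster state
    assign = np.zeros(n, dtype=np.int64)
    stats: dict[int, tuple[int, int]] = {0: (int(alts.sum()), int(refs.sum()))}
    sizes: dict[int, int] = {0: n}
    next_id = 1

    def state_partition() -> list[list[int]]:
        blocks: dict[int, list[int]] = {}
        for i, c in enumerate(assign):
            blocks.setdefault(int(c), []).append(i)
        return list(blocks.values())

    best_assign = assign.copy()
    best_score = partition_log_score(state_partition(), alts, refs, alpha)

    log_alpha = np.log(alpha)
    for _ in range(iters):
        for i in range(n):
            c_old = int(assign[i])
            a_i, r_i = int(alts[i]), int(refs[i])
            # remove item i from its cluster
            a_c, r_c = stats[c_old]
            if sizes[c_old] == 1:
                del stats[c_old], sizes[c_old]
            else:
                stats[c_old] = (a_c - a_i, r_c - r_i)
                sizes[c_old] -= 1
            # candidate clusters + a fresh one
            cand = list(stats.keys())
            logw = np.empty(len(cand) + 1)
            for k, c in enumerate(cand):
                a_c, r_c = stats[c]
                logw[k] = np.log(sizes[c]) + (
                    betaln(1 + a_c + a_i, 1 + r_c + r_i)
                    - betaln(1 + a_c, 1 + r_c)
                )
            logw[-1] = log_alpha + _cluster_log_marginal(a_i, r_i)
            probs = np.exp(logw - logsumexp(logw))
            choice = rng.choice(len(cand) + 1, p=probs / probs.sum())
            if choice == len(cand):
                c_new = next_id
                next_id += 1
                stats[c_new] = (a_i, r_i)
                sizes[c_new] = 1
            else:
                c_new = cand[choice]
                a_c, r_c = stats[c_new]
                stats[c_new] = (a_c + a_i, r_c + r_i)
                sizes[c_new] += 1
            assign[i] = c_new
        score = partition_log_score(state_partition(), alts, refs, alpha)
        if score > best_score + 1e-12:
            best_score = score
            best_assign = assign.copy()

    # relabel the MAP state contiguously and compute posterior-mean VAFs
    members: dict[int, list[int]] = {}
    for i, c in enumerate(best_assign):
        members.setdefault(int(c), []).append(i)
    relabel = {c: k for k, c in enumerate(sorted(members))}
    final_assign = np.array([relabel[int(c)] for c in best_assign])
    final_members = {relabel[c]: idx for c, idx in members.items()}
    vafs = {
        c: float((1 + alts[idx].sum()) / (2 + depths[idx].sum()))
        for c, idx in final_members.items()
    }
    return VafClustering(
        assignments=final_assign,
        cluster_vafs=vafs,
        cluster_members=final_members,
        n_iterations=iters,
        seed=seed,
        log_score=best_score,
    )


def tumour_content_from_clusters(
    clustering: VafClustering,
    mutations: list[MutationCall],
    epsilon: float = 1e-3,
) -> TumourContentLabel:
    """Double the clonal-cluster VAF to obtain the tumour content.

    The cluster with the largest posterior-mean VAF is taken as clonal;
    if every mutation in it is non-annotated and another cluster exists,
    the second-largest cluster is used instead. The doubled value is
    clipped into ``(epsilon, 1 - epsilon)`` so it is valid as a
    beta-regression response.
    """
    if not clustering.cluster_vafs:
        raise ValueError("clustering has no clusters")
    usable = [m for m in mutations if m.cn_neutral]
    ranked = sorted(
        clustering.cluster_vafs, key=clustering.cluster_vafs.get, reverse=True
    )
    chosen = ranked[0]
    top_annotated = any(
        usable[i].annotated for i in clustering.cluster_members[chosen]
    )
    if not top_annotated and len(ranked) > 1:
        chosen = ranked[1]
    raw = 2.0 * clustering.cluster_vafs[chosen]
    value = min(1.0 - epsilon, max(epsilon, raw))
    return TumourContentLabel(
        sample_id=usable[0].sample_id,
        value=value,
        source="panel",
        chosen_cluster=chosen,
        clipped=(value != raw),
    )


def panel_label(
    mutations: list[MutationCall],
    alpha: float = 1.0,
    iters: int = 2000,
    seed: int = 0,
    epsilon: float = 1e-3,
) -> TumourContentLabel:
    """Cluster VAFs and apply the doubling rule in one step."""
    clustering = cluster_vafs(mutations, alpha=alpha, iters=iters, seed=seed)
    return tumour_content_from_clusters(clustering, mutations, epsilon=epsilon)


MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "alt_count", "depth", "cn_neutral", "annotated",
]


def read_mutations(path: str) -> list[MutationCall]:
    """Read a mutation table (TSV with the nine canonical columns)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in MUTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mutation columns {missing}")
    return [
        MutationCall(
            sample_id=str(row.sample_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            alt_count=int(row.alt_count),
            depth=int(row.depth),
            cn_neutral=bool(int(row.cn_neutral)),
            annotated=bool(int(row.annotated)),
        )
        for row in frame.itertuples()
    ]


def write_mutations(mutations: list[MutationCall], path: str) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in mutations],
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": "N",
            "alt": "N",
            "alt_count": [m.alt_count for m in mutations],
            "depth": [m.depth for m in mutations],
            "cn_neutral": [int(m.cn_neutral) for m in mutations],
            "annotated": [int(m.annotated) for m in mutations],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_mutations_vcf(path: str, sample_id: str) -> list[MutationCall]:
    """Read a minimal VCF: AD-style counts plus CN_NEUTRAL/ANNOTATED flags."""
    import pysam

    calls: list[MutationCall] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch():
            sample = rec.samples[0]
            ad = sample.get("AD")
            if ad is None or len(ad) < 2:
                raise ValueError(f"{path}: record at {rec.pos} lacks AD counts")
            ref_count, alt_count = int(ad[0]), int(ad[1])
            calls.append(
                MutationCall(
                    sample_id=sample_id,
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    alt_count=alt_count,
                    depth=ref_count + alt_count,
                    cn_neutral=bool(rec.info.get("CN_NEUTRAL", False)),
                    annotated=bool(rec.info.get("ANNOTATED", False)),
                )
            )
    return calls


def load_surrogate_labels(path: str) -> list[TumourContentLabel]:
    """Load surrogate tumour-content estimates from a ``sample_id,value`` CSV.

    Entries with value <= 0 are dropped (and counted in a log message):
    zero surrogate estimates carry no usable signal for a response that
    must live in the open unit interval.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn(f"{path}: no surrogate labels found", stacklevel=2)
        return []
    if not {"sample_id", "value"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns sample_id,value")
    if ((frame["value"] < 0) | (frame["value"] > 1)).any():
        bad = frame.loc[(frame["value"] < 0) | (frame["value"] > 1)].iloc[0]
        raise ValueError(
            f"{path}: surrogate value {bad['value']} outside [0, 1] "
            f"for sample {bad['sample_id']}"
        )
    kept = frame[frame["value"] > 0]
    n_dropped = len(frame) - len(kept)
    if n_dropped:
        logger.info("%s: dropped %d zero-valued surrogate labels", path, n_dropped)
    return [
        TumourContentLabel(
            sample_id=str(row.sample_id),
            value=float(min(row.value, 1.0 - 1e-3)),
            source="surrogate",
        )
        for row in kept.itertuples()
    ]
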
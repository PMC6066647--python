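"""MOTU delimitation: ABGD-style recursive gap partitioning, Poisson tree
processes (maximum-likelihood and Bayesian flavours) and a BIN-style
single-linkage clustering surrogate, plus concordance classification of
clusters against morphospecies labels.

ABGD
----
For each prior intraspecific limit P (log-spaced sweep), ranked pairwise
distances at or below P form the candidate intraspecific region.  Scanning
upward from there, the first *significant* gap between consecutive ranked
distances sets a partition threshold at its midpoint; groups are the
connected components of the graph linking pairs at or below the threshold,
and the procedure recurses inside each group until no gap is found.  A gap
g at distance d is significant when it exceeds X times both the mean gap in
a sliding window of the preceding W ranked distances and d itself; the
second condition is the relative-width requirement that keeps rank-order
jitter among intraspecific distances from being mistaken for a barcode gap.

PTP
---
The Poisson tree processes model classifies every branch of a rooted tree
as a speciation-process or coalescent-process draw from one of two
exponential distributions; a valid configuration is an antichain of "MOTU
root" nodes so that each root-to-tip path crosses the class boundary at most
once.  Rates are profiled out at their per-class MLE (1/mean branch length).
The ML search is a greedy boundary descent with random restarts; the
Bayesian flavour is a Metropolis–Hastings sampler over the same state space
with a flat prior, reporting per-MOTU posterior support.

BIN surrogate
-------------
BOLD's RESL algorithm is not published in implementable detail.  The
surrogate here is stated and deterministic: single-linkage clustering at
2.2% followed by a within-cluster gap refinement that splits clusters across
internal gaps of at least the same width.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import rand_score

from .distances import DistanceMatrix, Model
from .io import BarcodeLibrary

EPS_BRANCH = 1e-8  # floor for zero branch lengths in exponential densities
DEFAULT_SEED = 42


class Method(str, enum.Enum):
    ABGD = "ABGD"
    PTP_ML = "PTP_ML"
    BPTP = "bPTP"
    BINLIKE = "BINlike"
    TRUTH = "truth"


@dataclass
class Partition:
    """Assignment of specimens to MOTU clusters by one method."""

    method: Method
    assignment: dict[str, int]
    parameters: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, cid in self.assignment.items():
            out.setdefault(cid, []).append(sid)
        return out

    def labels_for(self, ids: Sequence[str]) -> list[int]:
        return [self.assignment[i] for i in ids]

    def relabel_canonical(self) -> "Partition":
        """Renumber clusters 0..k-1 in order of first appearance."""
        seen: dict[int, int] = {}
        new = {}
        for sid, cid in self.assignment.items():
            if cid not in seen:
                seen[cid] = len(seen)
            new[sid] = seen[cid]
        return Partition(self.method, new, dict(self.parameters))

    def same_clustering(self, other: "Partition") -> bool:
        ids = sorted(self.assignment)
        if ids != sorted(other.assignment):
            return False
        return rand_score(self.labels_for(ids), other.labels_for(ids)) == 1.0


# ---------------------------------------------------------------------------
# ABGD


@dataclass
class AbgdConfig:
    p_min: float = 0.001
    p_max: float = 0.1
    n_steps: int = 20
    relative_gap_width: float = 1.0  # X
    window: int = 10  # W ranked distances in the sliding window
    model: Model = Model.K2P

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min < self.p_max < 1.0):
            raise ValueError("need 0 < p_min < p_max < 1")
        if self.relative_gap_width <= 0:
            raise ValueError("relative gap width X must be positive")

    def priors(self) -> np.ndarray:
        return np.geomspace(self.p_min, self.p_max, self.n_steps)


def _find_gap_threshold(
    dists: np.ndarray,
    prior: float,
    X: float,
    W: int,
    resolution: float = 0.0,
) -> Optional[float]:
    """Midpoint of the first significant gap above the prior region, or None.

    ``resolution`` is the smallest meaningful gap: distances computed from L
    compared sites move in steps of roughly 1/L, so gaps below ~2/L are
    sampling granularity, not structure.
    """
    d = np.sort(dists)
    if d.size < 2:
        return None
    start = int(np.searchsorted(d, prior, side="right"))
    gaps = np.diff(d)
    # the gap out of the prior region itself is eligible
    for i in range(max(start - 1, 0), d.size - 1):
        g = gaps[i]
        if g <= 0 or g < resolution:
            continue
        window = gaps[max(0, i - W) : i]
        mean_gap = float(window.mean()) if window.size else 0.0
        if g > X * mean_gap and g > X * d[i]:
            return float(d[i] + 0.5 * g)
    return None


def _resolution(matrix: DistanceMatrix) -> float:
    iu = np.triu_indices(len(matrix.ids), k=1)
    counts = matrix.site_counts[iu]
    if counts.size == 0 or counts.max() == 0:
        return 0.0
    return 2.0 / float(np.median(counts))


def _components(values: np.ndarray, threshold: float) -> np.ndarray:
    adj = csr_matrix(values <= threshold)
    _, labels = connected_components(adj, directed=False)
    return labels


def _abgd_split(
    matrix: DistanceMatrix,
    ids: list[str],
    prior: float,
    cfg: AbgdConfig,
    resolution: float,
) -> list[list[str]]:
    if len(ids) < 2:
        return [ids]
    sub = matrix.submatrix(ids)
    iu = np.triu_indices(len(ids), k=1)
    dists = sub.values[iu]
    if dists.max() <= prior:  # whole group within the prior limit
        return [ids]
    threshold = _find_gap_threshold(
        dists, prior, cfg.relative_gap_width, cfg.window, resolution
    )
    if threshold is None:
        return [ids]
    labels = _components(sub.values, threshold)
    if len(set(labels)) == 1:
        return [ids]
    groups = []
    for lbl in sorted(set(labels)):
        members = [ids[k] for k in np.flatnonzero(labels == lbl)]
        groups.extend(_abgd_split(matrix, members, prior, cfg, resolution))
    return groups


def abgd_partition(
    matrix: DistanceMatrix, config: AbgdConfig | None = None
) -> list[tuple[float, Partition, int]]:
    """Recursive gap partition for each prior P in the sweep."""
    cfg = config or AbgdConfig()
    if len(matrix) < 2:
        raise ValueError("need at least 2 specimens")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("saturated distances; gap scan undefined")
    out = []
    resolution = _resolution(matrix)
    for prior in cfg.priors():
        groups = _abgd_split(
            matrix, list(matrix.ids), float(prior), cfg, resolution
        )
        assignment = {
            sid: gi for gi, grp in enumerate(groups) for sid in grp
        }
        part = Partition(
            Method.ABGD,
            assignment,
            parameters={"prior": float(prior), "X": cfg.relative_gap_width},
        ).relabel_canonical()
        out.append((float(prior), part, part.n_groups))
    return out


def select_partition(
    abgd_output: list[tuple[float, Partition, int]], companion: Partition
) -> Partition:
    """Pick the sweep partition most consistent with a companion clustering.

    Consistency is pairwise co-clustering agreement (Rand index); ties go to
    the smaller prior P.
    """
    if not abgd_output:
        raise ValueError("empty sweep")
    best = None
    for prior, part, _ in abgd_output:
        ids = sorted(part.assignment)
        score = rand_score(part.labels_for(ids), companion.labels_for(ids))
        if best is None or score > best[0] + 1e-12:
            best = (score, prior, part)
    return best[2]


# ---------------------------------------------------------------------------
# PTP


@dataclass
class PtpModel:
    lambda_speciation: float
    lambda_coalescent: float
    edge_classes: dict[int, str]  # edge id -> "speciation" | "coalescent"
    log_likelihood: float
    low_confidence: bool = False


class _PtpTree:
    """Indexed view of a rooted tree for fast PTP state evaluation.

    ``min_branch`` floors every branch length.  Without a floor tied to the
    data's resolution the profile likelihood is unbounded: a class whose
    branch-length sum tends to zero drives its rate MLE to infinity, and the
    search degenerates towards all-singleton partitions.  Pipelines pass
    half a substitution at the alignment length (0.5/L); the default keeps
    densities finite only.
    """

    def __init__(self, tree: dendropy.Tree, min_branch: float = EPS_BRANCH):
        t = tree.clone(depth=1)
        if len(t.seed_node.child_nodes()) > 2:
            # unrooted (trifurcating) input: midpoint-root it
            t.reroot_at_midpoint(update_bipartitions=False)
        self.nodes = list(t.preorder_node_iter())
        self.index = {id(nd): k for k, nd in enumerate(self.nodes)}
        self.parent = [
            self.index[id(nd.parent_node)] if nd.parent_node else -1
            for nd in self.nodes
        ]
        self.children: list[list[int]] = [[] for _ in self.nodes]
        for k, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(k)
        self.lengths = np.array(
            [
                max(nd.edge.length or 0.0, min_branch)
                if nd.parent_node is not None
                else 0.0
                for nd in self.nodes
            ]
        )
        self.is_leaf = np.array([not c for c in self.children])
        self.tip_label = [
            nd.taxon.label if nd.is_leaf() and nd.taxon else None
            for nd in self.nodes
        ]
        # subtree edge sums / counts (edges strictly below each node)
        n = len(self.nodes)
        self.sub_sum = np.zeros(n)
        self.sub_cnt = np.zeros(n, dtype=int)
        for k in range(n - 1, -1, -1):
            for c in self.children[k]:
                self.sub_sum[k] += self.sub_sum[c] + self.lengths[c]
                self.sub_cnt[k] += self.sub_cnt[c] + 1
        self.total_sum = self.sub_sum[0]
        self.total_cnt = self.sub_cnt[0]
        self.tips_below: list[list[int]] = [[] for _ in self.nodes]
        for k in range(n - 1, -1, -1):
            if self.is_leaf[k]:
                self.tips_below[k] = [k]
            else:
                self.tips_below[k] = list(
                    itertools.chain.from_iterable(
                        self.tips_below[c] for c in self.children[k]
                    )
                )

    # -- states: frozenset of MOTU-root node indices (an antichain covering
    #    all tips)

    def all_tip_state(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.is_leaf))

    def root_state(self) -> frozenset[int]:
        return frozenset([0])

    def log_likelihood(self, state: Iterable[int]) -> float:
        coal_sum = sum(self.sub_sum[r] for r in state)
        coal_cnt = sum(self.sub_cnt[r] for r in state)
        spec_sum = self.total_sum - coal_sum
        spec_cnt = self.total_cnt - coal_cnt
        ll = 0.0
        for cnt, total in ((spec_cnt, spec_sum), (coal_cnt, coal_sum)):
            if cnt:
                total = max(total, EPS_BRANCH)
                ll += cnt * math.log(cnt / total) - cnt
        return ll

    def moves(self, state: frozenset[int]) -> list[frozenset[int]]:
        """Neighbouring states: split one MOTU root, or merge a sibling set."""
        out = []
        for r in state:
            if not self.is_leaf[r]:
                out.append(state - {r} | frozenset(self.children[r]))
        parents = {self.parent[r] for r in state if self.parent[r] >= 0}
        for p in parents:
            if all(c in state for c in self.children[p]):
                out.append(state - frozenset(self.children[p]) | {p})
        return out

    def partition_from(self, state: Iterable[int]) -> dict[str, int]:
        assignment = {}
        for gi, r in enumerate(sorted(state)):
            for tip in self.tips_below[r]:
                assignment[self.tip_label[tip]] = gi
        return assignment

    def edge_classes_from(self, state: Iterable[int]) -> dict[int, str]:
        coal: set[int] = set()
        for r in state:
            stack = list(self.children[r])
            while stack:
                k = stack.pop()
                coal.add(k)
                stack.extend(self.children[k])
        return {
            k: ("coalescent" if k in coal else "speciation")
            for k in range(1, len(self.nodes))
        }

    def rates_from(self, state: Iterable[int]) -> tuple[float, float]:
        coal_sum = sum(self.sub_sum[r] for r in state)
        coal_cnt = sum(self.sub_cnt[r] for r in state)
        spec_sum = self.total_sum - coal_sum
        spec_cnt = self.total_cnt - coal_cnt
        lam_s = spec_cnt / spec_sum if spec_cnt else float("nan")
        lam_c = coal_cnt / coal_sum if coal_cnt else float("nan")
        return lam_s, lam_c

    def threshold_state(self, cutoff: float) -> frozenset[int]:
        """Antichain from an edge-length cutoff: MOTU roots are the maximal
        nodes whose subtree contains only edges shorter than the cutoff."""
        n = len(self.nodes)
        pure = np.zeros(n, dtype=bool)
        for k in range(n - 1, -1, -1):
            if self.is_leaf[k]:
                pure[k] = True
            else:
                pure[k] = all(
                    pure[c] and self.lengths[c] < cutoff
                    for c in self.children[k]
                )
        state = []
        stack = [0]
        while stack:
            k = stack.pop()
            if pure[k]:
                state.append(k)
            else:
                stack.extend(self.children[k])
        return frozenset(state)

    def random_state(self, rng: np.random.Generator) -> frozenset[int]:
        state = []
        stack = [0]
        while stack:
            k = stack.pop()
            if self.is_leaf[k] or rng.random() < 0.5:
                state.append(k)
            else:
                stack.extend(self.children[k])
        return frozenset(state)


def _deterministic_starts(pt: _PtpTree) -> list[frozenset[int]]:
    lengths = pt.lengths[1:]
    cutoffs = np.quantile(lengths, np.linspace(0.05, 0.95, 19))
    starts = [pt.all_tip_state(), pt.root_state()]
    starts += [pt.threshold_state(float(c)) for c in np.unique(cutoffs)]
    return starts


def _greedy_descent(pt: _PtpTree, state: frozenset[int]) -> tuple[frozenset[int], float]:
    ll = pt.log_likelihood(state)
    while True:
        neighbors = pt.moves(state)
        if not neighbors:
            return state, ll
        scored = [(pt.log_likelihood(s), tuple(sorted(s)), s) for s in neighbors]
        best_ll, _, best_state = max(scored, key=lambda t: (t[0], t[1]))
        if best_ll <= ll + 1e-12:
            return state, ll
        state, ll = best_state, best_ll


def ptp_ml(
    tree: dendropy.Tree,
    n_restarts: int = 20,
    seed: int = DEFAULT_SEED,
    min_branch: float = EPS_BRANCH,
) -> tuple[PtpModel, Partition]:
    """Maximum-likelihood PTP delimitation on a tree with branch lengths."""
    pt = _PtpTree(tree, min_branch=min_branch)
    n_tips = int(pt.is_leaf.sum())
    if n_tips < 3:
        raise ValueError("PTP needs at least 3 tips")
    lengths = pt.lengths[1:]
    if np.ptp(lengths) < 1e-12:
        # No two-class signal at all: a single MOTU, flagged.
        state = pt.root_state()
        lam_s, lam_c = pt.rates_from(state)
        model = PtpModel(
            lambda_speciation=lam_s,
            lambda_coalescent=lam_c,
            edge_classes=pt.edge_classes_from(state),
            log_likelihood=pt.log_likelihood(state),
            low_confidence=True,
        )
        part = Partition(Method.PTP_ML, pt.partition_from(state))
        return model, part

    rng = np.random.default_rng(seed)
    starts = _deterministic_starts(pt)
    starts += [pt.random_state(rng) for _ in range(n_restarts)]
    best_state, best_ll = None, -math.inf
    for s in starts:
        state, ll = _greedy_descent(pt, s)
        if ll > best_ll + 1e-12 or (
            best_state is not None
            and abs(ll - best_ll) <= 1e-12
            and tuple(sorted(state)) < tuple(sorted(best_state))
        ):
            best_state, best_ll = state, ll
    lam_s, lam_c = pt.rates_from(best_state)
    model = PtpModel(
        lambda_speciation=lam_s,
        lambda_coalescent=lam_c,
        edge_classes=pt.edge_classes_from(best_state),
        log_likelihood=best_ll,
    )
    part = Partition(
        Method.PTP_ML,
        pt.partition_from(best_state),
        parameters={"seed": seed, "n_restarts": n_restarts},
    ).relabel_canonical()
    return model, part


@dataclass
class BptpConfig:
    generations: int = 500_000
    thinning: int = 100
    burn_in: float = 0.10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (0.0 <= self.burn_in < 1.0):
            raise ValueError("burn_in must be in [0, 1)")


def bptp_sample(
    tree: dendropy.Tree,
    config: BptpConfig | None = None,
    min_branch: float = EPS_BRANCH,
) -> tuple[Partition, dict[str, float]]:
    """Bayesian PTP: MH sampling over boundary configurations.

    Returns the highest-support non-conflicting MOTU set and per-specimen
    support (posterior frequency with which the specimen's exact MOTU tip
    set is delimited).
    """
    cfg = config or BptpConfig()
    pt = _PtpTree(tree, min_branch=min_branch)
    rng = np.random.default_rng(cfg.seed)
    # start near the posterior mode (the chain is valid from any start;
    # this just shortens burn-in)
    state, ll = max(
        (_greedy_descent(pt, s) for s in _deterministic_starts(pt)),
        key=lambda t: t[1],
    )
    moves = pt.moves(state)
    samples: list[frozenset[int]] = []
    keep_from = int(cfg.generations * cfg.burn_in)
    for gen in range(cfg.generations):
        proposal = moves[rng.integers(len(moves))]
        prop_ll = pt.log_likelihood(proposal)
        prop_moves = pt.moves(proposal)
        log_alpha = (prop_ll - ll) + math.log(len(moves) / len(prop_moves))
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            state, ll, moves = proposal, prop_ll, prop_moves
        if gen >= keep_from and (gen - keep_from) % cfg.thinning == 0:
            samples.append(state)
    # per-MOTU support: frequency each exact tip set appears
    counts: dict[frozenset[int], int] = {}
    state_counts: dict[frozenset[int], int] = {}
    for s in samples:
        state_counts[s] = state_counts.get(s, 0) + 1
        for r in s:
            key = frozenset(pt.tips_below[r])
            counts[key] = counts.get(key, 0) + 1
    n_samples = len(samples)
    support = {k: v / n_samples for k, v in counts.items()}
    # modal sampled configuration (ties broken by sorted node ids)
    modal = max(
        state_counts.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0], reverse=True)))
    )[0]
    assignment = {}
    spec_support = {}
    for gi, r in enumerate(sorted(modal)):
        tipset = frozenset(pt.tips_below[r])
        sup = support.get(tipset, 0.0)
        for t in tipset:
            assignment[pt.tip_label[t]] = gi
            spec_support[pt.tip_label[t]] = sup
    state_freq = {
        frozenset(
            frozenset(pt.tip_label[t] for t in pt.tips_below[r]) for r in s
        ): c / n_samples
        for s, c in state_counts.items()
    }
    part = Partition(
        Method.BPTP,
        assignment,
        parameters={
            "generations": cfg.generations,
            "thinning": cfg.thinning,
            "burn_in": cfg.burn_in,
            "seed": cfg.seed,
            "state_frequencies": state_freq,
            "n_samples": n_samples,
        },
    ).relabel_canonical()
    return part, spec_support


def bptp_exact_posterior(tree: dendropy.Tree) -> dict[frozenset[frozenset[str]], float]:
    """Exhaustive PTP posterior over all boundary configurations.

    Only feasible for small trees; used as an oracle for the sampler.
    States are returned as partitions (frozenset of tip-label frozensets)
    with their normalised posterior mass under a flat prior.
    """
    pt = _PtpTree(tree)

    def antichains(k: int) -> list[list[int]]:
        if pt.is_leaf[k]:
            return [[k]]
        below = [[k]]
        child_chains = [antichains(c) for c in pt.children[k]]
        for combo in itertools.product(*child_chains):
            below.append(list(itertools.chain.from_iterable(combo)))
        return below

    states = antichains(0)
    lls = np.array([pt.log_likelihood(s) for s in states])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    out = {}
    for s, p in zip(states, w):
        key = frozenset(
            frozenset(pt.tip_label[t] for t in pt.tips_below[r]) for r in s
        )
        out[key] = out.get(key, 0.0) + float(p)
    return out


# ---------------------------------------------------------------------------
# BIN-style surrogate


BIN_THRESHOLD = 0.022  # single-linkage seed threshold, 2.2%


def _binlike_split(
    matrix: DistanceMatrix, ids: list[str], X: float, W: int
) -> list[list[str]]:
    if len(ids) < 2:
        return [ids]
    sub = matrix.submatrix(ids)
    iu = np.triu_indices(len(ids), k=1)
    dists = np.sort(sub.values[iu])
    gaps = np.diff(dists)
    gap_at = None
    for i in range(dists.size - 1):
        g = gaps[i]
        if g < BIN_THRESHOLD:
            continue
        window = gaps[max(0, i - W) : i]
        mean_gap = float(window.mean()) if window.size else 0.0
        if g > X * mean_gap:
            gap_at = i
            break
    if gap_at is None:
        return [ids]
    # cut at the gap midpoint; if a chaining link keeps the cluster
    # connected, lower the cut through the distinct values below the gap
    # until the deep divergence actually separates (or give up)
    candidates = [float(dists[gap_at] + 0.5 * gaps[gap_at])]
    candidates += sorted(set(dists[: gap_at + 1]), reverse=True)
    labels = None
    for threshold in candidates:
        trial = _components(sub.values, threshold)
        if len(set(trial)) == 1:
            continue
        # accept only if the components are separated by at least the BIN
        # threshold, i.e. the cut realises a deep divergence rather than
        # shattering a chain
        cross = sub.values[trial[:, None] != trial[None, :]]
        if cross.size and cross.min() >= BIN_THRESHOLD:
            labels = trial
            break
    if labels is None:
        return [ids]
    groups = []
    for lbl in sorted(set(labels)):
        members = [ids[k] for k in np.flatnonzero(labels == lbl)]
        groups.extend(_binlike_split(matrix, members, X, W))
    return groups


def binlike_partition(
    matrix: DistanceMatrix, relative_gap_width: float = 1.0, window: int = 10
) -> Partition:
    """BIN-style clustering: single linkage at 2.2%, then gap refinement.

    Stage 1 links every pair at or below 2.2% divergence and takes connected
    components.  Stage 2 rescans each component for an internal gap of at
    least 2.2% (significant relative to the local gap structure) and splits
    recursively.  Deterministic and order-invariant.
    """
    labels = _components(matrix.values, BIN_THRESHOLD)
    groups: list[list[str]] = []
    for lbl in sorted(set(labels)):
        members = [matrix.ids[k] for k in np.flatnonzero(labels == lbl)]
        groups.extend(
            _binlike_split(matrix, members, relative_gap_width, window)
        )
    # canonical numbering independent of specimen input order
    groups.sort(key=lambda grp: min(grp))
    assignment = {sid: gi for gi, grp in enumerate(groups) for sid in grp}
    return Partition(
        Method.BINLIKE,
        assignment,
        parameters={"threshold": BIN_THRESHOLD, "X": relative_gap_width},
    )


# ---------------------------------------------------------------------------
# Full delimitation pipeline


@dataclass
class DelimitationResult:
    matrix: DistanceMatrix
    tree: "dendropy.Tree"
    abgd_sweep: list[tuple[float, Partition, int]]
    partitions: dict[Method, Partition]
    bptp_support: dict[str, float]
    ptp_model: PtpModel


def run_delimitation(
    library: BarcodeLibrary,
    model: Model | str = Model.K2P,
    tree: "dendropy.Tree | None" = None,
    abgd_config: AbgdConfig | None = None,
    bptp_config: BptpConfig | None = None,
    seed: int = DEFAULT_SEED,
) -> DelimitationResult:
    """Distance matrix, NJ tree (unless supplied) and all four partitions.

    PTP branch lengths are floored at half a substitution over the
    alignment length — the resolution below which the tree cannot
    distinguish a branch from zero.
    """
    from .distances import build_matrix
    from .trees import neighbor_joining

    matrix = build_matrix(library, model)
    if tree is None:
        tree = neighbor_joining(matrix)
    min_branch = 0.5 / library.alignment_length
    binlike = binlike_partition(matrix)
    cfg = abgd_config or AbgdConfig(model=Model(model))
    sweep = abgd_partition(matrix, cfg)
    abgd = select_partition(sweep, binlike)
    ptp_model, ptp = ptp_ml(tree, seed=seed, min_branch=min_branch)
    bcfg = bptp_config or BptpConfig(generations=100_000, seed=seed)
    bptp, support = bptp_sample(tree, bcfg, min_branch=min_branch)
    return DelimitationResult(
        matrix=matrix,
        tree=tree,
        abgd_sweep=sweep,
        partitions={
            Method.BINLIKE: binlike,
            Method.ABGD: abgd,
            Method.PTP_ML: ptp,
            Method.BPTP: bptp,
        },
        bptp_support=support,
        ptp_model=ptp_model,
    )


# ---------------------------------------------------------------------------
# Concordance with morphology


class Concordance(str, enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    SINGLETON = "singleton"


@dataclass
class ConcordanceLabel:
    cluster_id: int
    label: Concordance
    member_species: frozenset[str]


@dataclass
class ConcordanceCounts:
    concordant: int
    discordant: int
    singleton: int

    @property
    def total(self) -> int:
        return self.concordant + self.discordant + self.singleton


def classify_concordance(
    partition: Partition, library: BarcodeLibrary
) -> tuple[list[ConcordanceLabel], ConcordanceCounts]:
    """Label each cluster concordant (one morphospecies, >=2 specimens),
    discordant (>=2 morphospecies) or singleton (one specimen)."""
    by_species = {r.specimen_id: r.morphospecies for r in library.records}
    missing = set(by_species) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover {sorted(missing)}")
    labels = []
    for cid, members in sorted(partition.clusters().items()):
        species = frozenset(by_species[m] for m in members)
        if len(members) == 1:
            kind = Concordance.SINGLETON
        elif len(species) == 1:
            kind = Concordance.CONCORDANT
        else:
            kind = Concordance.DISCORDANT
        labels.append(ConcordanceLabel(cid, kind, species))
    counts = ConcordanceCounts(
        concordant=sum(l.label is Concordance.CONCORDANT for l in labels),
        discordant=sum(l.label is Concordance.DISCORDANT for l in labels),
        singleton=sum(l.label is Concordance.SINGLETON for l in labels),
    )
    return labels, counts
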
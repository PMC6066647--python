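"""The decision layer: combine distance summaries, nearest-neighbour
evidence and the three delimitation partitions into per-morphospecies
verdicts and an overall MOTU tally.

Two rules operate, routed by nomenclature:

* **Described rule** — applies to plain binomials and to uncertain
  identifications anchored to a nominal species (``aff.``, ``cf.``,
  ``gr.``).  A species is a *cryptic candidate* when its maximum
  intraspecific divergence exceeds the threshold (default 2%), the three
  delimitation methods congruently split it into k >= 2 clusters, and none
  of its clusters is shared with another nominal species.  Deep divergence
  with a shared cluster instead suggests misidentification or
  introgression/hybridisation (indistinguishable from COI alone); deep
  divergence without congruent method support is left unresolved.

* **Undescribed rule** — applies to ``sp.`` and family-level labels.  Such
  a taxon is a *new MOTU* when it occupies at least one cluster exclusive
  of (and not assignable by sequence similarity to) any nominal species;
  taxa whose clusters are all shared with, or >= 98% similar to, a nominal
  species are assigned to that neighbour instead.

Cluster-count congruence is configurable: ``strict`` requires all three
methods to report the same count, ``majority`` accepts agreement between
any two.

The cryptic tally counts MOTUs hidden *within* labels: for a flagged
described species, the congruent cluster count minus the number of nominal
labels it covers; for an undescribed taxon, every exclusive cluster beyond
the one carrying the label itself — all of them when the label is also
anchored elsewhere (shared or similarity-assigned clusters) and its
divergence structure shows a genuine internal split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, SpeciesSummary, species_summaries
from .delimit import Method, Partition
from .io import BarcodeLibrary, NomenclatureStatus, Qualifier

#: Qualifiers whose labels are anchored to a nominal species and therefore
#: judged by the described-species rule.
NOMINAL_QUALIFIERS = {Qualifier.NONE, Qualifier.AFF, Qualifier.CF, Qualifier.GR}


class Strictness(str, enum.Enum):
    STRICT = "strict"
    MAJORITY = "majority"


class Verdict(str, enum.Enum):
    CRYPTIC_CANDIDATE = "cryptic_candidate"
    NEW_MOTU = "new_motu"
    ASSIGNED_TO_NOMINAL = "assigned_to_nominal"
    MISID_OR_HYBRID_SUSPECT = "misid_or_hybrid_suspect"
    UNRESOLVED = "unresolved"


@dataclass
class CongruenceConfig:
    intra_threshold: float = 2.0  # percent
    inter_low_threshold: float = 1.0  # percent
    similarity_assign_threshold: float = 98.0  # percent
    strictness: Strictness = Strictness.STRICT

    def __post_init__(self) -> None:
        if not self.inter_low_threshold < self.intra_threshold:
            raise ValueError("inter_low_threshold must be < intra_threshold")


@dataclass
class SpeciesEvidence:
    """Everything the decision rules need about one morphospecies."""

    morphospecies: str
    nomenclature_status: NomenclatureStatus
    qualifier: Qualifier
    max_intra: Optional[float] = None  # percent
    mean_intra: Optional[float] = None
    n_clades: Optional[int] = None  # NJ tree clades (evidence only)
    n_bin: Optional[int] = None
    n_abgd: Optional[int] = None
    n_bptp: Optional[int] = None
    shares_cluster_with_nominal: bool = False
    n_exclusive_clusters: int = 0  # exclusive and not similarity-assignable
    has_assigned_cluster: bool = False  # exclusive but >=98% to a nominal sp.
    nn_species: str = ""
    nn_distance: Optional[float] = None  # percent
    max_similarity: Optional[float] = None  # percent
    n_labels: int = 1  # morphospecies covered by this evidence row


@dataclass
class MOTUDecision:
    morphospecies: str
    verdict: Verdict
    n_new_motus: int
    n_cryptic: int
    evidence: SpeciesEvidence
    rationale: str


def congruent_count(
    evidence: SpeciesEvidence, strictness: Strictness
) -> Optional[int]:
    """The cluster count the three methods agree on, or None."""
    counts = [evidence.n_bin, evidence.n_abgd, evidence.n_bptp]
    if any(c is None for c in counts):
        raise ValueError(
            f"{evidence.morphospecies}: missing cluster counts {counts}"
        )
    if counts[0] == counts[1] == counts[2]:
        return counts[0]
    if strictness is Strictness.MAJORITY:
        for value in set(counts):
            if counts.count(value) >= 2:
                return value
    return None


def flag_described(
    evidence: SpeciesEvidence, config: CongruenceConfig | None = None
) -> MOTUDecision:
    """Described-species rule (see module docstring)."""
    cfg = config or CongruenceConfig()
    ev = evidence
    if ev.max_intra is None or ev.max_intra <= cfg.intra_threshold:
        return MOTUDecision(
            ev.morphospecies, Verdict.ASSIGNED_TO_NOMINAL, 0, 0, ev,
            "intraspecific divergence at or below threshold",
        )
    if ev.shares_cluster_with_nominal:
        return MOTUDecision(
            ev.morphospecies, Verdict.MISID_OR_HYBRID_SUSPECT, 0, 0, ev,
            "deep divergence but clustered with another nominal species",
        )
    k = congruent_count(ev, cfg.strictness)
    if k is None:
        return MOTUDecision(
            ev.morphospecies, Verdict.UNRESOLVED, 0, 0, ev,
            "delimitation methods disagree on cluster count",
        )
    if k >= ev.n_labels + 1:
        extra = k - ev.n_labels
        return MOTUDecision(
            ev.morphospecies, Verdict.CRYPTIC_CANDIDATE, extra, extra, ev,
            f"deep divergence with {k} congruent exclusive clusters",
        )
    return MOTUDecision(
        ev.morphospecies, Verdict.UNRESOLVED, 0, 0, ev,
        "deep divergence but methods recover a single cluster",
    )


def flag_undescribed(
    evidence: SpeciesEvidence, config: CongruenceConfig | None = None
) -> MOTUDecision:
    """Undescribed-taxon rule (see module docstring)."""
    cfg = config or CongruenceConfig()
    ev = evidence
    n_new = ev.n_exclusive_clusters
    if n_new == 0:
        return MOTUDecision(
            ev.morphospecies, Verdict.ASSIGNED_TO_NOMINAL, 0, 0, ev,
            f"all clusters shared with or assignable to {ev.nn_species or 'a nominal species'}",
        )
    k = congruent_count(ev, cfg.strictness)
    if k is None:
        return MOTUDecision(
            ev.morphospecies, Verdict.UNRESOLVED, 0, 0, ev,
            "delimitation methods disagree on cluster count",
        )
    anchored = ev.shares_cluster_with_nominal or ev.has_assigned_cluster
    deep = (
        ev.max_intra is not None and ev.max_intra > cfg.intra_threshold
    ) or n_new >= 2
    n_cryptic = n_new if (anchored and deep) else n_new - 1
    return MOTUDecision(
        ev.morphospecies, Verdict.NEW_MOTU, n_new, n_cryptic, ev,
        f"{n_new} exclusive cluster(s) not assignable to a nominal species",
    )


def decide(
    evidence: SpeciesEvidence, config: CongruenceConfig | None = None
) -> MOTUDecision:
    """Route one evidence row to the appropriate rule."""
    if evidence.qualifier in NOMINAL_QUALIFIERS:
        return flag_described(evidence, config)
    return flag_undescribed(evidence, config)


@dataclass
class MotuTally:
    n_species: int
    cryptic_motus: int
    new_motu_taxa: int
    cryptic_candidates: int
    assigned: int
    suspects: int
    unresolved: int


def motu_tally(decisions: Sequence[MOTUDecision]) -> MotuTally:
    """Summary counts over one decision per morphospecies row."""
    return MotuTally(
        n_species=len(decisions),
        cryptic_motus=sum(d.n_cryptic for d in decisions),
        new_motu_taxa=sum(d.verdict is Verdict.NEW_MOTU for d in decisions),
        cryptic_candidates=sum(
            d.verdict is Verdict.CRYPTIC_CANDIDATE for d in decisions
        ),
        assigned=sum(
            d.verdict is Verdict.ASSIGNED_TO_NOMINAL for d in decisions
        ),
        suspects=sum(
            d.verdict is Verdict.MISID_OR_HYBRID_SUSPECT for d in decisions
        ),
        unresolved=sum(d.verdict is Verdict.UNRESOLVED for d in decisions),
    )


# ---------------------------------------------------------------------------
# Evidence compilation from a full pipeline run


def _clades_on_tree(tree, members: set[str]) -> int:
    """Minimum number of label-pure clades covering the member tips."""
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._pure = node.taxon.label in members
            node._holds = node._pure
        else:
            kids = node.child_nodes()
            node._pure = all(c._pure for c in kids)
            node._holds = any(c._holds for c in kids)
    count = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if node._pure and node._holds and (parent is None or not parent._pure):
            count += 1
    return count


def compile_evidence(
    library: BarcodeLibrary,
    matrix: DistanceMatrix,
    partitions: dict[Method, Partition],
    tree=None,
    config: CongruenceConfig | None = None,
    min_specimens: int = 3,
) -> list[SpeciesEvidence]:
    """Build one evidence row per morphospecies from pipeline outputs.

    ``partitions`` must hold the BINlike, ABGD (selected) and bPTP
    partitions.  Cluster sharing and exclusivity are judged on the BINlike
    partition, mirroring the role the reference-database clustering plays as
    the anchor for taxonomic assignment.
    """
    cfg = config or CongruenceConfig()
    summaries = {
        s.morphospecies: s
        for s in species_summaries(matrix, library, min_specimens)
    }
    by_label = library.species_of()
    rec_of = {r.specimen_id: r for r in library.records}
    ref = partitions[Method.BINLIKE]
    ref_clusters = ref.clusters()
    p_idx = None
    out = []
    for label, members in by_label.items():
        rec = rec_of[members[0]]
        summ = summaries[label]
        counts = {}
        for method in (Method.BINLIKE, Method.ABGD, Method.BPTP):
            part = partitions[method]
            counts[method] = len({part.assignment[m] for m in members})
        member_set = set(members)
        shares = False
        n_exclusive = 0
        has_assigned = False
        for cid, cluster in ref_clusters.items():
            cset = set(cluster)
            if not (cset & member_set):
                continue
            other_nominal = any(
                rec_of[m].morphospecies != label
                and rec_of[m].qualifier in NOMINAL_QUALIFIERS
                for m in cluster
            )
            if other_nominal:
                shares = True
            elif cset <= member_set:
                # exclusive cluster; assignable if some member is within the
                # similarity threshold of a nominal heterospecific specimen
                assignable = _cluster_assignable(
                    matrix, library, cset, label, cfg
                )
                if assignable:
                    has_assigned = True
                else:
                    n_exclusive += 1
        out.append(
            SpeciesEvidence(
                morphospecies=label,
                nomenclature_status=rec.nomenclature_status,
                qualifier=rec.qualifier,
                max_intra=summ.max_intra,
                mean_intra=summ.mean_intra,
                n_clades=_clades_on_tree(tree, member_set) if tree else None,
                n_bin=counts[Method.BINLIKE],
                n_abgd=counts[Method.ABGD],
                n_bptp=counts[Method.BPTP],
                shares_cluster_with_nominal=shares,
                n_exclusive_clusters=n_exclusive,
                has_assigned_cluster=has_assigned,
                nn_species=summ.nn_species,
                nn_distance=summ.nn_distance,
                max_similarity=summ.max_similarity,
            )
        )
    return out


def _cluster_assignable(
    matrix: DistanceMatrix,
    library: BarcodeLibrary,
    cluster: set[str],
    label: str,
    cfg: CongruenceConfig,
) -> bool:
    from .distances import Model, build_matrix

    rec_of = {r.specimen_id: r for r in library.records}
    nominal_ids = [
        r.specimen_id
        for r in library.records
        if r.morphospecies != label and r.qualifier in NOMINAL_QUALIFIERS
    ]
    if not nominal_ids:
        return False
    pm = matrix if matrix.model is Model.P else build_matrix(library, Model.P)
    rows = [pm.index(m) for m in cluster]
    cols = [pm.index(m) for m in nominal_ids]
    min_p = float(pm.values[np.ix_(rows, cols)].min())
    return 100.0 * (1.0 - min_p) >= cfg.similarity_assign_threshold


def decide_all(
    evidence: Sequence[SpeciesEvidence],
    config: CongruenceConfig | None = None,
) -> list[MOTUDecision]:
    return [decide(ev, config) for ev in evidence]


class IncongruenceType(str, enum.Enum):
    MERGE = "merge"
    SPLIT = "split"
    GAP_VIOLATION = "gap_violation"


def incongruence_types(
    partitions: dict[Method, Partition],
    library: BarcodeLibrary,
    matrix: DistanceMatrix,
    config: CongruenceConfig | None = None,
    min_specimens: int = 3,
) -> dict[str, set[IncongruenceType]]:
    """Per-morphospecies incongruence flags across all methods.

    ``merge``: some method pools the species with another morphospecies;
    ``split``: some method spreads it over >= 2 clusters; ``gap_violation``:
    max intraspecific divergence above the deep threshold combined with a
    nearest-neighbour distance below the low interspecific threshold.
    """
    cfg = config or CongruenceConfig()
    by_label = library.species_of()
    rec_of = {r.specimen_id: r for r in library.records}
    summaries = {
        s.morphospecies: s
        for s in species_summaries(matrix, library, min_specimens)
    }
    out: dict[str, set[IncongruenceType]] = {lbl: set() for lbl in by_label}
    for label, members in by_label.items():
        member_set = set(members)
        for part in partitions.values():
            cids = {part.assignment[m] for m in members}
            if len(cids) >= 2:
                out[label].add(IncongruenceType.SPLIT)
            for cid, cluster in part.clusters().items():
                if cid in cids and any(
                    rec_of[m].morphospecies != label for m in cluster
                ):
                    out[label].add(IncongruenceType.MERGE)
        summ = summaries[label]
        if (
            summ.max_intra is not None
            and summ.max_intra > cfg.intra_threshold
            and summ.nn_distance < cfg.inter_low_threshold
        ):
            out[label].add(IncongruenceType.GAP_VIOLATION)
    return out
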
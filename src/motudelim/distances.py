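"""Pairwise evolutionary distances and barcode-gap summaries.

Distances are computed under pairwise deletion: for each sequence pair, only
alignment columns where *both* sequences carry an unambiguous A/C/G/T are
compared.  Three models are supported:

* ``p``    — raw mismatch proportion,
* ``JC69`` — Jukes–Cantor, d = -(3/4) ln(1 - (4/3) p),
* ``K2P``  — Kimura two-parameter, d = -(1/2) ln[(1 - 2P - Q) sqrt(1 - 2Q)],
  where P and Q are the transition and transversion proportions.

K2P is the conventional model for COI barcode surveys and the default
throughout the package.  When the log argument is non-positive the distance
is saturated: it is flagged and reported as +inf.

Rank summaries pool distances between specimens sharing a label at a given
rank: conspecific pairs (species), congeneric heterospecific pairs (genus)
and confamilial heterogeneric pairs (family).  Species-level summaries also
report the nearest-neighbour species/distance and a BOLD-style maximum
similarity, 100 x (1 - minimum p-distance to any heterospecific specimen).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import BarcodeLibrary

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
# A=0 C=1 G=2 T=3; purines are even codes, so a transition is a difference
# between two codes of equal parity.


class Model(str, enum.Enum):
    K2P = "K2P"
    JC69 = "JC69"
    P = "p"


class DistanceError(ValueError):
    """No comparable sites, or a malformed matrix."""


@dataclass
class K2PStats:
    """Transition/transversion proportions for one pair."""

    P: float
    Q: float
    n_sites: int


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (255 = gap/ambiguity)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(n comparable sites, n transitions, n transversions) for coded pair."""
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    diff = ok & (a != b)
    ts = int((diff & ((a % 2) == (b % 2))).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def pairwise_k2p(seq_a: str, seq_b: str) -> tuple[float, K2PStats]:
    """K2P distance for one aligned pair; +inf when saturated."""
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences have different lengths")
    n, ts, tv = _pair_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        raise DistanceError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    stats = K2PStats(P=P, Q=Q, n_sites=n)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf, stats
    return -0.5 * math.log(w1 * math.sqrt(w2)), stats


def pairwise_jc69(seq_a: str, seq_b: str) -> float:
    """JC69 distance for one aligned pair; +inf when saturated (p >= 3/4)."""
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences have different lengths")
    n, ts, tv = _pair_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        raise DistanceError("no comparable sites after pairwise deletion")
    p = (ts + tv) / n
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.inf
    return -0.75 * math.log(arg)


def pairwise_p(seq_a: str, seq_b: str) -> float:
    """Raw mismatch proportion for one aligned pair."""
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences have different lengths")
    n, ts, tv = _pair_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        raise DistanceError("no comparable sites after pairwise deletion")
    return (ts + tv) / n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with site-count bookkeeping."""

    ids: list[str]
    model: Model
    values: np.ndarray
    site_counts: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise DistanceError("matrix shape does not match id count")
        finite = v[np.isfinite(v)]
        if not np.allclose(np.diag(v), 0.0):
            raise DistanceError("non-zero diagonal")
        sym = np.where(np.isfinite(v), v, -1.0)
        if not np.allclose(sym, sym.T):
            raise DistanceError("matrix is not symmetric")
        if finite.size and finite.min() < -1e-12:
            raise DistanceError("negative distances")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def submatrix(self, subset: list[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in subset]
        return DistanceMatrix(
            ids=list(subset),
            model=self.model,
            values=self.values[np.ix_(idx, idx)],
            site_counts=self.site_counts[np.ix_(idx, idx)],
            saturated=self.saturated[np.ix_(idx, idx)],
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy 'condensed' order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def build_matrix(library: BarcodeLibrary, model: Model | str = Model.K2P) -> DistanceMatrix:
    """All pairwise distances for a library, in record order."""
    model = Model(model)
    ids = library.ids
    coded = [encode(r.sequence) for r in library.records]
    n = len(ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        sites[i, i] = int((coded[i] < 4).sum())
        for j in range(i + 1, n):
            ns, ts, tv = _pair_counts(coded[i], coded[j])
            if ns == 0:
                raise DistanceError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            if model is Model.P:
                d = (ts + tv) / ns
            elif model is Model.JC69:
                arg = 1.0 - 4.0 * (ts + tv) / (3.0 * ns)
                d = -0.75 * math.log(arg) if arg > 0 else math.inf
            else:
                w1 = 1.0 - (2.0 * ts + tv) / ns
                w2 = 1.0 - 2.0 * tv / ns
                d = (
                    -0.5 * math.log(w1 * math.sqrt(w2))
                    if (w1 > 0 and w2 > 0)
                    else math.inf
                )
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = ns
            sat[i, j] = sat[j, i] = not math.isfinite(d)
    return DistanceMatrix(
        ids=list(ids), model=model, values=values, site_counts=sites, saturated=sat
    )


def write_phylip(matrix: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix export (names padded to 10 chars)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, name in enumerate(matrix.ids):
            row = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(len(matrix.ids)))
            fh.write(f"{name[:10]:<10} {row}\n")


def write_long_tsv(matrix: DistanceMatrix, path) -> None:
    """Long-form export: id_a, id_b, model, distance, n_sites."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tmodel\tdistance\tn_sites\n")
        for i, a in enumerate(matrix.ids):
            for j in range(i + 1, len(matrix.ids)):
                fh.write(
                    f"{a}\t{matrix.ids[j]}\t{matrix.model.value}\t"
                    f"{matrix.values[i, j]:.8f}\t{matrix.site_counts[i, j]}\n"
                )


# ---------------------------------------------------------------------------
# Rank-level summaries


@dataclass
class RankSummary:
    rank: str  # species | genus | family
    n_pairs: int
    min: float  # percent
    mean: float
    max: float


def _rank_pairs(library: BarcodeLibrary, rank: str) -> list[tuple[int, int]]:
    recs = library.records
    pairs = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if rank == "species":
                keep = a.morphospecies == b.morphospecies
            elif rank == "genus":
                keep = (
                    a.genus
                    and a.genus == b.genus
                    and a.morphospecies != b.morphospecies
                )
            elif rank == "family":
                keep = (
                    a.family
                    and a.family == b.family
                    and a.genus != b.genus
                )
            else:
                raise ValueError(f"unknown rank {rank!r}")
            if keep:
                pairs.append((i, j))
    return pairs


def summarize_ranks(
    matrix: DistanceMatrix, library: BarcodeLibrary
) -> list[RankSummary]:
    """Min/mean/max percent divergence pooled at species, genus and family
    rank (conspecific, congeneric-heterospecific, confamilial-heterogeneric
    pairs respectively).  Ranks with no comparable pair are omitted with a
    warning."""
    out = []
    for rank in ("species", "genus", "family"):
        pairs = _rank_pairs(library, rank)
        dists = [matrix.values[i, j] for i, j in pairs]
        dists = [d for d in dists if math.isfinite(d)]
        if not dists:
            warnings.warn(f"no comparable pair at rank {rank!r}; omitted")
            continue
        arr = np.asarray(dists) * 100.0
        out.append(
            RankSummary(
                rank=rank,
                n_pairs=len(dists),
                min=float(arr.min()),
                mean=float(arr.mean()),
                max=float(arr.max()),
            )
        )
    return out


@dataclass
class HistogramTable:
    rank: str
    bin_edges: np.ndarray  # percent
    counts: np.ndarray
    fraction_below_1: float
    fraction_below_2: float


def divergence_histogram(
    matrix: DistanceMatrix,
    library: BarcodeLibrary,
    rank: str = "species",
    bin_width: float = 1.0,
) -> HistogramTable:
    """Histogram of per-group maximum divergence (percent).

    Groups are morphospecies (rank ``species``: max conspecific distance) or
    genera (rank ``genus``: max congeneric-heterospecific distance); groups
    with no comparable pair are counted in the first bin at 0.
    """
    groups: dict[str, list[float]] = {}
    recs = library.records
    for i, j in _rank_pairs(library, rank):
        key = recs[i].morphospecies if rank == "species" else recs[i].genus
        d = matrix.values[i, j]
        if math.isfinite(d):
            groups.setdefault(key, []).append(d * 100.0)
    labels = (
        {r.morphospecies for r in recs}
        if rank == "species"
        else {r.genus for r in recs if r.genus}
    )
    maxima = np.array(
        [max(groups.get(lbl, [0.0])) for lbl in sorted(labels)]
    )
    top = max(bin_width, float(np.ceil(maxima.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(maxima, bins=edges)
    return HistogramTable(
        rank=rank,
        bin_edges=edges,
        counts=counts,
        fraction_below_1=float((maxima < 1.0).mean()),
        fraction_below_2=float((maxima < 2.0).mean()),
    )


@dataclass
class SpeciesSummary:
    morphospecies: str
    n_specimens: int
    max_intra: Optional[float]  # percent; None when n < min_specimens
    mean_intra: Optional[float]
    nn_species: str
    nn_distance: float  # percent
    max_similarity: float  # percent, from p-distance

    @property
    def barcode_gap(self) -> Optional[float]:
        if self.max_intra is None:
            return None
        return self.nn_distance - self.max_intra


def species_summaries(
    matrix: DistanceMatrix,
    library: BarcodeLibrary,
    min_specimens: int = 3,
) -> list[SpeciesSummary]:
    """Per-morphospecies divergence, nearest neighbour and similarity.

    Intraspecific statistics are reported only for species with at least
    ``min_specimens`` specimens (sparser species give unstable estimates and
    are conventionally excluded).  ``max_similarity`` uses p-distance,
    mirroring how sequence-similarity scores are reported by barcode
    reference databases.
    """
    species = library.species_of()
    if len(species) < 2:
        raise DistanceError("need at least two morphospecies")
    p_matrix = (
        matrix
        if matrix.model is Model.P
        else build_matrix(library, Model.P)
    )
    idx = {sid: k for k, sid in enumerate(matrix.ids)}
    out = []
    for label, members in species.items():
        rows = [idx[m] for m in members]
        others = [k for sid, k in idx.items() if sid not in set(members)]
        intra = [
            matrix.values[a, b]
            for ai, a in enumerate(rows)
            for b in rows[ai + 1 :]
            if math.isfinite(matrix.values[a, b])
        ]
        if len(members) >= min_specimens and intra:
            max_intra = float(max(intra)) * 100.0
            mean_intra = float(np.mean(intra)) * 100.0
        else:
            max_intra = mean_intra = None
        sub = matrix.values[np.ix_(rows, others)]
        k = int(np.argmin(sub))
        r, c = divmod(k, sub.shape[1])
        nn_idx = others[c]
        nn_distance = float(sub[r, c]) * 100.0
        nn_species = library.records[nn_idx].morphospecies
        p_sub = p_matrix.values[np.ix_(rows, others)]
        max_similarity = 100.0 * (1.0 - float(p_sub.min()))
        out.append(
            SpeciesSummary(
                morphospecies=label,
                n_specimens=len(members),
                max_intra=max_intra,
                mean_intra=mean_intra,
                nn_species=nn_species,
                nn_distance=nn_distance,
                max_similarity=max_similarity,
            )
        )
    return out
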
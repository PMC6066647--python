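"""Synthetic barcode libraries with known truth, plus packaged evidence
fixtures transcribing the published survey tables.

The generator emulates the statistical structure a COI barcode survey
assumes: well-separated species (a star species tree whose stem lengths put
every interspecific distance at or above ``min_inter``), shallow star
genealogies within species (expected pairwise intraspecific divergence
``expected_intra``), and a two-rate substitution process (transitions
``kappa`` times faster than each transversion, the K2P generating model) run
over a stop-free protein-coding scaffold so that every simulated sequence
passes the NUMT screen.  On top of the clean library three kinds of noise
can be injected, each logged in the truth table:

* *cryptic lineages* — an extra within-label split at ``cryptic_depth``,
  the signature of a cryptic species;
* *label swaps* — one specimen relabelled to another morphospecies,
  mimicking misidentification;
* *shared haplotypes* — one specimen's sequence replaced by a haplotype
  from another species, mimicking introgression/hybridisation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .congruence import SpeciesEvidence, NOMINAL_QUALIFIERS
from .io import (
    BarcodeLibrary,
    NomenclatureStatus,
    Qualifier,
    SpecimenRecord,
    parse_nomenclature,
)

_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _MITO_STOPS
]
# transition partner of each base: A<->G, C<->T
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_species: int = 10
    specimens_per_species: float = 4.5  # int -> exact; float -> mean of draw
    seq_length: int = 658
    kappa: float = 4.0  # transition/transversion rate ratio
    expected_intra: float = 0.005
    min_inter: float = 0.05
    n_cryptic_injections: int = 0
    cryptic_depth: float = 0.08
    n_label_swaps: int = 0
    n_shared_haplotypes: int = 0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.min_inter <= self.expected_intra:
            raise SimulationError("min_inter must exceed expected_intra")
        if self.n_cryptic_injections and self.cryptic_depth <= self.expected_intra:
            raise SimulationError("cryptic_depth must exceed expected_intra")
        for name in (
            "n_species",
            "n_cryptic_injections",
            "n_label_swaps",
            "n_shared_haplotypes",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        needed = (
            self.n_cryptic_injections
            + 2 * self.n_label_swaps
            + 2 * self.n_shared_haplotypes
        )
        if needed > self.n_species:
            raise SimulationError(
                "not enough species for the requested injections"
            )


@dataclass
class TruthTable:
    """specimen id -> true MOTU id, plus the injected-event log."""

    assignment: dict[str, str]
    events: list[dict] = field(default_factory=list)

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["specimen_id", "true_motu"])
            for sid, motu in self.assignment.items():
                w.writerow([sid, motu])


def _random_coding_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    n_codons, rest = divmod(length, 3)
    picks = rng.integers(0, len(_CODONS), n_codons)
    seq = "".join(_CODONS[k] for k in picks)
    seq += "".join(_BASES[k] for k in rng.integers(0, 4, rest))
    return np.array([_BASES.index(c) for c in seq], dtype=np.int8)


def _evolve(
    seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve coded sequence for branch length t (expected subs/site).

    Events are placed Poisson(t * L); each is a transition with probability
    kappa/(kappa+2), else one of the two transversions.  A substitution that
    would create an in-frame stop codon is re-drawn (the scaffold is a
    protein-coding gene under purifying selection at stop positions).
    """
    out = seq.copy()
    L = out.size
    n_events = rng.poisson(t * L)
    p_ts = kappa / (kappa + 2.0)
    for _ in range(n_events):
        for _attempt in range(20):
            site = int(rng.integers(L))
            old = int(out[site])
            if rng.random() < p_ts:
                new = _TRANSITION[old]
            else:
                choices = [b for b in range(4) if b != old and b != _TRANSITION[old]]
                new = choices[int(rng.integers(2))]
            out[site] = new
            codon_start = 3 * (site // 3)
            if codon_start + 3 <= L:
                codon = "".join(_BASES[b] for b in out[codon_start : codon_start + 3])
                if codon in _MITO_STOPS:
                    out[site] = old  # would create a stop; re-draw
                    continue
            break
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def simulate_library(config: SimConfig) -> tuple[BarcodeLibrary, TruthTable]:
    """Generate a library plus its truth table; reproducible given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    root = _random_coding_sequence(cfg.seq_length, rng)

    # star species tree: stems in [min_inter/2, 3*min_inter/2] so every
    # interspecific path length is >= min_inter
    stems = cfg.min_inter / 2.0 * (1.0 + 2.0 * rng.random(cfg.n_species))
    species_names = [f"Genus{i:02d} aquatilis{i:02d}" for i in range(cfg.n_species)]

    if float(cfg.specimens_per_species).is_integer():
        counts = [int(cfg.specimens_per_species)] * cfg.n_species
    else:
        counts = [
            2 + int(rng.poisson(cfg.specimens_per_species - 2.0))
            for _ in range(cfg.n_species)
        ]

    # choose disjoint species for each injection type
    order = list(rng.permutation(cfg.n_species))
    cryptic_sp = order[: cfg.n_cryptic_injections]
    k = cfg.n_cryptic_injections
    swap_pairs = [
        (order[k + 2 * j], order[k + 2 * j + 1])
        for j in range(cfg.n_label_swaps)
    ]
    k += 2 * cfg.n_label_swaps
    share_pairs = [
        (order[k + 2 * j], order[k + 2 * j + 1])
        for j in range(cfg.n_shared_haplotypes)
    ]

    records: list[SpecimenRecord] = []
    truth: dict[str, str] = {}
    events: list[dict] = []
    specimens_by_species: dict[int, list[int]] = {}
    tip_branch = cfg.expected_intra / 2.0

    for i in range(cfg.n_species):
        anc = _evolve(root, stems[i], cfg.kappa, rng)
        n = counts[i]
        sub_ancestors = [anc] * n
        motu_ids = [f"MOTU{i:02d}"] * n
        if i in cryptic_sp and n >= 2:
            cryptic_anc = _evolve(anc, cfg.cryptic_depth, cfg.kappa, rng)
            half = n // 2
            sub_ancestors = [anc] * (n - half) + [cryptic_anc] * half
            motu_ids = [f"MOTU{i:02d}"] * (n - half) + [f"MOTU{i:02d}c"] * half
            events.append(
                {
                    "type": "cryptic_injection",
                    "species": species_names[i],
                    "depth": cfg.cryptic_depth,
                    "n_specimens": half,
                }
            )
        specimens_by_species[i] = []
        for j in range(n):
            seq = _evolve(sub_ancestors[j], tip_branch, cfg.kappa, rng)
            sid = f"SP{i:02d}-{j:02d}"
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    sequence=_decode(seq),
                    morphospecies=species_names[i],
                    genus=f"Genus{i:02d}",
                    family=f"Family{i // 3:02d}",
                    site_id=f"site{int(rng.integers(1, 6)):02d}",
                    basin="SimBasin",
                )
            )
            truth[sid] = motu_ids[j]
            specimens_by_species[i].append(len(records) - 1)

    for src, dst in swap_pairs:
        # one specimen of `src` is misidentified under `dst`'s label
        ridx = specimens_by_species[src][-1]
        rec = records[ridx]
        records[ridx] = SpecimenRecord(
            specimen_id=rec.specimen_id,
            sequence=rec.sequence,
            morphospecies=species_names[dst],
            genus=f"Genus{dst:02d}",
            family=f"Family{dst // 3:02d}",
            site_id=rec.site_id,
            basin=rec.basin,
        )
        events.append(
            {
                "type": "label_swap",
                "species": species_names[dst],
                "true_species": species_names[src],
                "specimen": rec.specimen_id,
            }
        )

    for src, dst in share_pairs:
        # one specimen of `dst` carries a haplotype copied from `src`
        src_idx = specimens_by_species[src][0]
        dst_idx = specimens_by_species[dst][-1]
        rec = records[dst_idx]
        records[dst_idx] = SpecimenRecord(
            specimen_id=rec.specimen_id,
            sequence=records[src_idx].sequence,
            morphospecies=rec.morphospecies,
            genus=rec.genus,
            family=rec.family,
            site_id=rec.site_id,
            basin=rec.basin,
        )
        truth[rec.specimen_id] = truth[records[src_idx].specimen_id]
        events.append(
            {
                "type": "shared_haplotype",
                "species": species_names[dst],
                "donor_species": species_names[src],
                "specimen": rec.specimen_id,
            }
        )

    return BarcodeLibrary(records=records), TruthTable(truth, events)


# ---------------------------------------------------------------------------
# Packaged evidence fixtures (transcribed survey tables)


def _data_rows(name: str) -> list[dict[str, str]]:
    text = resources.files("motudelim.data").joinpath(name).read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return [
        {k: (v or "").strip() for k, v in row.items() if k is not None}
        for row in reader
    ]


def load_deep_divergence_rows() -> list[dict[str, str]]:
    """Raw rows of the described-species deep-divergence table."""
    return _data_rows("deep_divergence_table.tsv")


def load_undescribed_rows() -> list[dict[str, str]]:
    """Raw per-cluster rows of the undescribed-species NN table."""
    return _data_rows("undescribed_nn_table.tsv")


def _deep_divergence_evidence() -> list[SpeciesEvidence]:
    out = []
    for row in load_deep_divergence_rows():
        out.append(
            SpeciesEvidence(
                morphospecies=row["morphospecies"],
                nomenclature_status=NomenclatureStatus.DESCRIBED,
                qualifier=Qualifier.NONE,  # nominal-anchored: described rule
                max_intra=float(row["max_intra"]),
                mean_intra=float(row["mean_intra"]),
                n_clades=int(row["n_clades"]),
                n_bin=int(row["n_bin"]),
                n_abgd=int(row["n_abgd"]),
                n_bptp=int(row["n_bptp"]),
                shares_cluster_with_nominal=row["shares_with_nominal"] == "yes",
                n_labels=int(row["n_labels"]),
            )
        )
    return out


def _undescribed_evidence(
    similarity_assign_threshold: float = 98.0,
) -> list[SpeciesEvidence]:
    clusters = load_undescribed_rows()
    counts = {r["morphospecies"]: r for r in _data_rows("undescribed_taxon_counts.tsv")}
    by_taxon: dict[str, list[dict[str, str]]] = {}
    for row in clusters:
        by_taxon.setdefault(row["morphospecies"], []).append(row)
    out = []
    for taxon, rows in by_taxon.items():
        shares = False
        n_exclusive = 0
        has_assigned = False
        best_sim, best_nn = -1.0, ""
        for row in rows:
            sim = float(row["max_similarity"])
            if sim > best_sim:
                best_sim, best_nn = sim, row["nn_species"]
            if not row["bin"]:
                continue  # similarity comparison only, not a cluster
            kind = row["bin_classification"]
            if kind == "Discordant":
                shares = True
                continue
            nn_label = row["nn_species"].split("/")[0].split(",")[0].strip()
            _, nn_qual = parse_nomenclature(nn_label)
            assignable = (
                kind == "Concordant"
                and sim >= similarity_assign_threshold
                and nn_qual in NOMINAL_QUALIFIERS
                and nn_label != taxon
            )
            if assignable:
                has_assigned = True
            else:
                n_exclusive += 1
        meta = counts[taxon]
        status, qual = parse_nomenclature(taxon)
        out.append(
            SpeciesEvidence(
                morphospecies=taxon,
                nomenclature_status=status,
                qualifier=qual,
                max_intra=float(meta["max_intra"]) if meta.get("max_intra") else None,
                mean_intra=float(meta["mean_intra"]) if meta.get("mean_intra") else None,
                n_bin=int(meta["n_bin"]),
                n_abgd=int(meta["n_abgd"]),
                n_bptp=int(meta["n_bptp"]),
                shares_cluster_with_nominal=shares,
                n_exclusive_clusters=n_exclusive,
                has_assigned_cluster=has_assigned,
                nn_species=best_nn,
                max_similarity=best_sim,
            )
        )
    return out


def table_fixtures() -> tuple[list[SpeciesEvidence], list[SpeciesEvidence]]:
    """Evidence rows for the two survey tables.

    Returns ``(deep_divergence_rows, undescribed_rows)``: described species
    with deep intraspecific divergence, and undescribed taxa with their
    nearest-neighbour/cluster survey.
    """
    return _deep_divergence_evidence(), _undescribed_evidence()


def combined_fixture_evidence() -> list[SpeciesEvidence]:
    """One evidence row per morphospecies across both tables.

    Taxa present in the deep-divergence table (including each label of its
    combined row) are judged there and dropped from the undescribed list to
    avoid double counting.
    """
    deep, undescribed = table_fixtures()
    covered = set()
    for ev in deep:
        for label in ev.morphospecies.split("/"):
            covered.add(label.strip())
    return deep + [ev for ev in undescribed if ev.morphospecies not in covered]
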
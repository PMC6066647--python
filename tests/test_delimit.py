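"""ABGD, PTP (ML and Bayesian), the BIN-style surrogate and concordance."""

import numpy as np
import pytest

import dendropy

from motudelim import (
    AbgdConfig,
    BptpConfig,
    Method,
    Model,
    Partition,
    SimConfig,
    abgd_partition,
    binlike_partition,
    bptp_exact_posterior,
    bptp_sample,
    build_matrix,
    classify_concordance,
    neighbor_joining,
    ptp_ml,
    select_partition,
    simulate_library,
)
from motudelim.delimit import _PtpTree
from motudelim.io import BarcodeLibrary, SpecimenRecord

from conftest import matrix_from_values, truth_to_partition


# ---------------------------------------------------------------------------
# ABGD


def test_abgd_recovers_species_at_low_priors(clean_matrix, truth_partition, clean_library):
    # construction premise: every intraspecific distance below 1%
    library, _ = clean_library
    for members in library.species_of().values():
        idx = [clean_matrix.index(x) for x in members]
        assert clean_matrix.values[np.ix_(idx, idx)].max() <= 0.01
    sweep = abgd_partition(clean_matrix)
    for prior, part, n in sweep:
        if prior <= 0.02:
            assert n == 5, f"prior {prior}: {n} groups"
            assert part.same_clustering(truth_partition)


def test_abgd_group_count_non_increasing_in_prior(clean_matrix):
    sweep = abgd_partition(clean_matrix)
    counts = [n for _, _, n in sweep]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_abgd_all_zero_distances_single_group():
    v = np.zeros((4, 4))
    sweep = abgd_partition(matrix_from_values(list("ABCD"), v))
    assert all(n == 1 for _, _, n in sweep)


def test_abgd_prior_beyond_max_distance_single_group(clean_matrix):
    big = clean_matrix.values.max()
    cfg = AbgdConfig(p_min=big + 0.01, p_max=big + 0.02, n_steps=2)
    sweep = abgd_partition(clean_matrix, cfg)
    assert all(n == 1 for _, _, n in sweep)


def test_select_partition_prefers_companion_match(clean_matrix, truth_partition):
    sweep = abgd_partition(clean_matrix)
    chosen = select_partition(sweep, truth_partition)
    assert chosen.same_clustering(truth_partition)
    # ties (several priors reach Rand = 1) resolve to the smallest prior
    perfect = [p for p, part, _ in sweep if part.same_clustering(truth_partition)]
    assert chosen.parameters["prior"] == min(perfect)


def test_select_partition_identity_companion():
    part = Partition(Method.ABGD, {"a": 0, "b": 0, "c": 1})
    sweep = [(0.001, part, 2), (0.01, part, 2)]
    companion = Partition(Method.BINLIKE, {"a": 5, "b": 5, "c": 9})
    assert select_partition(sweep, companion) is part


# ---------------------------------------------------------------------------
# PTP


def _simulated_tree(seed=21, n_species=4, n_per=4):
    """Tree with short within-species and long between-species branches."""
    lib, truth = simulate_library(
        SimConfig(
            n_species=n_species,
            specimens_per_species=n_per,
            expected_intra=0.004,
            min_inter=0.16,
            seed=seed,
        )
    )
    tree = neighbor_joining(build_matrix(lib))
    return tree, truth_to_partition(truth)


def test_ptp_ml_recovers_species_on_clean_tree():
    tree, truth = _simulated_tree()
    model, part = ptp_ml(tree, seed=1)
    assert part.same_clustering(truth)
    assert model.lambda_coalescent > model.lambda_speciation


def test_ptp_ml_beats_null_configurations(clean_matrix):
    tree = neighbor_joining(clean_matrix)
    model, _ = ptp_ml(tree, seed=1)
    pt = _PtpTree(tree)
    assert model.log_likelihood >= pt.log_likelihood(pt.root_state()) - 1e-9
    assert model.log_likelihood >= pt.log_likelihood(pt.all_tip_state()) - 1e-9


def test_ptp_ml_three_tip_exhaustive():
    tree = dendropy.Tree.get(
        data="((A:0.31,B:0.30):0.02,C:0.33):0.0;", schema="newick"
    )
    model, part = ptp_ml(tree, seed=3)
    pt = _PtpTree(tree)
    best = max(
        pt.log_likelihood(s)
        for s in [pt.root_state(), pt.all_tip_state()]
        + [frozenset(x) for x in _all_antichains(pt)]
    )
    assert model.log_likelihood == pytest.approx(best, abs=1e-9)


def _all_antichains(pt):
    import itertools

    def rec(k):
        if pt.is_leaf[k]:
            return [[k]]
        out = [[k]]
        for combo in itertools.product(*(rec(c) for c in pt.children[k])):
            out.append(list(itertools.chain.from_iterable(combo)))
        return out

    return rec(0)


def test_ptp_ml_flags_featureless_star_tree():
    tree = dendropy.Tree.get(
        data="(A:0.001,B:0.001,C:0.001,D:0.001):0.0;", schema="newick"
    )
    model, part = ptp_ml(tree)
    assert part.n_groups == 1
    assert model.low_confidence


# ---------------------------------------------------------------------------
# bPTP


def test_bptp_matches_exhaustive_posterior_small_tree():
    import math

    tree = dendropy.Tree.get(
        data="((A:0.01,B:0.012):0.2,(C:0.011,D:0.009):0.21):0.0;",
        schema="newick",
    )
    exact = bptp_exact_posterior(tree)
    cfg = BptpConfig(generations=40_000, thinning=10, burn_in=0.1, seed=5)
    part, _ = bptp_sample(tree, cfg)
    freq = part.parameters["state_frequencies"]
    n_eff = part.parameters["n_samples"] / 10  # autocorrelation allowance
    for key, p in exact.items():
        observed = freq.get(key, 0.0)
        se = math.sqrt(p * (1 - p) / n_eff)
        assert abs(observed - p) <= 3 * se + 0.01, (key, observed, p)


def test_bptp_recovers_species_and_is_seed_stable():
    tree, truth = _simulated_tree(seed=23)
    cfg1 = BptpConfig(generations=20_000, thinning=20, seed=1)
    cfg2 = BptpConfig(generations=20_000, thinning=20, seed=99)
    part1, support1 = bptp_sample(tree, cfg1)
    part2, _ = bptp_sample(tree, cfg2)
    assert part1.same_clustering(truth)
    assert part1.same_clustering(part2)
    assert all(0.0 <= s <= 1.0 for s in support1.values())
    assert np.mean([support1[sid] for sid in part1.assignment]) > 0.9


def test_bptp_reproducible_given_seed():
    tree, _ = _simulated_tree(seed=29)
    cfg = BptpConfig(generations=5_000, thinning=10, seed=7)
    part1, sup1 = bptp_sample(tree, cfg)
    part2, sup2 = bptp_sample(tree, cfg)
    assert part1.assignment == part2.assignment
    assert sup1 == sup2


# ---------------------------------------------------------------------------
# BIN-style surrogate


def test_binlike_separates_distant_clusters():
    v = np.zeros((4, 4))
    v[np.ix_([0, 1], [2, 3])] = 0.10
    v[np.ix_([2, 3], [0, 1])] = 0.10
    part = binlike_partition(matrix_from_values(list("ABCD"), v))
    assert part.n_groups == 2


def test_binlike_single_linkage_chain_stays_together():
    v = np.array([[0, 0.01, 0.02], [0.01, 0, 0.01], [0.02, 0.01, 0]])
    part = binlike_partition(matrix_from_values(list("ABC"), v))
    assert part.n_groups == 1


def test_binlike_refinement_splits_internal_gap():
    # one chaining link at exactly 2.2% bridges two tight pairs 5% apart
    v = np.array(
        [
            [0, 0.01, 0.022, 0.05],
            [0.01, 0, 0.05, 0.05],
            [0.022, 0.05, 0, 0.01],
            [0.05, 0.05, 0.01, 0],
        ]
    )
    part = binlike_partition(matrix_from_values(list("ABCD"), v))
    assert part.n_groups == 2
    assert part.assignment["A"] == part.assignment["B"]
    assert part.assignment["C"] == part.assignment["D"]


def test_binlike_invariant_to_specimen_order(clean_library):
    library, _ = clean_library
    mat = build_matrix(library)
    part = binlike_partition(mat)
    rev = BarcodeLibrary(records=list(reversed(library.records)))
    part_rev = binlike_partition(build_matrix(rev))
    assert part.same_clustering(part_rev)


# ---------------------------------------------------------------------------
# concordance


def _two_species_library():
    recs = [
        SpecimenRecord("A1", "A" * 100, "Genus01 unus", "Genus01", "F"),
        SpecimenRecord("A2", "A" * 100, "Genus01 unus", "Genus01", "F"),
        SpecimenRecord("B1", "T" * 100, "Genus02 duo", "Genus02", "F"),
        SpecimenRecord("B2", "T" * 100, "Genus02 duo", "Genus02", "F"),
    ]
    return BarcodeLibrary(records=recs)


def test_concordance_perfectly_labeled():
    lib = _two_species_library()
    part = Partition(Method.BINLIKE, {"A1": 0, "A2": 0, "B1": 1, "B2": 1})
    labels, counts = classify_concordance(part, lib)
    assert counts.concordant == 2 and counts.discordant == 0 and counts.singleton == 0


def test_concordance_discordant_and_singleton():
    lib = _two_species_library()
    part = Partition(Method.BINLIKE, {"A1": 0, "A2": 0, "B1": 0, "B2": 1})
    labels, counts = classify_concordance(part, lib)
    assert counts.discordant == 1
    assert counts.singleton == 1  # B2 alone, even though its label recurs
    assert counts.total == 2
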
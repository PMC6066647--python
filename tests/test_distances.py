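"""K2P/JC69 distances, rank summaries, histograms and species summaries."""

import math

import numpy as np
import pytest

from motudelim import (
    Model,
    SimConfig,
    build_matrix,
    divergence_histogram,
    pairwise_jc69,
    pairwise_k2p,
    pairwise_p,
    simulate_library,
    species_summaries,
    summarize_ranks,
)
from motudelim.distances import DistanceError
from motudelim.io import BarcodeLibrary, SpecimenRecord


def test_identical_sequences_have_zero_distance():
    s = "ACGT" * 25
    assert pairwise_k2p(s, s)[0] == 0.0
    assert pairwise_jc69(s, s) == 0.0


def test_k2p_closed_form_transitions_only():
    # 100 sites, 10 transitions (A->G), 0 transversions
    a = "A" * 100
    b = "G" * 10 + "A" * 90
    d, stats = pairwise_k2p(a, b)
    assert stats.P == 0.1 and stats.Q == 0.0 and stats.n_sites == 100
    assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)


def test_k2p_closed_form_mixed():
    # 100 sites, P = 0.1 (A->G), Q = 0.1 (A->C)
    b = "G" * 10 + "C" * 10 + "A" * 80
    d, stats = pairwise_k2p("A" * 100, b)
    assert (stats.P, stats.Q) == (0.1, 0.1)
    assert d == pytest.approx(-0.5 * math.log(0.7 * math.sqrt(0.8)), abs=1e-12)


def test_jc69_closed_form_and_saturation():
    b = "C" * 10 + "A" * 90
    assert pairwise_jc69("A" * 100, b) == pytest.approx(
        -0.75 * math.log(1 - 0.4 / 3), abs=1e-12
    )
    sat = "C" * 75 + "A" * 25
    assert math.isinf(pairwise_jc69("A" * 100, sat))


def test_pairwise_deletion_skips_gaps_and_ambiguities():
    a = "ACGTN-RACGT"
    b = "ACGT-TAACGT"
    d, stats = pairwise_k2p(a, b)
    assert stats.n_sites == 8  # columns 4,5,6 dropped
    assert d == 0.0


def test_no_comparable_sites_raises():
    with pytest.raises(DistanceError):
        pairwise_k2p("NNNN", "ACGT")


def test_both_models_increase_with_mismatch_count():
    length = 50
    prev_k2p = prev_jc = -1.0
    for k in range(0, 25):  # k = 25 transitions saturates K2P on 50 sites
        b = "G" * k + "A" * (length - k)
        dk, _ = pairwise_k2p("A" * length, b)
        dj = pairwise_jc69("A" * length, b)
        assert dk > prev_k2p and dj > prev_jc
        prev_k2p, prev_jc = dk, dj


def _toy_library():
    # 3 identical specimens of one species
    recs = [
        SpecimenRecord(f"T{i}", "ACGT" * 30, "Hoplias malabaricus", "Hoplias", "Erythrinidae")
        for i in range(3)
    ]
    return BarcodeLibrary(records=recs)


def test_build_matrix_identical_sequences_and_symmetry():
    mat = build_matrix(_toy_library())
    assert np.all(mat.values == 0.0)
    assert np.array_equal(mat.values, mat.values.T)


def test_build_matrix_matches_pairwise_calls(clean_library):
    library, _ = clean_library
    mat = build_matrix(library, Model.K2P)
    recs = library.records
    for i in range(0, len(recs), 7):
        for j in range(i + 1, len(recs), 5):
            d, _ = pairwise_k2p(recs[i].sequence, recs[j].sequence)
            assert mat.values[i, j] == pytest.approx(d, abs=1e-15)


def test_build_matrix_reorder_permutes_values(clean_library):
    library, _ = clean_library
    mat = build_matrix(library)
    rev = BarcodeLibrary(records=list(reversed(library.records)))
    mat_rev = build_matrix(rev)
    assert np.allclose(mat_rev.values, mat.values[::-1, ::-1])


def test_rank_means_are_ordered(clean_library):
    # regroup the five simulated species into shared genera/family so that
    # congeneric and confamilial pairs exist
    library, _ = clean_library
    species = sorted(library.species_of())
    genus_of = {sp: f"G{k // 2}" for k, sp in enumerate(species)}
    recs = [
        SpecimenRecord(
            r.specimen_id, r.sequence, r.morphospecies,
            genus_of[r.morphospecies], "FamilyShared",
        )
        for r in library.records
    ]
    lib = BarcodeLibrary(records=recs)
    mat = build_matrix(lib)
    ranks = {s.rank: s for s in summarize_ranks(mat, lib)}
    assert ranks["species"].mean < ranks["genus"].mean
    assert ranks["species"].mean < ranks["family"].mean
    for s in ranks.values():
        assert s.min <= s.mean <= s.max


def test_rank_summary_exact_arithmetic():
    # two species, one conspecific pair each at exactly 1% and 3% p-distance
    recs = [
        SpecimenRecord("A1", "A" * 100, "Genus01 unus", "Genus01", "Fam"),
        SpecimenRecord("A2", "G" * 1 + "A" * 99, "Genus01 unus", "Genus01", "Fam"),
        SpecimenRecord("B1", "T" * 50 + "A" * 50, "Genus02 duo", "Genus02", "Fam"),
        SpecimenRecord("B2", "T" * 50 + "G" * 3 + "A" * 47, "Genus02 duo", "Genus02", "Fam"),
    ]
    lib = BarcodeLibrary(records=recs)
    mat = build_matrix(lib, Model.P)
    species = [s for s in summarize_ranks(mat, lib) if s.rank == "species"][0]
    assert species.min == pytest.approx(1.0)
    assert species.max == pytest.approx(3.0)
    assert species.mean == pytest.approx(2.0)


def test_singleton_species_contribute_no_species_rank_pairs():
    recs = [
        SpecimenRecord("A1", "A" * 100, "Genus01 unus", "Genus01", "Fam"),
        SpecimenRecord("A2", "A" * 100, "Genus01 unus", "Genus01", "Fam"),
        SpecimenRecord("B1", "T" * 100, "Genus02 duo", "Genus02", "Fam"),
    ]
    lib = BarcodeLibrary(records=recs)
    species = [s for s in summarize_ranks(build_matrix(lib), lib) if s.rank == "species"][0]
    assert species.n_pairs == 1  # only the conspecific A pair


def test_histogram_all_zero_matrix_first_bin():
    lib = _toy_library()
    hist = divergence_histogram(build_matrix(lib), lib, "species")
    assert hist.counts[0] == 1 and hist.counts.sum() == 1
    assert hist.fraction_below_1 == 1.0


def test_histogram_counts_sum_to_species(clean_library):
    library, _ = clean_library
    mat = build_matrix(library)
    hist = divergence_histogram(mat, library, "species")
    assert hist.counts.sum() == len(library.species_of())
    assert 0.0 <= hist.fraction_below_1 <= hist.fraction_below_2 <= 1.0


def test_species_summaries_well_separated_gap(clean_library):
    library, _ = clean_library
    mat = build_matrix(library)
    for summ in species_summaries(mat, library):
        assert summ.max_intra is not None
        assert summ.barcode_gap > 0
        assert summ.nn_distance >= 4.0  # percent; min_inter = 5% generating


def test_species_summaries_shared_haplotype():
    seq = "ACGT" * 30
    recs = [
        SpecimenRecord("A1", seq, "Genus01 unus", "Genus01", "Fam"),
        SpecimenRecord("A2", seq, "Genus01 unus", "Genus01", "Fam"),
        SpecimenRecord("B1", seq, "Genus02 duo", "Genus02", "Fam"),
        SpecimenRecord("B2", "T" + seq[1:], "Genus02 duo", "Genus02", "Fam"),
    ]
    lib = BarcodeLibrary(records=recs)
    summs = {s.morphospecies: s for s in species_summaries(build_matrix(lib), lib, min_specimens=2)}
    assert summs["Genus01 unus"].nn_distance == 0.0
    assert summs["Genus01 unus"].max_similarity == 100.0


def test_matrix_exports_round_trip(tmp_path):
    lib = _toy_library()
    recs = lib.records + [
        SpecimenRecord("X9", "TGCA" * 30, "Genus09 novem", "Genus09", "F")
    ]
    from motudelim.io import BarcodeLibrary as BL
    from motudelim import write_long_tsv, write_phylip

    lib2 = BL(records=recs)
    mat = build_matrix(lib2)
    write_phylip(mat, tmp_path / "m.phy")
    lines = (tmp_path / "m.phy").read_text().splitlines()
    assert lines[0].strip() == "4"
    assert len(lines) == 5
    write_long_tsv(mat, tmp_path / "m.tsv")
    rows = (tmp_path / "m.tsv").read_text().splitlines()
    assert len(rows) == 1 + 6  # header + upper triangle
    a, b, model, d, n = rows[1].split("\t")
    assert model == "K2P" and float(d) == pytest.approx(mat.get(a, b))


def test_mean_intra_matches_generator_expectation():
    # over replicate libraries, realized mean intraspecific K2P ~ expected
    expected = 0.005
    means = []
    for seed in range(12):
        lib, _ = simulate_library(
            SimConfig(n_species=4, specimens_per_species=5, seed=100 + seed)
        )
        mat = build_matrix(lib)
        intra = []
        for members in lib.species_of().values():
            idx = [mat.index(m) for m in members]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    intra.append(mat.values[idx[a], idx[b]])
        means.append(np.mean(intra))
    grand = np.mean(means)
    se = np.std(means, ddof=1) / math.sqrt(len(means))
    assert abs(grand - expected) < 3 * se + 1e-4
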
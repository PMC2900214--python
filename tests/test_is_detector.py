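import math

import numpy as np
import pytest
from Bio.Seq import Seq

import erosionscan as es
from erosionscan.is_detector import ISConfig, _orfs_in
from erosionscan.synthetic_data import make_is_consensus


def _random_seq(n, rng, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# TIRs
# ---------------------------------------------------------------------------

def test_planted_perfect_tir_found():
    rng = np.random.default_rng(0)
    cons = make_is_consensus(900, 20, 0.4, rng)
    tir = es.find_tirs(cons)
    assert tir is not None and tir.length >= 20


def test_tir_mismatch_tolerance():
    rng = np.random.default_rng(1)
    tir = _random_seq(20, rng)
    body = _random_seq(800, rng)
    rc = str(Seq(tir).reverse_complement())

    def mutate(s, positions):
        out = list(s)
        for p in positions:
            out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
        return "".join(out)

    elem2 = tir + body + mutate(rc, [5, 12])
    found = es.find_tirs(elem2)
    assert found is not None and found.length >= 10
    elem3 = tir + body + mutate(rc, [2, 5, 9, 13, 16])
    found3 = es.find_tirs(elem3)
    assert found3 is None or found3.length < 10 or found3.left_offset > 0


def test_poly_a_has_no_tir():
    assert es.find_tirs("A" * 500) is None


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def test_e_value_formula():
    cfg = ISConfig()
    raw = 100
    S = (cfg.karlin_lambda * raw - math.log(cfg.karlin_k)) / math.log(2)
    assert es.bit_score(raw) == pytest.approx(S)
    assert es.e_value(raw, 1_000_000, 10_000) == \
        pytest.approx(1_000_000 * 10_000 * 2 ** (-S))


def test_e_value_strictly_decreasing_in_score():
    evs = [es.e_value(raw, 1_000_000, 10_000) for raw in range(10, 200, 10)]
    assert all(a > b for a, b in zip(evs, evs[1:]))


# ---------------------------------------------------------------------------
# Homology scan
# ---------------------------------------------------------------------------

def test_verbatim_insert_is_found_with_tiny_evalue():
    rng = np.random.default_rng(2)
    insert = _random_seq(800, rng)
    genome = [es.GenomeRecord(
        "chr", _random_seq(30_000, rng) + insert + _random_seq(30_000, rng))]
    hits = es.scan_homology(genome, {"lib1": insert})
    assert hits
    best = min(hits, key=lambda h: h.e_value)
    assert best.e_value < 1e-50
    assert best.start <= 30_000 + 20 and best.end >= 30_000 + 780


def test_reverse_strand_insert_is_found():
    rng = np.random.default_rng(3)
    insert = _random_seq(800, rng)
    rc = str(Seq(insert).reverse_complement())
    genome = [es.GenomeRecord(
        "chr", _random_seq(20_000, rng) + rc + _random_seq(20_000, rng))]
    hits = es.scan_homology(genome, {"lib1": insert})
    assert any(h.strand == "-" and h.e_value < 1e-50 for h in hits)


def test_shuffled_library_gives_no_hits():
    rng = np.random.default_rng(4)
    genome = [es.GenomeRecord("chr", _random_seq(100_000, rng))]
    library = {"shuf": _random_seq(2_000, rng)}
    assert es.scan_homology(genome, library) == []


# ---------------------------------------------------------------------------
# Repeat families
# ---------------------------------------------------------------------------

def _plant_copies(rng, element, n, spacing=5_000):
    parts = []
    for _ in range(n):
        parts.append(_random_seq(spacing, rng))
        parts.append(element)
    parts.append(_random_seq(spacing, rng))
    return es.GenomeRecord("chr", "".join(parts))


def test_five_exact_copies_form_one_family():
    rng = np.random.default_rng(5)
    element = _random_seq(900, rng)
    genome = [_plant_copies(rng, element, 5)]
    fams = es.find_repeat_families(genome)
    assert len(fams) == 1
    assert len(fams[0].consensus) >= 600
    assert len(fams[0].copies) == 5


def test_short_repeat_is_below_length_floor():
    rng = np.random.default_rng(6)
    element = _random_seq(500, rng)
    genome = [_plant_copies(rng, element, 5)]
    assert es.find_repeat_families(genome) == []


def test_random_sequence_has_no_families():
    rng = np.random.default_rng(7)
    genome = [es.GenomeRecord("chr", _random_seq(200_000, rng))]
    assert es.find_repeat_families(genome) == []


# ---------------------------------------------------------------------------
# Fragment merging
# ---------------------------------------------------------------------------

def _hit(rid, s, e, lib_s, lib_e, fam="famA", strand="+"):
    return es.HomologyHit(rid, s, e, strand, fam, lib_s, lib_e,
                          raw_score=e - s, bits=100.0, e_value=1e-30)


def test_close_fragments_merge_into_one_site():
    hits = [_hit("chr", 1000, 1500, 0, 500),
            _hit("chr", 2000, 2600, 520, 1120)]
    remnants = es.merge_fragments(hits)
    assert len(remnants) == 1
    assert len(remnants[0].fragments) == 2
    assert (remnants[0].start, remnants[0].end) == (1000, 2600)


def test_distant_fragments_stay_separate():
    hits = [_hit("chr", 1000, 1500, 0, 500),
            _hit("chr", 6600, 7200, 520, 1120)]  # 5.1 kb gap > 3000
    assert len(es.merge_fragments(hits)) == 2


def test_incompatible_library_coordinates_not_merged():
    # second fragment re-covers the same library interval: two insertions
    hits = [_hit("chr", 1000, 1500, 0, 500),
            _hit("chr", 2000, 2500, 0, 500)]
    assert len(es.merge_fragments(hits)) == 2


def test_merge_is_idempotent(is_bundle):
    rem = is_bundle.remnants
    hits2 = [es.HomologyHit(r.replicon_id, s, e, r.strand, r.family_id,
                            ls, le, 100, 100.0, 1e-30)
             for r in rem for (s, e, ls, le) in r.fragments]
    rem2 = es.merge_fragments(hits2, is_bundle.families, is_bundle.cfg)
    assert [(r.replicon_id, r.start, r.end) for r in rem2] == \
           [(r.replicon_id, r.start, r.end) for r in rem]


def test_distinct_site_recall_on_synthetic(is_bundle):
    """>= 90% of planted insertions recovered; fragmented ones merged,
    never double-counted."""
    tsites = is_bundle.truth.by_kind("is_element")
    matched = 0
    for t in tsites:
        cover = [r for r in is_bundle.remnants
                 if r.replicon_id == t.replicon_id
                 and min(r.end, t.end) - max(r.start, t.start)
                 > 0.5 * (t.end - t.start)]
        assert len(cover) <= 1  # no double-counting
        matched += bool(cover)
    assert matched / len(tsites) >= 0.9
    assert len(is_bundle.remnants) <= len(tsites) + 1


def test_every_remnant_overlaps_evidence(is_bundle):
    for r in is_bundle.remnants:
        assert any(h.replicon_id == r.replicon_id
                   and min(h.end, r.end) - max(h.start, r.start) > 0
                   for h in is_bundle.hits)


# ---------------------------------------------------------------------------
# Transposase census
# ---------------------------------------------------------------------------

def test_orf_scan_finds_planted_orf():
    rng = np.random.default_rng(8)
    cons = make_is_consensus(900, 20, 0.4, rng)
    orfs = _orfs_in(cons)
    assert max(e - s for s, e in orfs) >= 0.8 * len(cons)


def test_census_statuses_match_truth(is_bundle):
    n_intact_truth = sum(1 for t in is_bundle.truth.by_kind("is_element")
                         if t.detail.get("mode") == "intact")
    n_intact = sum(1 for r in is_bundle.remnants
                   if r.status == "intact_transposase")
    assert n_intact == n_intact_truth
    assert is_bundle.n_long <= is_bundle.n_orfs


def test_internal_stop_element_is_fragmented():
    rng = np.random.default_rng(9)
    cons = make_is_consensus(900, 20, 0.4, rng)
    pieces, detail = es.plant_is_element(cons, 20, fragmented=True, rng=rng)
    while detail["mode"] != "internal_stop":
        pieces, detail = es.plant_is_element(cons, 20, fragmented=True, rng=rng)
    genome = [es.GenomeRecord("chr", _random_seq(5000, rng) + pieces[0]
                              + _random_seq(5000, rng))]
    rem = [es.ISRemnant("s0", "chr", 5000, 5000 + len(pieces[0]), "+", "famA",
                        fragments=[(5000, 5000 + len(pieces[0]), 0, 900)])]
    fam = [es.RepeatFamily("famA", cons)]
    n_orfs, n_long, _ = es.census_transposase_orfs(genome, rem, families=fam)
    assert rem[0].status == "fragmented"
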
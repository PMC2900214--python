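import itertools

import numpy as np
import pytest

import erosionscan as es
from erosionscan.pseudo_caller import (CallerConfig, ChainedAlignment,
                                       _candidate_region, _RefIndex,
                                       best_chain)
from erosionscan.synthetic_data import translate
from tests.conftest import event_of


def _gene(rng, n_codons=100):
    prot = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                    size=n_codons - 1))
    return es.back_translate(prot, 0.383, rng), prot


# ---------------------------------------------------------------------------
# three_frame_align
# ---------------------------------------------------------------------------

def test_self_alignment_single_clean_block():
    rng = np.random.default_rng(0)
    dna, prot = _gene(rng)  # 300 nt, 99 aa internal
    blocks = es.three_frame_align(dna, prot)
    frames = {b.frame for b in blocks}
    assert 0 in frames
    main = max(blocks, key=lambda b: b.score)
    assert main.frame == 0
    assert (main.ref_start, main.ref_end) == (0, len(prot))
    assert main.n_internal_stops == 0


def test_premature_stop_is_counted_not_terminal():
    rng = np.random.default_rng(0)
    dna, prot = _gene(rng)
    mut = dna[:150] + "TAA" + dna[153:]  # codon 50 -> stop
    blocks = es.three_frame_align(mut, prot)
    main = max(blocks, key=lambda b: b.score)
    assert main.n_internal_stops == 1
    assert main.ref_end - main.ref_start > 90  # block spans the stop


def test_single_deletion_yields_two_frames():
    rng = np.random.default_rng(0)
    dna, prot = _gene(rng)
    mut = dna[:150] + dna[151:]  # 1-bp deletion at codon 50
    blocks = es.three_frame_align(mut, prot)
    chain = es.chain_blocks(blocks, len(prot))
    assert chain.n_frameshifts == 1
    frames = [b.frame for b in chain.blocks]
    assert frames[0] == 0 and frames[-1] == 2
    assert chain.aligned_fraction > 0.9


def test_short_region_returns_no_blocks():
    assert es.three_frame_align("ATGGCTGCT", "MAA") == []


# ---------------------------------------------------------------------------
# chain_blocks
# ---------------------------------------------------------------------------

def _chain_oracle(blocks, scoring, region_tol=36, ref_tol=12):
    """Exhaustive enumeration of all collinear block subsets with the same
    scoring contract as the chain DP."""
    best = 0.0
    order = sorted(blocks, key=lambda b: (b.region_start, b.ref_start, b.frame))
    n = len(order)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            ok = True
            score = order[combo[0]].score
            for u, v in zip(combo, combo[1:]):
                a, b = order[u], order[v]
                if (b.region_start < a.region_end - region_tol
                        or b.ref_start < a.ref_end - ref_tol
                        or b.region_start <= a.region_start
                        or b.ref_start < a.ref_start):
                    ok = False
                    break
                score += b.score
                if a.frame != b.frame:
                    score += scoring.frameshift_penalty
                score -= 4.0 * max((a.region_end - b.region_start) / 3.0,
                                   float(a.ref_end - b.ref_start), 0.0)
            if ok and score > best:
                best = score
    return best


def test_chain_score_matches_exhaustive_oracle():
    """Chain DP equals subset enumeration on small mutated genes."""
    rng = np.random.default_rng(8)
    scoring = es.ScoringScheme()
    n_checked = 0
    for case in range(20):
        dna, prot = _gene(rng, n_codons=rng.integers(60, 160))
        cls = ["internal_stop", "frameshift", "truncated"][case % 3]
        mut, _ = es.plant_pseudogene(dna, cls, rng)
        blocks = es.three_frame_align(mut, prot, scoring)
        if not 1 <= len(blocks) <= 8:
            continue
        chain = es.chain_blocks(blocks, len(prot), scoring)
        oracle = _chain_oracle(blocks, scoring)
        assert chain.score == pytest.approx(oracle, abs=1e-9)
        n_checked += 1
    assert n_checked >= 10


def test_single_full_block_chain():
    b = es.AlignmentBlock(0, 0, 300, 0, 100, 500.0, 0)
    chain = es.chain_blocks([b], 100)
    assert chain.n_frameshifts == 0
    assert chain.aligned_fraction == 1.0


def test_two_frame_chain_counts_one_frameshift():
    b1 = es.AlignmentBlock(0, 0, 150, 0, 50, 250.0, 0)
    b2 = es.AlignmentBlock(2, 152, 300, 50, 99, 240.0, 0)
    chain = es.chain_blocks([b1, b2], 100)
    assert chain.n_frameshifts == 1
    assert len(chain.blocks) == 2


def test_empty_block_list_gives_empty_chain():
    chain = es.chain_blocks([], 100)
    assert chain.is_empty and chain.aligned_fraction == 0.0


# ---------------------------------------------------------------------------
# classify_candidate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_stops,n_fs,fraction,expected", [
    (0, 0, 1.00, "intact"),
    (2, 0, 0.95, "internal_stop"),
    (0, 2, 0.95, "frameshift"),
    (1, 1, 0.95, "frameshift"),
    (0, 0, 0.25, "truncated"),
    (1, 0, 0.90, "intact"),   # one interruption tolerated by default
    (0, 1, 0.90, "intact"),
])
def test_calling_rules(n_stops, n_fs, fraction, expected):
    chain = ChainedAlignment(
        blocks=[es.AlignmentBlock(0, 0, 30, 0, 10, 50.0, n_stops)],
        ref_protein_id="r", score=50.0, n_frameshifts=n_fs, n_stops=n_stops,
        aligned_fraction=fraction)
    verdict = es.classify_candidate(chain)
    if expected == "intact":
        assert verdict == "intact"
    else:
        assert verdict.pg_class == expected


def test_no_homolog_is_intact_by_rule():
    assert es.classify_candidate(ChainedAlignment()) == "intact"


def test_truncation_boundary_29_vs_31(ref_proteome):
    """Kept fraction 0.29 -> truncated; 0.31 -> intact, at threshold 0.30."""
    rng = np.random.default_rng(12)
    dna, prot = _gene(rng, n_codons=200)
    for kept, expect_trunc in ((0.29, True), (0.31, False)):
        mut, _ = es.plant_pseudogene(dna, "truncated", rng, kept_fraction=kept)
        blocks = es.three_frame_align(mut, prot)
        chain = es.chain_blocks(blocks, len(prot), ref_protein_id="r")
        verdict = es.classify_candidate(chain)
        if expect_trunc:
            assert verdict.pg_class == "truncated"
        else:
            assert verdict == "intact"


def test_threshold_monotonicity(called_bundle):
    """Raising the interruption threshold never increases calls; lowering
    the truncation fraction never increases truncated calls."""
    g, f, p = called_bundle.genome, called_bundle.features, called_bundle.proteome
    n_prev = None
    for thr in (2, 3, 4):
        _, calls = es.call_pseudogenes(g, f, p,
                                       CallerConfig(interruption_threshold=thr))
        if n_prev is not None:
            assert len(calls) <= n_prev
        n_prev = len(calls)
    n_trunc_prev = None
    for frac in (0.30, 0.20, 0.10):
        _, calls = es.call_pseudogenes(g, f, p,
                                       CallerConfig(truncation_fraction=frac))
        n_trunc = sum(1 for c in calls if c.pg_class == "truncated")
        if n_trunc_prev is not None:
            assert n_trunc <= n_trunc_prev
        n_trunc_prev = n_trunc


# ---------------------------------------------------------------------------
# whole-annotation calling
# ---------------------------------------------------------------------------

def test_recovery_against_truth(called_bundle):
    """>= 95% of planted pseudogenes recovered, no intact gene miscalled."""
    truth_pg = {r.event_id for r in called_bundle.truth.by_kind("pseudogene")}
    called_events = {event_of(c.feature_id) for c in called_bundle.calls}
    tp = called_events & truth_pg
    fp = called_events - truth_pg
    n_intact = len(called_bundle.truth.by_kind("intact_gene"))
    assert len(tp) / len(truth_pg) >= 0.95
    assert len(fp) / n_intact <= 0.01


def test_split_events_grouped(called_bundle):
    """Both halves of every recovered split gene share one event id."""
    split_truth = [r for r in called_bundle.truth.by_kind("pseudogene")
                   if r.pg_class == "split"]
    assert split_truth
    calls_by_fid = {c.feature_id: c for c in called_bundle.calls}
    for r in split_truth:
        ids = r.detail["fragment_ids"]
        got = [calls_by_fid.get(fid) for fid in ids]
        assert all(g is not None and g.pg_class == "split" for g in got)
        assert len({g.event_id for g in got}) == 1


def test_calling_is_deterministic(synth_bundle):
    g, f, p = synth_bundle.genome, synth_bundle.features, synth_bundle.proteome
    _, c1 = es.call_pseudogenes(g, f, p)
    _, c2 = es.call_pseudogenes(g, f, p)
    assert [(c.feature_id, c.pg_class, c.n_stops, c.n_frameshifts)
            for c in c1] == \
           [(c.feature_id, c.pg_class, c.n_stops, c.n_frameshifts)
            for c in c2]


def test_all_intact_genome_yields_no_calls(ref_proteome):
    cfg = es.SynthConfig(seed=5, n_genes=20, pseudogene_fraction=0.0,
                         n_is_elements=0,
                         replicon_lengths=(40_000, 8_000, 6_000))
    genome, features, truth = es.generate_genome(cfg, ref_proteome)
    _, calls = es.call_pseudogenes(genome, features, ref_proteome)
    assert calls == []


def test_empty_reference_set_is_error(synth_bundle):
    with pytest.raises(ValueError):
        es.call_pseudogenes(synth_bundle.genome, synth_bundle.features, {})


def test_adjacent_paralogs_are_not_split(ref_proteome):
    """Two neighbours each covering most of the same reference: no split."""
    rng = np.random.default_rng(33)
    prot = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=119))
    refs = {"paralog": prot}
    dna1 = es.back_translate(prot, 0.4, rng)
    dna2 = es.back_translate(prot, 0.4, rng)
    spacer = "".join(rng.choice(list("ACGT"), size=200))
    other = es.back_translate(
        "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80)),
        0.4, rng)
    seq = spacer + dna1 + spacer + other + spacer + dna2 + spacer
    genome = [es.GenomeRecord("chr", seq)]
    s1 = len(spacer)
    s2 = s1 + len(dna1) + len(spacer)
    s3 = s2 + len(other) + len(spacer)
    features = es.FeatureSet([
        es.Feature("a", "chr", s1, s1 + len(dna1), "+", "CDS", "paralog"),
        es.Feature("x", "chr", s2, s2 + len(other), "+", "CDS", "other"),
        es.Feature("b", "chr", s3, s3 + len(dna2), "+", "CDS", "paralog"),
    ])
    refs["otherp"] = translate(other)[:-1]
    _, calls = es.call_pseudogenes(genome, features, refs)
    assert all(c.pg_class != "split" for c in calls)
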
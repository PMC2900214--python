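"""Rule-based pseudogene calling via frameshift-aware translated alignment.

A candidate coding region is compared against its best reference protein by
aligning all three forward-strand reading frames locally (BLOSUM62-style
scoring; premature stop codons are scored as strong mismatches but never
terminate a block) and chaining collinear blocks across frames.  Each frame
change along the chain is one frameshift; stop codons inside aligned blocks
are premature stops.  A region is called a pseudogene when

* premature stops + frameshifts reach the interruption threshold
  (default 2, i.e. "more than one"), or
* the chain covers less than the truncation fraction (default 30%) of the
  full-length reference protein, or
* the region is one of two fragments hitting disjoint parts of the same
  reference with another ORF in between (the ORF-split rule).

Otherwise it is intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_io import Feature, FeatureSet, GenomeRecord

__all__ = [
    "ScoringScheme", "CallerConfig", "AlignmentBlock", "ChainedAlignment",
    "PseudogeneCall", "three_frame_align", "chain_blocks",
    "classify_candidate", "detect_split_orf", "call_pseudogenes", "best_chain",
]


@dataclass
class ScoringScheme:
    """Protein-level scoring for the three-frame aligner."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    frameshift_penalty: float = -15.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.frameshift_penalty >= 0:
            raise ValueError("frameshift_penalty must be negative")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class CallerConfig:
    """Thresholds of the calling rules.

    ``interruption_threshold`` is the minimum number of premature stops plus
    frameshifts ("more than one" = 2).  ``truncation_fraction`` is the
    minimum covered fraction of the full-length reference below which a
    region is a truncation pseudogene.
    """

    interruption_threshold: int = 2
    truncation_fraction: float = 0.30
    min_block_score: float = 40.0
    split_max_gap: int = 5000
    split_max_ref_overlap: float = 0.20
    genetic_code: int = 11
    region_flank: int = 90          # candidate region extension, nt per side
    n_candidate_refs: int = 3       # k-mer prefilter depth
    kmer: int = 5                   # protein k-mer for reference prefilter

    def __post_init__(self) -> None:
        if not (0 < self.truncation_fraction < 1):
            raise ValueError("truncation_fraction must be in (0, 1)")
        if self.interruption_threshold < 1:
            raise ValueError("interruption_threshold must be >= 1")


@dataclass
class AlignmentBlock:
    frame: int            # 0, 1 or 2 relative to region start, feature strand
    region_start: int     # nt offsets within the candidate region
    region_end: int
    ref_start: int        # aa offsets in the reference protein
    ref_end: int
    score: float
    n_internal_stops: int


@dataclass
class ChainedAlignment:
    blocks: list[AlignmentBlock] = field(default_factory=list)
    ref_protein_id: str = ""
    score: float = 0.0
    n_frameshifts: int = 0
    n_stops: int = 0
    aligned_fraction: float = 0.0

    @property
    def is_empty(self) -> bool:
        return not self.blocks


@dataclass
class PseudogeneCall:
    feature_id: str
    pg_class: str          # internal_stop | frameshift | split | truncated
    n_stops: int
    n_frameshifts: int
    aligned_fraction: float
    ref_protein_id: str
    evidence_note: str = ""
    event_id: str = ""


def _translate_frame(dna: str, frame: int) -> str:
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=11))


def _decompose_alignment(aln, aa: str, ref: str, frame: int, qoff: int,
                         scoring: "ScoringScheme", min_score: float,
                         xdrop: float = 25.0) -> list[AlignmentBlock]:
    """Segment one local alignment into high-scoring sub-blocks.

    A local aligner with cheap gap extension happily bridges two strong
    matches across a stretch of out-of-frame garbage; here the alignment
    columns are re-scored and cut wherever the running score falls to zero
    or drops by more than ``xdrop`` from its running maximum — the standard
    HSP decomposition.  Each surviving segment becomes one block.
    """
    matrix = scoring.matrix
    qranges, rranges = aln.aligned
    cols: list[tuple] = []  # ("pair", q, r) | ("gap", length)
    prev_q, prev_r = int(qranges[0][0]), int(rranges[0][0])
    for (qs, qe), (rs, re) in zip(qranges, rranges):
        qs, qe, rs, re = int(qs), int(qe), int(rs), int(re)
        for gap in (qs - prev_q, rs - prev_r):
            if gap > 0:
                cols.append(("gap", gap))
        for i in range(qe - qs):
            cols.append(("pair", qs + i, rs + i))
        prev_q, prev_r = qe, re

    def col_score(c) -> float:
        if c[0] == "gap":
            return scoring.gap_open + scoring.gap_extend * (c[1] - 1)
        return float(matrix[aa[c[1]], ref[c[2]]])

    # cut runs whose local identity collapses: a stretch of out-of-frame
    # translation scores near zero under a log-odds matrix (random pairs
    # average only about -0.5), so a score drop alone cannot separate it
    # from genuine homology; windowed identity can
    import numpy as _np
    ident = _np.array([1.0 if c[0] == "pair" and aa[c[1]] == ref[c[2]] else 0.0
                       for c in cols])
    w = 11
    if len(ident) >= w:
        kernel = _np.ones(w) / w
        smooth = _np.convolve(ident, kernel, mode="same")
        # edges of the convolution underestimate; renormalize
        norm = _np.convolve(_np.ones_like(ident), kernel, mode="same")
        smooth = smooth / norm
        good = smooth >= 0.30
    else:
        good = _np.ones(len(ident), dtype=bool)
    # a long gap also separates blocks; chaining rejoins same-frame
    # neighbours at no cost, so cutting here is free for true homology
    for i, c in enumerate(cols):
        if c[0] == "gap" and c[1] >= 4:
            good[i] = False

    pieces: list[tuple[int, int]] = []
    i = 0
    while i < len(cols):
        if not good[i]:
            i += 1
            continue
        j = i
        while j < len(cols) and good[j]:
            j += 1
        pieces.append((i, j - 1))
        i = j

    segments: list[tuple[int, int]] = []
    for ps, pe in pieces:
        start, cum, maxcum, maxpos = ps, 0.0, 0.0, ps - 1
        for i in range(ps, pe + 1):
            cum += col_score(cols[i])
            if cum > maxcum:
                maxcum, maxpos = cum, i
            if cum <= 0 or cum < maxcum - xdrop:
                if maxpos >= start:
                    segments.append((start, maxpos))
                start, cum, maxcum, maxpos = i + 1, 0.0, 0.0, i
        if maxpos >= start:
            segments.append((start, maxpos))

    blocks = []
    for s, e in segments:
        # trim ragged ends: a block must start and end on a run of >= 3
        # consecutive exact matches, else scattered chance matches drag the
        # boundary into neighbouring non-homologous sequence
        run = 0
        first_anchor = last_anchor = None
        for i in range(s, e + 1):
            c = cols[i]
            if c[0] == "pair" and aa[c[1]] == ref[c[2]]:
                run += 1
                if run >= 3:
                    if first_anchor is None:
                        first_anchor = i - 2
                    last_anchor = i
            else:
                run = 0
        if first_anchor is not None:
            s, e = first_anchor, last_anchor
        pairs = [c for c in cols[s: e + 1] if c[0] == "pair"]
        if not pairs:
            continue
        score = sum(col_score(c) for c in cols[s: e + 1])
        if score < min_score:
            continue
        qstart, qend = pairs[0][1], pairs[-1][1] + 1
        rstart, rend = pairs[0][2], pairs[-1][2] + 1
        n_stops = sum(1 for c in pairs if aa[c[1]] == "*")
        blocks.append(AlignmentBlock(
            frame=frame,
            region_start=3 * (qoff + qstart) + frame,
            region_end=3 * (qoff + qend) + frame,
            ref_start=rstart,
            ref_end=rend,
            score=float(score),
            n_internal_stops=n_stops,
        ))
    return blocks


def _find_blocks(aa: str, ref: str, frame: int, aligner: Align.PairwiseAligner,
                 scoring: "ScoringScheme", min_score: float,
                 qoff: int = 0, depth: int = 0) -> list[AlignmentBlock]:
    """Greedy recursive extraction of non-overlapping local alignments of one
    translated frame against the full reference."""
    if depth > 6 or len(aa) < 5 or not ref:
        return []
    try:
        alignments = aligner.align(aa, ref)
        if len(alignments) == 0:
            return []
        aln = alignments[0]
    except (ValueError, OverflowError):
        return []
    if aln.score < min_score:
        return []
    qranges, _rranges = aln.aligned
    qstart, qend = int(qranges[0][0]), int(qranges[-1][1])
    out = _decompose_alignment(aln, aa, ref, frame, qoff, scoring, min_score)
    out += _find_blocks(aa[:qstart], ref, frame, aligner, scoring, min_score,
                        qoff, depth + 1)
    out += _find_blocks(aa[qend:], ref, frame, aligner, scoring, min_score,
                        qoff + qend, depth + 1)
    return out


def three_frame_align(region_dna: str, ref_protein: str,
                      scoring: Optional[ScoringScheme] = None,
                      min_block_score: float = 40.0) -> list[AlignmentBlock]:
    """Local alignment blocks of the three forward frames of a region
    against one reference protein.

    Regions shorter than 30 nt carry no evidence and yield no blocks.
    Premature stops within a block are counted, not block-terminating.
    """
    if len(region_dna) < 30:
        return []
    scoring = scoring or ScoringScheme()
    aligner = scoring.make_aligner()
    blocks: list[AlignmentBlock] = []
    for frame in (0, 1, 2):
        aa = _translate_frame(region_dna, frame)
        blocks += _find_blocks(aa, ref_protein, frame, aligner, scoring,
                               min_block_score)
    blocks.sort(key=lambda b: (b.region_start, b.ref_start, b.frame))
    return blocks


def chain_blocks(blocks: Sequence[AlignmentBlock], ref_len: int,
                 scoring: Optional[ScoringScheme] = None,
                 ref_protein_id: str = "",
                 region_overlap_tol: int = 36,
                 ref_overlap_tol: int = 12) -> ChainedAlignment:
    """Maximum-score chain of blocks collinear in region and reference.

    Consecutive chained blocks in different frames are charged the
    frameshift penalty; small boundary overlaps (alignment fuzz around an
    indel) are tolerated but charged so that clean junctions win.
    """
    scoring = scoring or ScoringScheme()
    if not blocks:
        return ChainedAlignment(ref_protein_id=ref_protein_id)
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    bl = sorted(blocks, key=lambda b: (b.region_start, b.ref_start, b.frame))
    n = len(bl)
    best = [b.score for b in bl]
    prev: list[Optional[int]] = [None] * n
    for i in range(n):
        for j in range(i):
            a, b = bl[j], bl[i]
            if b.region_start < a.region_end - region_overlap_tol:
                continue
            if b.ref_start < a.ref_end - ref_overlap_tol:
                continue
            if b.region_start <= a.region_start or b.ref_start < a.ref_start:
                continue
            penalty = scoring.frameshift_penalty if a.frame != b.frame else 0.0
            overlap_aa = max((a.region_end - b.region_start) / 3.0,
                             float(a.ref_end - b.ref_start), 0.0)
            penalty -= 4.0 * overlap_aa
            cand = best[j] + b.score + penalty
            if cand > best[i]:
                best[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -bl[i].region_start))
    chain_idx = []
    k: Optional[int] = end
    while k is not None:
        chain_idx.append(k)
        k = prev[k]
    chain = [bl[i] for i in reversed(chain_idx)]

    n_frameshifts = sum(1 for a, b in zip(chain, chain[1:]) if a.frame != b.frame)
    n_stops = sum(b.n_internal_stops for b in chain)
    covered = 0
    last_end = 0
    for b in chain:
        covered += max(0, b.ref_end - max(b.ref_start, last_end))
        last_end = max(last_end, b.ref_end)
    return ChainedAlignment(
        blocks=chain,
        ref_protein_id=ref_protein_id,
        score=float(best[end]),
        n_frameshifts=n_frameshifts,
        n_stops=n_stops,
        aligned_fraction=min(1.0, covered / ref_len),
    )


def classify_candidate(chain: ChainedAlignment, cfg: Optional[CallerConfig] = None,
                       feature_id: str = "") -> PseudogeneCall | str:
    """Apply the calling rules to one chained alignment.

    Returns a PseudogeneCall, or the string ``"intact"``.  An empty chain
    (no homolog found) is intact by this rule; callers flag it as
    ``no_evidence``.
    """
    cfg = cfg or CallerConfig()
    if chain.is_empty:
        return "intact"
    interruptions = chain.n_stops + chain.n_frameshifts
    if interruptions >= cfg.interruption_threshold:
        pg_class = ("internal_stop" if chain.n_stops > chain.n_frameshifts
                    else "frameshift")
        note = (f"{chain.n_stops} premature stop(s) + "
                f"{chain.n_frameshifts} frameshift(s)")
        return PseudogeneCall(feature_id, pg_class, chain.n_stops,
                              chain.n_frameshifts, chain.aligned_fraction,
                              chain.ref_protein_id, note)
    if chain.aligned_fraction < cfg.truncation_fraction:
        note = (f"covers {chain.aligned_fraction:.2f} "
                f"< {cfg.truncation_fraction:.2f} of reference")
        return PseudogeneCall(feature_id, "truncated", chain.n_stops,
                              chain.n_frameshifts, chain.aligned_fraction,
                              chain.ref_protein_id, note)
    return "intact"


# ---------------------------------------------------------------------------
# Whole-annotation calling
# ---------------------------------------------------------------------------

def _protein_kmers(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


class _RefIndex:
    """k-mer prefilter over the reference proteome."""

    def __init__(self, ref_proteins: dict[str, str], k: int) -> None:
        self.k = k
        self.ref_proteins = ref_proteins
        self.kmer_to_refs: dict[str, list[str]] = {}
        for rid, seq in ref_proteins.items():
            for km in _protein_kmers(seq, k):
                self.kmer_to_refs.setdefault(km, []).append(rid)

    def candidates(self, region_dna: str, top: int) -> list[str]:
        counts: dict[str, int] = {}
        for frame in (0, 1, 2):
            aa = _translate_frame(region_dna, frame)
            for seg in aa.split("*"):
                for km in _protein_kmers(seg, self.k):
                    for rid in self.kmer_to_refs.get(km, ()):
                        counts[rid] = counts.get(rid, 0) + 1
        ranked = sorted(counts, key=lambda r: (-counts[r], r))
        return ranked[:top]


def _candidate_region(feature: Feature, genome: dict[str, GenomeRecord],
                      flank: int) -> str:
    """Feature interval extended by `flank` nt each side, on its strand, so
    truncation is measured against evidence rather than annotation edges."""
    rec = genome[feature.replicon_id]
    s = max(0, feature.start - flank)
    e = min(len(rec), feature.end + flank)
    sub = rec.sequence[s:e]
    if feature.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def best_chain(region_dna: str, ref_proteins: dict[str, str],
               index: Optional[_RefIndex] = None,
               scoring: Optional[ScoringScheme] = None,
               cfg: Optional[CallerConfig] = None) -> ChainedAlignment:
    """Best-scoring chain over candidate references for one region.

    Ties break toward the longer reference, then lexicographic id.
    """
    cfg = cfg or CallerConfig()
    scoring = scoring or ScoringScheme()
    index = index or _RefIndex(ref_proteins, cfg.kmer)
    best: Optional[ChainedAlignment] = None
    for rid in index.candidates(region_dna, cfg.n_candidate_refs):
        ref = ref_proteins[rid]
        blocks = three_frame_align(region_dna, ref, scoring, cfg.min_block_score)
        chain = chain_blocks(blocks, len(ref), scoring, ref_protein_id=rid)
        if best is None:
            best = chain
            continue
        key = (chain.score, len(ref), )
        bkey = (best.score, len(ref_proteins.get(best.ref_protein_id, "")))
        if key > bkey or (key == bkey and rid < best.ref_protein_id):
            best = chain
    return best if best is not None else ChainedAlignment()


def detect_split_orf(features: FeatureSet,
                     chains: dict[str, ChainedAlignment],
                     cfg: Optional[CallerConfig] = None) -> list[PseudogeneCall]:
    """Pair features whose best hits are disjoint segments of one reference.

    Two same-strand features on one replicon, within ``split_max_gap`` of
    each other, whose best reference is the same protein hit on
    near-disjoint segments in genome-consistent order, with at least one
    intervening annotated ORF of a different product, are both flagged as
    one split-pseudogene event.
    """
    cfg = cfg or CallerConfig()
    calls: list[PseudogeneCall] = []
    by_ref: dict[str, list[Feature]] = {}
    for f in features.of_type("CDS", "pseudogene"):
        ch = chains.get(f.feature_id)
        if ch is None or ch.is_empty:
            continue
        by_ref.setdefault(ch.ref_protein_id, []).append(f)

    ordered = list(features)
    pos_in_order = {f.feature_id: i for i, f in enumerate(ordered)}
    event_no = 0
    for rid, flist in sorted(by_ref.items()):
        if len(flist) < 2:
            continue
        flist = sorted(flist, key=lambda f: (f.replicon_id, f.start))
        for i in range(len(flist)):
            for j in range(i + 1, len(flist)):
                a, b = flist[i], flist[j]
                if a.replicon_id != b.replicon_id or a.strand != b.strand:
                    continue
                gap = b.start - a.end
                if gap < 0 or gap > cfg.split_max_gap:
                    continue
                ca, cb = chains[a.feature_id], chains[b.feature_id]
                seg_a = (ca.blocks[0].ref_start, ca.blocks[-1].ref_end)
                seg_b = (cb.blocks[0].ref_start, cb.blocks[-1].ref_end)
                overlap = min(seg_a[1], seg_b[1]) - max(seg_a[0], seg_b[0])
                shorter = min(seg_a[1] - seg_a[0], seg_b[1] - seg_b[0])
                if shorter <= 0 or overlap >= cfg.split_max_ref_overlap * shorter:
                    continue
                # genome order must match reference order on the strand
                if a.strand == "+":
                    if not seg_a[0] < seg_b[0]:
                        continue
                else:
                    if not seg_b[0] < seg_a[0]:
                        continue
                # at least one intervening ORF with a different product
                lo, hi = pos_in_order[a.feature_id], pos_in_order[b.feature_id]
                intervening = [g for g in ordered[lo + 1: hi]
                               if g.ftype in ("CDS", "pseudogene")
                               and g.start >= a.end and g.end <= b.start
                               and g.product != a.product]
                if not intervening:
                    continue
                event_no += 1
                eid = f"split_{event_no:04d}"
                for f, ch in ((a, ca), (b, cb)):
                    calls.append(PseudogeneCall(
                        f.feature_id, "split", ch.n_stops, ch.n_frameshifts,
                        ch.aligned_fraction, rid,
                        f"fragment of {rid} (event {eid})", event_id=eid))
    return calls


def call_pseudogenes(genome: list[GenomeRecord], features: FeatureSet,
                     ref_proteins: dict[str, str],
                     cfg: Optional[CallerConfig] = None,
                     scoring: Optional[ScoringScheme] = None
                     ) -> tuple[FeatureSet, list[PseudogeneCall]]:
    """Classify every CDS feature as intact or pseudogene.

    Returns an updated FeatureSet (ftype ``pseudogene`` where called, with
    evidence attributes) and the list of calls.  Deterministic for fixed
    inputs.
    """
    cfg = cfg or CallerConfig()
    scoring = scoring or ScoringScheme()
    if not ref_proteins:
        raise ValueError("reference protein set is empty")
    gmap = {g.replicon_id: g for g in genome}
    index = _RefIndex(ref_proteins, cfg.kmer)

    chains: dict[str, ChainedAlignment] = {}
    calls: dict[str, PseudogeneCall] = {}
    no_evidence: set[str] = set()
    for f in features.of_type("CDS"):
        region = _candidate_region(f, gmap, cfg.region_flank)
        chain = best_chain(region, ref_proteins, index, scoring, cfg)
        chains[f.feature_id] = chain
        verdict = classify_candidate(chain, cfg, feature_id=f.feature_id)
        if isinstance(verdict, PseudogeneCall):
            calls[f.feature_id] = verdict
        elif chain.is_empty:
            no_evidence.add(f.feature_id)

    for sc in detect_split_orf(features, chains, cfg):
        calls[sc.feature_id] = sc  # split grouping wins over per-half verdicts

    out = FeatureSet()
    for f in features:
        if f.feature_id in calls:
            c = calls[f.feature_id]
            attrs = dict(f.attrs)
            attrs.update({
                "pseudo_class": c.pg_class,
                "n_stops": c.n_stops,
                "n_frameshifts": c.n_frameshifts,
                "aligned_fraction": f"{c.aligned_fraction:.4f}",
                "ref_protein": c.ref_protein_id,
            })
            if c.event_id:
                attrs["split_event"] = c.event_id
            out.add(Feature(f.feature_id, f.replicon_id, f.start, f.end,
                            f.strand, "pseudogene", f.product,
                            f.cog_category, attrs))
        else:
            attrs = dict(f.attrs)
            if f.feature_id in no_evidence:
                attrs["no_evidence"] = "true"
            out.add(Feature(f.feature_id, f.replicon_id, f.start, f.end,
                            f.strand, f.ftype, f.product, f.cog_category, attrs))
    return out, sorted(calls.values(), key=lambda c: c.feature_id)
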
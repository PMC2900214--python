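"""Detection of insertion-sequence remnants.

Four stages, mirroring how IS remains are found in eroding genomes:

1. de-novo repeat families: k-mer seeds occurring in >= ``min_copies``
   places are extended bidirectionally into a majority consensus while the
   copies agree at >= 80% identity; families shorter than ``min_repeat_len``
   (default 600 bp) are dropped;
2. terminal-inverted-repeat (TIR) search at element ends;
3. nucleotide homology of the genome against an IS library, with a seeded
   ungapped-extension aligner scored +1/-2 and Karlin-Altschul E-values
   (lambda = 1.33, K = 0.621); hits at E >= 1e-5 are discarded;
4. merging of co-familial fragments within ``merge_max_gap`` (default
   3000 bp, the IS length ceiling) into distinct insertion sites, plus a
   transposase ORF census over the merged sites.

E-values use fixed approximate Karlin-Altschul constants; they are
comparable within a run, not across tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .genome_io import GenomeRecord

__all__ = [
    "ISConfig", "RepeatFamily", "HomologyHit", "ISRemnant", "TIR",
    "find_repeat_families", "find_tirs", "scan_homology",
    "merge_fragments", "census_transposase_orfs", "bit_score", "e_value",
]

_LN2 = math.log(2.0)
STOPS = ("TAA", "TAG", "TGA")
STARTS = ("ATG", "GTG", "TTG")


@dataclass
class ISConfig:
    min_repeat_len: int = 600
    min_copies: int = 3
    k: int = 16                    # repeat seeding k-mer
    seed_k: int = 11               # homology seeding k-mer
    e_value_max: float = 1e-5
    merge_max_gap: int = 3000
    tir_min_len: int = 10
    tir_max_offset: int = 50
    tir_max_mismatch: int = 2
    transposase_min_aa: int = 200
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 1.33
    karlin_k: float = 0.621
    xdrop: int = 20

    def __post_init__(self) -> None:
        for name in ("min_repeat_len", "min_copies", "k", "seed_k",
                     "merge_max_gap", "tir_min_len", "tir_max_offset",
                     "transposase_min_aa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TIR:
    length: int
    left_seq: str
    right_seq: str
    left_offset: int
    right_offset: int
    mismatches: int


@dataclass
class RepeatFamily:
    family_id: str
    consensus: str
    copies: list[tuple] = field(default_factory=list)  # (replicon, start, end, strand)
    tir: Optional[TIR] = None


@dataclass
class HomologyHit:
    replicon_id: str
    start: int
    end: int
    strand: str
    library_seq_id: str
    lib_start: int
    lib_end: int
    raw_score: int
    bits: float
    e_value: float


@dataclass
class ISRemnant:
    site_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    family_id: str
    fragments: list[tuple] = field(default_factory=list)  # (start, end, lib_start, lib_end)
    status: str = "fragmented"    # intact_transposase | fragmented
    tir_found: bool = False


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def bit_score(raw: int, cfg: Optional[ISConfig] = None) -> float:
    cfg = cfg or ISConfig()
    return (cfg.karlin_lambda * raw - math.log(cfg.karlin_k)) / _LN2


def e_value(raw: int, m: int, n: int, cfg: Optional[ISConfig] = None) -> float:
    """Karlin-Altschul expectation for a raw score: E = m * n * 2^-S."""
    cfg = cfg or ISConfig()
    return m * n * math.pow(2.0, -bit_score(raw, cfg))


# ---------------------------------------------------------------------------
# De-novo repeat families
# ---------------------------------------------------------------------------

def _doubled_views(genome: Sequence[GenomeRecord]) -> dict[str, str]:
    """Forward plus reverse-complement views, so every copy of a repeat is a
    forward occurrence somewhere."""
    out: dict[str, str] = {}
    for g in genome:
        out[g.replicon_id] = g.sequence
        out[g.replicon_id + "\x00rc"] = _revcomp(g.sequence)
    return out


def _map_back(view_id: str, s: int, e: int, view_len: int) -> tuple[str, int, int, str]:
    if view_id.endswith("\x00rc"):
        rid = view_id[: -len("\x00rc")]
        return rid, view_len - e, view_len - s, "-"
    return view_id, s, e, "+"


def _extend_family(views: dict[str, str], occs: list[tuple[str, int]], k: int,
                   min_copies: int, max_extend: int = 5000
                   ) -> tuple[str, list[tuple[str, int, int]]]:
    """Greedy bidirectional consensus extension from seed occurrences.

    A copy is dropped once its mismatch count exceeds 20% of the extended
    length; extension stops when fewer than ``min_copies`` copies survive.
    """
    state = [{"vid": v, "left": p, "right": p + k, "mm": 0, "alive": True}
             for v, p in occs]
    total_len = k
    window = 30  # recent-agreement window: stops extension at copy boundaries

    def column(side: int, recent: list[float]) -> bool:
        nonlocal total_len
        bases = []
        for st in state:
            if not st["alive"]:
                bases.append(None)
                continue
            seq = views[st["vid"]]
            pos = st["left"] - 1 if side < 0 else st["right"]
            if pos < 0 or pos >= len(seq):
                bases.append(None)
            else:
                bases.append(seq[pos])
        counts: dict[str, int] = {}
        for b in bases:
            if b is not None:
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            return False
        consensus = max(sorted(counts), key=lambda b: counts[b])
        n_alive = sum(1 for st in state if st["alive"])
        agree = counts.get(consensus, 0)
        recent.append(agree / n_alive if n_alive else 0.0)
        if len(recent) > window:
            recent.pop(0)
        if len(recent) == window and sum(recent) / window < 0.8:
            return False
        n_alive = 0
        for st, b in zip(state, bases):
            if not st["alive"]:
                continue
            if b is None:
                st["alive"] = False
                continue
            if b != consensus:
                st["mm"] += 1
            if st["mm"] > 0.2 * (total_len + 1):
                st["alive"] = False
                continue
            if side < 0:
                st["left"] -= 1
            else:
                st["right"] += 1
            n_alive += 1
        if n_alive < min_copies:
            # roll back the survivors' move for this failed column
            for st in state:
                if st["alive"]:
                    if side < 0:
                        st["left"] += 1
                    else:
                        st["right"] -= 1
            return False
        total_len += 1
        return True

    for side in (+1, -1):
        recent: list[float] = []
        steps = 0
        while steps < max_extend and column(side, recent):
            steps += 1
        # retract the low-agreement tail that accumulated before the
        # window tripped
        if len(recent) == window and sum(recent) / window < 0.8:
            bad = 0
            for frac in reversed(recent):
                if frac < 0.8:
                    bad += 1
                else:
                    break
            bad = min(bad, window)
            for st in state:
                if st["alive"]:
                    if side < 0:
                        st["left"] += bad
                    else:
                        st["right"] -= bad
            total_len -= bad

    alive = [st for st in state if st["alive"]]
    if len(alive) < min_copies:
        alive = [st for st in state][:min_copies]
    # consensus from the first surviving copy's span (copies are near-identical)
    ref = alive[0]
    consensus = views[ref["vid"]][ref["left"]: ref["right"]]
    spans = [(st["vid"], st["left"], st["right"]) for st in alive]
    return consensus, spans


def find_repeat_families(genome: Sequence[GenomeRecord],
                         cfg: Optional[ISConfig] = None) -> list[RepeatFamily]:
    """De-novo multi-copy repeat families of length >= ``min_repeat_len``."""
    cfg = cfg or ISConfig()
    views = _doubled_views(genome)
    k = cfg.k

    index: dict[str, list[tuple[str, int]]] = {}
    for vid, seq in views.items():
        for i in range(len(seq) - k + 1):
            km = seq[i: i + k]
            if "N" in km:
                continue
            index.setdefault(km, []).append((vid, i))

    seeds = sorted((km for km, v in index.items() if len(v) >= cfg.min_copies),
                   key=lambda km: (-len(index[km]), km))
    covered: dict[str, list[tuple[int, int]]] = {vid: [] for vid in views}

    def is_covered(vid: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in covered[vid])

    families: list[RepeatFamily] = []
    for km in seeds:
        occs = [(vid, p) for vid, p in index[km] if not is_covered(vid, p)]
        if len(occs) < cfg.min_copies:
            continue
        consensus, spans = _extend_family(views, occs, k, cfg.min_copies)
        if len(consensus) < cfg.min_repeat_len:
            continue
        fam = RepeatFamily(f"repfam_{len(families):03d}", consensus)
        for vid, s, e in spans:
            covered[vid].append((s, e))
            rid, fs, fe, strand = _map_back(vid, s, e, len(views[vid]))
            fam.copies.append((rid, fs, fe, strand))
        fam.tir = find_tirs(consensus, cfg)
        families.append(fam)

    # relocate copies genome-wide and deduplicate families found twice
    # (once forward, once as their own reverse complement)
    if families:
        lib = {f.family_id: f.consensus for f in families}
        hits = scan_homology(genome, lib, cfg)
        for f in families:
            f.copies = sorted({(h.replicon_id, h.start, h.end, h.strand)
                               for h in hits
                               if h.library_seq_id == f.family_id
                               and (h.end - h.start) >= 0.5 * len(f.consensus)})
        families.sort(key=lambda f: (-len(f.copies), -len(f.consensus),
                                     f.family_id))
        kept: list[RepeatFamily] = []
        for f in families:
            dup = False
            for g in kept:
                shared = sum(
                    1 for (r1, s1, e1, _) in f.copies
                    for (r2, s2, e2, _) in g.copies
                    if r1 == r2 and min(e1, e2) - max(s1, s2)
                    > 0.5 * min(e1 - s1, e2 - s2))
                if f.copies and shared >= 0.5 * len(f.copies):
                    dup = True
                    break
            if not dup:
                kept.append(f)
        families = [RepeatFamily(f"repfam_{i:03d}", f.consensus, f.copies, f.tir)
                    for i, f in enumerate(kept)]
    return families


# ---------------------------------------------------------------------------
# Terminal inverted repeats
# ---------------------------------------------------------------------------

def find_tirs(element: str, cfg: Optional[ISConfig] = None) -> Optional[TIR]:
    """Longest terminal-inverted-repeat pair of an element.

    The left copy must begin within ``tir_max_offset`` of the start, the
    right copy end within ``tir_max_offset`` of the end, and
    left == revcomp(right) up to ``tir_max_mismatch`` mismatches.  Ties
    break longest first, then outermost.
    """
    cfg = cfg or ISConfig()
    L = len(element)
    if L < 2 * cfg.tir_min_len:
        return None
    rc = _revcomp(element)
    best: Optional[TIR] = None
    max_len_cap = min(200, L // 2)
    for a in range(min(cfg.tir_max_offset, L) + 1):
        for b in range(min(cfg.tir_max_offset, L) + 1):
            # two-pointer walk: element[a + i] vs rc[b + i]
            mism = 0
            best_here = 0
            best_here_mism = 0
            i = 0
            while a + i < L - b and i < max_len_cap:
                if element[a + i] != rc[b + i]:
                    mism += 1
                    if mism > cfg.tir_max_mismatch:
                        break
                i += 1
                best_here = i
                best_here_mism = mism
            if best_here >= cfg.tir_min_len:
                cand = TIR(best_here,
                           element[a: a + best_here],
                           element[L - b - best_here: L - b],
                           a, b, best_here_mism)
                if (best is None or cand.length > best.length
                        or (cand.length == best.length
                            and cand.left_offset + cand.right_offset
                            < best.left_offset + best.right_offset)):
                    best = cand
    return best


# ---------------------------------------------------------------------------
# Homology scan
# ---------------------------------------------------------------------------

def _ungapped_extend(gseq: str, lseq: str, gpos: int, lpos: int, k: int,
                     cfg: ISConfig) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension around an exact k-mer seed.

    Returns (g_start, g_end, l_start, l_end, raw_score).
    """
    score = k * cfg.match
    # right
    best = score
    gi, li = gpos + k, lpos + k
    bg, bl = gi, li
    cur = score
    while gi < len(gseq) and li < len(lseq):
        cur += cfg.match if gseq[gi] == lseq[li] else cfg.mismatch
        gi += 1
        li += 1
        if cur > best:
            best, bg, bl = cur, gi, li
        if cur < best - cfg.xdrop:
            break
    g_end, l_end = bg, bl
    score = best
    # left
    best = score
    gi, li = gpos, lpos
    bg, bl = gi, li
    cur = score
    while gi > 0 and li > 0:
        gi -= 1
        li -= 1
        cur += cfg.match if gseq[gi] == lseq[li] else cfg.mismatch
        if cur > best:
            best, bg, bl = cur, gi, li
        if cur < best - cfg.xdrop:
            break
    return bg, g_end, bl, l_end, best


def scan_homology(genome: Sequence[GenomeRecord], library: dict[str, str],
                  cfg: Optional[ISConfig] = None) -> list[HomologyHit]:
    """Seeded ungapped-extension search of the genome against a nucleotide
    library, both strands, with E-value filtering.

    Neighbouring co-diagonal extensions separated by a small gap are merged
    with affine gap charges, approximating a gapped alignment.
    """
    cfg = cfg or ISConfig()
    if not library:
        raise ValueError("IS library is empty")
    k = cfg.seed_k
    m = sum(len(g.sequence) for g in genome)
    n = sum(len(s) for s in library.values())

    lib_index: dict[str, list[tuple[str, int]]] = {}
    for lid, seq in library.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i: i + k]
            if "N" not in km:
                lib_index.setdefault(km, []).append((lid, i))

    raw_hits: list[list] = []  # [lid, rid, strand, gs, ge, ls, le, raw]
    for g in genome:
        for strand in ("+", "-"):
            gseq = g.sequence if strand == "+" else _revcomp(g.sequence)
            seen_diag: dict[tuple[str, int], int] = {}
            for i in range(len(gseq) - k + 1):
                entries = lib_index.get(gseq[i: i + k])
                if not entries:
                    continue
                for lid, lpos in entries:
                    diag = i - lpos
                    if seen_diag.get((lid, diag), -1) > i:
                        continue
                    gs, ge, ls, le, raw = _ungapped_extend(
                        gseq, library[lid], i, lpos, k, cfg)
                    seen_diag[(lid, diag)] = ge
                    raw_hits.append([lid, g.replicon_id, strand,
                                     gs, ge, ls, le, raw])

    # merge co-diagonal neighbouring extensions (light gapped chaining)
    raw_hits.sort(key=lambda h: (h[0], h[1], h[2], h[3], h[4]))
    merged: list[list] = []
    for h in raw_hits:
        lid, rid, strand, gs, ge, ls, le, raw = h
        placed = False
        for mhit in reversed(merged[-20:]):
            mlid, mrid, mstrand, mgs, mge, mls, mle, mraw = mhit
            if (mlid, mrid, mstrand) != (lid, rid, strand):
                continue
            gap_g, gap_l = gs - mge, ls - mle
            if -k < gap_g <= 30 and -k < gap_l <= 30:
                if ge <= mge and le <= mle:   # contained: drop
                    placed = True
                    break
                gap = abs(gap_g - gap_l)
                penalty = (cfg.gap_open + cfg.gap_extend * max(gap - 1, 0)
                           if gap > 0 else 0)
                mhit[4] = max(mge, ge)
                mhit[6] = max(mle, le)
                mhit[7] = mraw + max(raw - k * cfg.match, 0) + penalty
                placed = True
                break
        if not placed:
            merged.append(list(h))

    hits: list[HomologyHit] = []
    gmap = {g.replicon_id: len(g.sequence) for g in genome}
    for lid, rid, strand, gs, ge, ls, le, raw in merged:
        ev = e_value(raw, m, n, cfg)
        if ev >= cfg.e_value_max:
            continue
        if strand == "-":
            L = gmap[rid]
            gs, ge = L - ge, L - gs
        hits.append(HomologyHit(rid, gs, ge, strand, lid, ls, le, raw,
                                bit_score(raw, cfg), ev))
    hits.sort(key=lambda h: (h.replicon_id, h.start, h.end, h.library_seq_id))
    return hits


# ---------------------------------------------------------------------------
# Fragment merging into distinct sites
# ---------------------------------------------------------------------------

def merge_fragments(hits: Sequence[HomologyHit],
                    families: Sequence[RepeatFamily] = (),
                    cfg: Optional[ISConfig] = None) -> list[ISRemnant]:
    """Merge co-familial fragments into distinct insertion sites.

    Fragments of one family on one replicon and strand are merged when the
    inter-fragment gap is <= ``merge_max_gap`` and their library coordinates
    are compatible (non-overlapping, ordered along the element).  The
    operation is idempotent.
    """
    cfg = cfg or ISConfig()
    frags: list[tuple[str, str, str, int, int, int, int]] = []
    for h in hits:
        frags.append((h.library_seq_id, h.replicon_id, h.strand,
                      h.start, h.end, h.lib_start, h.lib_end))
    # de-novo family copies fill loci the homology scan did not reach
    for f in families:
        for (rid, s, e, strand) in f.copies:
            if not any(fr[1] == rid
                       and min(fr[4], e) - max(fr[3], s) > 0.5 * (e - s)
                       for fr in frags):
                frags.append((f.family_id, rid, strand, s, e,
                              0, len(f.consensus)))

    # collapse overlapping fragments of the same family
    frags.sort()
    collapsed: list[list] = []
    for fr in frags:
        if collapsed:
            last = collapsed[-1]
            if (last[0], last[1], last[2]) == (fr[0], fr[1], fr[2]) \
                    and fr[3] <= last[4]:
                last[4] = max(last[4], fr[4])
                last[5] = min(last[5], fr[5])
                last[6] = max(last[6], fr[6])
                continue
        collapsed.append(list(fr))

    remnants: list[ISRemnant] = []
    current: Optional[list] = None  # [fam, rid, strand, fragments]
    def flush():
        nonlocal current
        if current is None:
            return
        fam, rid, strand, pieces = current
        start = min(p[0] for p in pieces)
        end = max(p[1] for p in pieces)
        remnants.append(ISRemnant(
            f"site_{len(remnants):04d}", rid, start, end, strand, fam,
            fragments=sorted(pieces)))
        current = None

    for fam, rid, strand, s, e, ls, le in collapsed:
        if current is not None:
            cfam, crid, cstrand, pieces = current
            prev = max(p[1] for p in pieces)
            lib_prev = pieces[-1][2:4]
            compatible = (
                cfam == fam and crid == rid and cstrand == strand
                and 0 <= s - prev <= cfg.merge_max_gap
                and ((strand == "+" and ls >= lib_prev[1] - 10)
                     or (strand == "-" and le <= lib_prev[0] + 10)))
            if compatible:
                pieces.append((s, e, ls, le))
                continue
            flush()
        current = [fam, rid, strand, [(s, e, ls, le)]]
    flush()

    # one genomic locus, one site: collapse remnants that overlap a kept
    # remnant (a library element and a de-novo family, or the two strand
    # readings of a near-palindromic element, describe the same insertion)
    remnants.sort(key=lambda r: (r.replicon_id, r.start,
                                 -(r.end - r.start), r.family_id))
    deduped: list[ISRemnant] = []
    for r in remnants:
        clash = None
        for q in deduped:
            if q.replicon_id != r.replicon_id:
                continue
            ov = min(q.end, r.end) - max(q.start, r.start)
            if ov > 0.5 * min(q.end - q.start, r.end - r.start):
                clash = q
                break
        if clash is None:
            deduped.append(r)
        elif (r.end - r.start) > (clash.end - clash.start):
            deduped[deduped.index(clash)] = r
    remnants = deduped

    # de-novo discovery can split one element into two families (e.g. when
    # some copies are themselves fragmented); families that sit adjacent
    # within the merge window at two or more independent loci are read as
    # parts of one element and their adjacent remnants unified
    pair_loci: dict[tuple[str, str], int] = {}
    remnants.sort(key=lambda r: (r.replicon_id, r.start))
    for a, b in zip(remnants, remnants[1:]):
        if (a.replicon_id == b.replicon_id and a.family_id != b.family_id
                and b.start > a.start and b.start - a.end <= cfg.merge_max_gap):
            key = tuple(sorted((a.family_id, b.family_id)))
            pair_loci[key] = pair_loci.get(key, 0) + 1
    linked = {pair for pair, n in pair_loci.items() if n >= 2}
    if linked:
        merged2: list[ISRemnant] = []
        for r in remnants:
            if merged2:
                p = merged2[-1]
                key = tuple(sorted((p.family_id, r.family_id)))
                if (p.replicon_id == r.replicon_id and r.start > p.start
                        and r.start - p.end <= cfg.merge_max_gap
                        and key in linked):
                    p.end = max(p.end, r.end)
                    p.fragments = sorted(p.fragments + r.fragments)
                    continue
            merged2.append(r)
        remnants = merged2

    for i, r in enumerate(remnants):
        r.site_id = f"site_{i:04d}"
    return remnants


# ---------------------------------------------------------------------------
# Transposase ORF census
# ---------------------------------------------------------------------------

def _orfs_in(seq: str, min_codons: int = 50) -> list[tuple[int, int]]:
    """(start, end) of start->stop ORFs >= min_codons codons, both strands,
    coordinates on the given sequence's forward orientation."""
    out = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            start: Optional[int] = None
            for i in range(frame, L - 2, 3):
                codon = s[i: i + 3]
                if start is None and codon in STARTS:
                    start = i
                elif start is not None and codon in STOPS:
                    if (i + 3 - start) // 3 >= min_codons:
                        if strand == "+":
                            out.append((start, i + 3))
                        else:
                            out.append((L - (i + 3), L - start))
                    start = None
    return out


def census_transposase_orfs(genome: Sequence[GenomeRecord],
                            remnants: Sequence[ISRemnant],
                            cfg: Optional[ISConfig] = None,
                            families: Sequence[RepeatFamily] = ()
                            ) -> tuple[int, int, list[dict]]:
    """Count transposase ORFs over merged insertion sites.

    Returns (n_orfs, n_long, per-remnant table); also sets each remnant's
    ``status``: intact_transposase when an ORF spans >= 80% of the family
    consensus (or of the site, if the family length is unknown).
    """
    cfg = cfg or ISConfig()
    gmap = {g.replicon_id: g.sequence for g in genome}
    fam_len = {f.family_id: len(f.consensus) for f in families}
    n_orfs = 0
    n_long = 0
    table = []
    for r in remnants:
        seq = gmap[r.replicon_id][r.start: r.end]
        orfs = _orfs_in(seq)
        ref_len = fam_len.get(r.family_id, r.end - r.start)
        longest = max((e - s for s, e in orfs), default=0)
        n_orfs += len(orfs)
        long_here = sum(1 for s, e in orfs
                        if (e - s) // 3 - 1 > cfg.transposase_min_aa)
        n_long += long_here
        r.status = ("intact_transposase" if longest >= 0.8 * ref_len
                    else "fragmented")
        r.tir_found = find_tirs(seq, cfg) is not None
        table.append({"site_id": r.site_id, "n_orfs": len(orfs),
                      "longest_orf_aa": max(0, longest // 3 - 1),
                      "n_long": long_here, "status": r.status,
                      "tir_found": r.tir_found})
    return n_orfs, n_long, table
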
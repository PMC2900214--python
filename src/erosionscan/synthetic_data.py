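"""Synthetic eroding genomes with planted, truth-tagged events.

The generator emulates the architecture of a multi-replicon cyanobacterial
endosymbiont genome in a reduced state: intact genes back-translated from a
reference proteome, pseudogenes of four classes (internal stop, frameshift,
ORF-split, truncation), insertion-sequence elements (700-3000 bp, terminal
inverted repeats, transposase ORF) both intact and fragmented, and per-gene
COG-category labels with a configurable skew of pseudogene odds across
categories.  Every planted event carries a TruthRecord so each downstream
detector can be scored exactly.

A single seeded numpy Generator drives all randomness; identical
(config, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import Feature, FeatureSet, GenomeRecord, write_fasta, write_gff

__all__ = [
    "SynthConfig", "TruthRecord", "TruthTable", "CapacityError",
    "random_proteome", "back_translate", "plant_pseudogene",
    "make_is_consensus", "plant_is_element", "generate_genome",
    "verify_truth", "write_synthetic",
]

COG_LETTERS = "BCDEFGHIJKLMNOPQRSTUV"
_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")

# aa -> list of codons (bacterial code, table 11)
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _BACTERIAL.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class CapacityError(ValueError):
    """A replicon is too short for the content requested of it."""


@dataclass
class SynthConfig:
    """Study conditions for one synthetic genome.

    Defaults mirror the eroding-endosymbiont regime: genome-wide GC 38.3%,
    31.2% of genes pseudogenized, IS elements 700-3000 bp with 20-bp TIRs.
    """

    n_replicons: int = 3
    replicon_lengths: tuple[int, ...] = (120_000, 20_000, 10_000)
    gc_target: float = 0.383
    n_genes: int = 100
    pseudogene_fraction: float = 0.312
    class_mix: dict = field(default_factory=lambda: {
        "internal_stop": 0.30, "frameshift": 0.30, "split": 0.20, "truncated": 0.20,
    })
    n_is_elements: int = 12
    n_is_families: int = 3
    is_length_range: tuple[int, int] = (700, 3000)
    tir_length: int = 20
    fragmented_is_fraction: float = 0.3
    n_rna_genes: int = 5
    cog_skew: dict = field(default_factory=lambda: {
        "L": 4.0, "Q": 2.0, "B": 2.0, "T": 1.5, "S": 1.5,
        "H": 0.4, "J": 0.3, "M": 0.5,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if len(self.replicon_lengths) != self.n_replicons:
            raise ValueError("replicon_lengths must have n_replicons entries")
        lo, hi = self.is_length_range
        if lo > hi:
            raise ValueError("is_length_range must be (low, high)")


@dataclass
class TruthRecord:
    event_id: str
    kind: str                     # intact_gene | pseudogene | is_element
    replicon_id: str
    start: int
    end: int
    strand: str
    pg_class: Optional[str] = None
    source_protein_id: Optional[str] = None
    cog_category: Optional[str] = None
    detail: dict = field(default_factory=dict)


class TruthTable:
    def __init__(self, records: Sequence[TruthRecord] = ()) -> None:
        self.records: list[TruthRecord] = list(records)
        self.is_families: dict[str, str] = {}  # family_id -> consensus

    def add(self, rec: TruthRecord) -> None:
        self.records.append(rec)

    def by_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def by_class(self, pg_class: str) -> list[TruthRecord]:
        return [r for r in self.records if r.pg_class == pg_class]

    def __len__(self) -> int:
        return len(self.records)


def _round_half_down(x: float) -> int:
    return math.ceil(x - 0.5)


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def random_spacer(length: int, gc: float, rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    bases = rng.choice(np.array(list("ACGT")), size=length, p=_base_probs(gc))
    return "".join(bases)


def _codon_weights(gc: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon weights: iid base probabilities at the GC target,
    conditioned on encoding the residue."""
    p = dict(zip("ACGT", _base_probs(gc)))
    out = {}
    for aa, codons in _AA_TO_CODONS.items():
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def random_proteome(n: int, rng: np.random.Generator,
                    length_range: tuple[int, int] = (80, 250)) -> dict[str, str]:
    """n random proteins (uniform residue usage, N-terminal Met)."""
    lo, hi = length_range
    out: dict[str, str] = {}
    aas = np.array(list(_AA20))
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(aas, size=L - 1))
        out[f"refprot_{i:04d}"] = "M" + body
    return out


def back_translate(protein: str, gc: float, rng: np.random.Generator,
                   weights: Optional[dict[str, np.ndarray]] = None) -> str:
    """DNA for a protein with codons sampled toward the GC target.

    The first Met becomes ATG; a GC-weighted stop codon is appended.
    """
    if weights is None:
        weights = _codon_weights(gc)
    codons = []
    for j, aa in enumerate(protein):
        if j == 0 and aa == "M":
            codons.append("ATG")
            continue
        cands = _AA_TO_CODONS[aa]
        codons.append(cands[int(rng.choice(len(cands), p=weights[aa]))])
    p = dict(zip("ACGT", _base_probs(gc)))
    sw = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in STOP_CODONS])
    codons.append(STOP_CODONS[int(rng.choice(3, p=sw / sw.sum()))])
    return "".join(codons)


def _random_sense_codons(n: int, gc: float, rng: np.random.Generator) -> str:
    """n random non-stop codons, GC-weighted."""
    p = dict(zip("ACGT", _base_probs(gc)))
    sense = sorted(_BACTERIAL.forward_table)
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in sense])
    w = w / w.sum()
    idx = rng.choice(len(sense), size=n, p=w)
    return "".join(sense[i] for i in idx)


def translate(dna: str) -> str:
    return str(Seq(dna[: len(dna) - len(dna) % 3]).translate(table=11))


# ---------------------------------------------------------------------------
# Pseudogene planting
# ---------------------------------------------------------------------------

def plant_pseudogene(gene_dna: str, pg_class: str, rng: np.random.Generator,
                     insert_dna: Optional[str] = None,
                     kept_fraction: Optional[float] = None,
                     n_interruptions: int = 2) -> tuple[str, dict]:
    """Mutate an intact gene into a pseudogene of the requested class.

    Classes: ``internal_stop`` (>=2 sense codons replaced by stops),
    ``frameshift`` (>=2 indels of length not divisible by 3, placed at codon
    boundaries), ``split`` (an intervening ORF of >=150 bp inserted
    mid-gene), ``truncated`` (only a prefix, <=29% by default, retained).
    The returned detail map records everything needed to re-verify the
    mutation from the emitted sequence.
    """
    L = len(gene_dna)
    if L < 150:
        raise CapacityError(f"gene of {L} bp too short to host a pseudogene plant")
    if L % 3 != 0:
        raise ValueError("gene length must be a multiple of 3")
    if gene_dna[:3] not in START_CODONS:
        raise ValueError("gene must begin with a start codon")
    if gene_dna[-3:] not in STOP_CODONS:
        raise ValueError("gene must end with a stop codon")
    n_codons = L // 3  # includes start and stop

    if pg_class == "internal_stop":
        lo, hi = 5, n_codons - 6
        # sense codons only (the back-translated body has no internal stops,
        # but guard anyway)
        candidates = [c for c in range(lo, hi)
                      if gene_dna[3 * c: 3 * c + 3] not in STOP_CODONS]
        pos = sorted(rng.choice(len(candidates), size=n_interruptions,
                                replace=False).tolist())
        pos = [candidates[i] for i in pos]
        stops = [STOP_CODONS[int(rng.integers(3))] for _ in pos]
        out = list(gene_dna)
        for c, s in zip(pos, stops):
            out[3 * c: 3 * c + 3] = s
        return "".join(out), {"stop_codons": pos, "stops": stops}

    if pg_class == "frameshift":
        # indels at codon boundaries, >=15 codons apart and clear of the ends
        lo, hi = 8, n_codons - 9
        c1 = int(rng.integers(lo, hi - 15))
        c2 = int(rng.integers(c1 + 15, hi))
        indels = []
        out = gene_dna
        offset = 0
        for c in (c1, c2):
            length = int(rng.integers(1, 3))           # 1 or 2 bp
            kind = "ins" if rng.random() < 0.5 else "del"
            pos = 3 * c + offset
            if kind == "ins":
                ins = random_spacer(length, 0.5, rng)
                out = out[:pos] + ins + out[pos:]
                offset += length
                indels.append({"orig_codon": c, "kind": "ins",
                               "len": length, "seq": ins})
            else:
                out = out[:pos] + out[pos + length:]
                offset -= length
                indels.append({"orig_codon": c, "kind": "del", "len": length})
        return out, {"indels": indels, "net": offset}

    if pg_class == "split":
        if insert_dna is None:
            insert_dna = ("ATG" + _random_sense_codons(60, 0.5, rng) + "TAA")
        if len(insert_dna) < 150:
            raise ValueError("intervening ORF must be >= 150 bp")
        c = int(rng.integers(int(n_codons * 0.4), int(n_codons * 0.6) + 1))
        cut = 3 * c
        out = gene_dna[:cut] + insert_dna + gene_dna[cut:]
        return out, {"split_codon": c, "pre_len": cut,
                     "insert_len": len(insert_dna)}

    if pg_class == "truncated":
        f = kept_fraction if kept_fraction is not None \
            else float(rng.uniform(0.18, 0.29))
        kept_codons = max(10, int(n_codons * f))
        if kept_codons >= n_codons:
            raise ValueError("kept_fraction leaves the gene intact")
        out = gene_dna[: 3 * kept_codons]
        return out, {"kept_fraction": f, "kept_nt": 3 * kept_codons,
                     "kept_codons": kept_codons}

    raise ValueError(f"unknown pseudogene class {pg_class!r}")


# ---------------------------------------------------------------------------
# IS element planting
# ---------------------------------------------------------------------------

def make_is_consensus(length: int, tir_length: int, gc: float,
                      rng: np.random.Generator) -> str:
    """Family consensus: TIR + transposase ORF (+pad) + reverse-complement TIR."""
    if not (700 <= length <= 3000):
        raise ValueError("IS consensus length must be within [700, 3000]")
    if tir_length >= length / 2:
        raise ValueError("tir_length must be < consensus length / 2")
    inner = length - 2 * tir_length
    n_codons = inner // 3
    pad = inner - 3 * n_codons
    tir = random_spacer(tir_length, gc, rng)
    orf = "ATG" + _random_sense_codons(n_codons - 2, gc, rng) + "TGA"
    rc_tir = str(Seq(tir).reverse_complement())
    return tir + orf + random_spacer(pad, gc, rng) + rc_tir


def plant_is_element(family_consensus: str, tir_length: int, fragmented: bool,
                     rng: np.random.Generator) -> tuple[list[str], dict]:
    """Instantiate one insertion: intact, or fragmented.

    Fragmented elements either carry an internal stop in the transposase
    ORF (one piece) or are emitted as two pieces; the generator separates
    two-piece insertions by a recorded gap below the merge window.
    """
    L = len(family_consensus)
    if tir_length >= L / 2:
        raise ValueError("tir_length must be < consensus length / 2")
    if not fragmented:
        return [family_consensus], {"mode": "intact", "tir_length": tir_length}
    if rng.random() < 0.5:
        # internal stop near the middle of the transposase ORF
        n_codons = (L - 2 * tir_length) // 3
        c = n_codons // 2 + int(rng.integers(-5, 6))
        pos = tir_length + 3 * c
        out = family_consensus[:pos] + "TAA" + family_consensus[pos + 3:]
        return [out], {"mode": "internal_stop", "stop_codon": c,
                       "tir_length": tir_length}
    cut = int(rng.integers(int(L * 0.3), int(L * 0.7)))
    return ([family_consensus[:cut], family_consensus[cut:]],
            {"mode": "split", "cut": cut, "tir_length": tir_length})


# ---------------------------------------------------------------------------
# Whole-genome assembly
# ---------------------------------------------------------------------------

def _allocate(counts: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of `counts` items over weights."""
    w = np.asarray(weights, dtype=float)
    quota = counts * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = counts - int(base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def generate_genome(cfg: SynthConfig, ref_proteome: dict[str, str]
                    ) -> tuple[list[GenomeRecord], FeatureSet, TruthTable]:
    """Emit a genome, its CDS/tRNA annotation, and the planted truth.

    Features record every gene as CDS regardless of planted status: deciding
    pseudogene status is the caller's job, not the generator's.  IS
    insertions are left unannotated for the detector to find de novo.
    """
    rng = np.random.default_rng(cfg.seed)
    if len(ref_proteome) < cfg.n_genes:
        raise CapacityError(
            f"reference proteome has {len(ref_proteome)} proteins, "
            f"need >= {cfg.n_genes}")
    weights = _codon_weights(cfg.gc_target)

    prot_ids = list(ref_proteome)
    gene_prot_idx = rng.choice(len(prot_ids), size=cfg.n_genes, replace=False)
    gene_prots = [prot_ids[i] for i in gene_prot_idx]
    spare = [p for p in prot_ids if p not in set(gene_prots)]

    # COG labels, then pseudogene membership with category-skewed odds
    cats = np.array(list(COG_LETTERS))
    gene_cogs = [str(c) for c in rng.choice(cats, size=cfg.n_genes)]
    n_pseudo = _round_half_down(cfg.n_genes * cfg.pseudogene_fraction)
    odds = np.array([cfg.cog_skew.get(c, 1.0) for c in gene_cogs], dtype=float)
    pseudo_idx = set(
        rng.choice(cfg.n_genes, size=n_pseudo, replace=False,
                   p=odds / odds.sum()).tolist())

    # class assignment by largest remainder over class_mix
    class_names = sorted(cfg.class_mix)
    class_counts = _allocate(n_pseudo, [cfg.class_mix[c] for c in class_names])
    class_pool: list[str] = []
    for name, k in zip(class_names, class_counts):
        class_pool += [name] * k
    rng.shuffle(class_pool)
    pseudo_classes = dict(zip(sorted(pseudo_idx), class_pool))

    # IS instances
    fam_lengths = [int(rng.integers(cfg.is_length_range[0],
                                    cfg.is_length_range[1] + 1))
                   for _ in range(cfg.n_is_families)]
    families = {f"ISfam_{i:02d}": make_is_consensus(fam_lengths[i],
                                                    cfg.tir_length,
                                                    cfg.gc_target, rng)
                for i in range(cfg.n_is_families)}
    fam_ids = sorted(families)
    n_frag = _round_half_down(cfg.n_is_elements * cfg.fragmented_is_fraction)
    frag_flags = [True] * n_frag + [False] * (cfg.n_is_elements - n_frag)
    rng.shuffle(frag_flags)
    is_plan = [(fam_ids[i % len(fam_ids)], frag_flags[i])
               for i in range(cfg.n_is_elements)]

    # distribute content over replicons by length
    rep_ids = (["chromosome"] + [f"plasmid_{i}" for i in range(1, cfg.n_replicons)]
               )[: cfg.n_replicons]
    gene_alloc = _allocate(cfg.n_genes, cfg.replicon_lengths)
    is_alloc = _allocate(cfg.n_is_elements, cfg.replicon_lengths)
    rna_alloc = _allocate(cfg.n_rna_genes, cfg.replicon_lengths)

    features = FeatureSet()
    truth = TruthTable()
    genome: list[GenomeRecord] = []
    gi = ii = 0  # global gene / IS cursors
    merge_guard = 3100  # keep distinct IS sites farther apart than merge_max_gap

    for r, rep_id in enumerate(rep_ids):
        rep_len = cfg.replicon_lengths[r]
        items: list[tuple] = [("gene", gi + j) for j in range(gene_alloc[r])]
        items += [("is", ii + j) for j in range(is_alloc[r])]
        items += [("rna", j) for j in range(rna_alloc[r])]
        gi += gene_alloc[r]
        ii += is_alloc[r]
        rng.shuffle(items)

        parts: list[str] = []
        cursor = 0
        last_is_end = -merge_guard

        def emit(seq: str) -> tuple[int, int]:
            nonlocal cursor
            parts.append(seq)
            s, cursor = cursor, cursor + len(seq)
            return s, cursor

        for item_kind, idx in items:
            spacer_len = int(rng.integers(100, 401))
            if item_kind == "is" and cursor + spacer_len - last_is_end < merge_guard:
                spacer_len = merge_guard - (cursor - last_is_end)
            emit(random_spacer(spacer_len, cfg.gc_target, rng))

            if item_kind == "gene":
                pid = gene_prots[idx]
                strand = "+" if rng.random() < 0.5 else "-"
                dna = back_translate(ref_proteome[pid], cfg.gc_target, rng, weights)
                cog = gene_cogs[idx]
                if idx in pseudo_idx:
                    pg_class = pseudo_classes[idx]
                    if pg_class == "split":
                        if not spare:
                            raise CapacityError(
                                "reference proteome too small for split inserts")
                        ins_pid = spare.pop(0)
                        ins_dna = back_translate(ref_proteome[ins_pid],
                                                 cfg.gc_target, rng, weights)
                        mut, detail = plant_pseudogene(dna, "split", rng,
                                                       insert_dna=ins_dna)
                        pre, ins_len = detail["pre_len"], detail["insert_len"]
                        if strand == "-":
                            mut_fwd = _revcomp(mut)
                        else:
                            mut_fwd = mut
                        s, e = emit(mut_fwd)
                        # sub-intervals on the forward strand
                        if strand == "+":
                            iv = [(s, s + pre), (s + pre, s + pre + ins_len),
                                  (s + pre + ins_len, e)]
                            half_a, insert_iv, half_b = iv
                        else:
                            L = e - s
                            half_b = (s, s + (L - pre - ins_len))
                            insert_iv = (s + (L - pre - ins_len), s + (L - pre))
                            half_a = (s + (L - pre), e)
                        fid = f"gene_{idx:04d}"
                        features.add(Feature(f"{fid}a", rep_id, *half_a, strand,
                                             "CDS", pid, cog))
                        features.add(Feature(f"ins_{idx:04d}", rep_id, *insert_iv,
                                             strand, "CDS", ins_pid,
                                             str(rng.choice(cats))))
                        features.add(Feature(f"{fid}b", rep_id, *half_b, strand,
                                             "CDS", pid, cog))
                        detail = dict(detail, fragment_ids=[f"{fid}a", f"{fid}b"],
                                      insert_id=f"ins_{idx:04d}")
                        truth.add(TruthRecord(fid, "pseudogene", rep_id, s, e,
                                              strand, "split", pid, cog, detail))
                        truth.add(TruthRecord(f"ins_{idx:04d}", "intact_gene",
                                              rep_id, *insert_iv, strand,
                                              None, ins_pid, None, {}))
                        continue
                    mut, detail = plant_pseudogene(dna, pg_class, rng)
                    seq = _revcomp(mut) if strand == "-" else mut
                    s, e = emit(seq)
                    fid = f"gene_{idx:04d}"
                    features.add(Feature(fid, rep_id, s, e, strand, "CDS",
                                         pid, cog))
                    truth.add(TruthRecord(fid, "pseudogene", rep_id, s, e,
                                          strand, pg_class, pid, cog, detail))
                else:
                    seq = _revcomp(dna) if strand == "-" else dna
                    s, e = emit(seq)
                    fid = f"gene_{idx:04d}"
                    features.add(Feature(fid, rep_id, s, e, strand, "CDS",
                                         pid, cog))
                    truth.add(TruthRecord(fid, "intact_gene", rep_id, s, e,
                                          strand, None, pid, cog, {}))

            elif item_kind == "is":
                fam_id, fragged = is_plan[idx]
                pieces, detail = plant_is_element(families[fam_id],
                                                  cfg.tir_length, fragged, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    pieces = [_revcomp(p) for p in reversed(pieces)]
                site_start = cursor
                frag_ivs = []
                for k, piece in enumerate(pieces):
                    if k > 0:
                        gap = int(rng.integers(300, 1201))
                        emit(random_spacer(gap, cfg.gc_target, rng))
                        detail = dict(detail, gap=gap)
                    frag_ivs.append(emit(piece))
                site_end = cursor
                last_is_end = site_end
                truth.add(TruthRecord(f"is_{idx:03d}", "is_element", rep_id,
                                      site_start, site_end, strand, None, None,
                                      None, dict(detail, family_id=fam_id,
                                                 fragment_count=len(pieces),
                                                 fragments=frag_ivs,
                                                 fragmented=fragged)))

            else:  # rna
                s, e = emit(random_spacer(75, cfg.gc_target, rng))
                features.add(Feature(f"trna_{rep_id}_{idx:02d}", rep_id, s, e,
                                     "+", "tRNA", f"tRNA-{idx}"))

        if cursor > rep_len:
            raise CapacityError(
                f"{rep_id}: content needs {cursor} bp, replicon is {rep_len} bp")
        parts.append(random_spacer(rep_len - cursor, cfg.gc_target, rng))
        genome.append(GenomeRecord(rep_id, "".join(parts),
                                   "circular" if r == 0 else "linear"))

    truth.is_families = dict(families)
    return genome, features, truth


# ---------------------------------------------------------------------------
# Truth verification (used by the test suite)
# ---------------------------------------------------------------------------

def _oriented(rec: TruthRecord, genome: dict[str, GenomeRecord]) -> str:
    s = genome[rec.replicon_id].sequence[rec.start: rec.end]
    return _revcomp(s) if rec.strand == "-" else s


def verify_truth(genome: list[GenomeRecord], truth: TruthTable,
                 ref_proteome: dict[str, str]) -> list[str]:
    """Re-check every TruthRecord's defining property against the emitted
    sequence.  Returns a list of failure messages (empty = all verified)."""
    gmap = {g.replicon_id: g for g in genome}
    failures: list[str] = []

    def fail(rec, msg):
        failures.append(f"{rec.event_id}: {msg}")

    for rec in truth.records:
        dna = _oriented(rec, gmap)
        if rec.kind == "intact_gene":
            prot = ref_proteome[rec.source_protein_id]
            if translate(dna) != prot + "*":
                fail(rec, "translation does not match source protein")
        elif rec.kind == "pseudogene":
            prot = ref_proteome[rec.source_protein_id]
            d = rec.detail
            if rec.pg_class == "internal_stop":
                aa = translate(dna)
                for c in d["stop_codons"]:
                    if aa[c] != "*":
                        fail(rec, f"no stop at planted codon {c}")
            elif rec.pg_class == "frameshift":
                c1 = d["indels"][0]["orig_codon"]
                c2 = d["indels"][1]["orig_codon"]
                net = d["net"]
                if translate(dna[: 3 * c1]) != prot[:c1]:
                    fail(rec, "prefix upstream of first indel corrupted")
                tail_start = 3 * (c2 + 1) + net
                want = prot[c2 + 1:] + "*"
                if translate(dna[tail_start: tail_start + 3 * len(want)]) != want:
                    fail(rec, "suffix downstream of second indel corrupted")
            elif rec.pg_class == "split":
                pre, ins = d["pre_len"], d["insert_len"]
                if translate(dna[:pre]) != prot[: pre // 3]:
                    fail(rec, "first split fragment corrupted")
                insert = dna[pre: pre + ins]
                if not (insert[:3] in START_CODONS and insert[-3:] in STOP_CODONS
                        and len(insert) >= 150):
                    fail(rec, "intervening ORF malformed")
                tail = translate(dna[pre + ins:])
                if tail != prot[pre // 3:] + "*":
                    fail(rec, "second split fragment corrupted")
            elif rec.pg_class == "truncated":
                if len(dna) != d["kept_nt"]:
                    fail(rec, "truncated length mismatch")
                if translate(dna) != prot[: d["kept_codons"]]:
                    fail(rec, "truncated prefix corrupted")
        elif rec.kind == "is_element":
            t = rec.detail["tir_length"]
            if rec.detail["fragment_count"] == 1:
                if dna[:t] != _revcomp(dna[-t:]):
                    fail(rec, "TIRs are not reverse complements")
                if rec.detail["mode"] == "internal_stop":
                    c = rec.detail["stop_codon"]
                    if dna[t + 3 * c: t + 3 * c + 3] not in STOP_CODONS:
                        fail(rec, "planted transposase stop missing")
            else:
                cut = rec.detail["cut"]
                gap = rec.detail["gap"]
                joined = dna[:cut] + dna[cut + gap:]
                if joined[:t] != _revcomp(joined[-t:]):
                    fail(rec, "re-joined fragments lack matching TIRs")
    return failures


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    import json as _json
    with open(path, "w") as fh:
        fh.write("event_id\tkind\tclass\treplicon_id\tstart\tend\tstrand\t"
                 "source_protein_id\tcog_category\tdetail\n")
        for r in truth.records:
            fh.write("\t".join([
                r.event_id, r.kind, r.pg_class or ".", r.replicon_id,
                str(r.start), str(r.end), r.strand,
                r.source_protein_id or ".", r.cog_category or ".",
                _json.dumps(r.detail, sort_keys=True),
            ]) + "\n")


def write_synthetic(cfg: SynthConfig, outdir: str | Path,
                    ref_proteome: Optional[dict[str, str]] = None) -> dict:
    """Generate and write genome.fasta, features.gff3, refs.faa, is_library.fasta
    and truth.tsv; returns paths plus in-memory objects."""
    from .genome_io import write_protein_fasta
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ref_proteome is None:
        rng = np.random.default_rng(cfg.seed + 1)
        ref_proteome = random_proteome(cfg.n_genes + 40, rng)
    genome, features, truth = generate_genome(cfg, ref_proteome)

    write_fasta(genome, outdir / "genome.fasta")
    write_gff(features, outdir / "features.gff3")
    write_protein_fasta(ref_proteome, outdir / "refs.faa")
    # family consensi double as the IS homology library
    if truth.is_families:
        write_fasta([GenomeRecord(fid, seq) for fid, seq in
                     sorted(truth.is_families.items())],
                    outdir / "is_library.fasta")
    write_truth_tsv(truth, outdir / "truth.tsv")
    return {"genome": genome, "features": features, "truth": truth,
            "ref_proteome": ref_proteome,
            "paths": {k: str(outdir / v) for k, v in
                      [("genome", "genome.fasta"), ("features", "features.gff3"),
                       ("refs", "refs.faa"), ("truth", "truth.tsv"),
                       ("is_library", "is_library.fasta")]}}
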
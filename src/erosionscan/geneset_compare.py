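"""Status of curated gene sets in an eroded genome, and best-reciprocal-hit
ortholog pairing between proteomes.

Each entry of a gene set (e.g. a minimal bacterial set, or cyanobacterial
core/shell sets) is located in the genome by the same frameshift-aware
chain machinery the pseudogene caller uses; its status is copied from the
best-matching feature's call.  An intact copy anywhere in the genome
overrides pseudogenized copies elsewhere — plasmid-borne pseudogenes with
intact chromosomal counterparts count as intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .genome_io import FeatureSet, GenomeRecord, read_protein_fasta
from .pseudo_caller import (CallerConfig, ScoringScheme, _RefIndex,
                            _candidate_region, best_chain, chain_blocks,
                            three_frame_align)

__all__ = ["GeneSetEntry", "GeneStatus", "load_gene_set",
           "best_reciprocal_hits", "classify_gene_set"]


@dataclass
class GeneSetEntry:
    gene_name: str
    ref_protein: str
    set_name: str = "custom"    # minimal | core | shell | custom

    def __post_init__(self) -> None:
        if not self.ref_protein:
            raise ValueError(f"gene {self.gene_name!r}: empty protein")


@dataclass
class GeneStatus:
    gene_name: str
    set_name: str
    status: str                 # intact | pseudogene | absent
    matched_feature_id: Optional[str] = None
    score: float = 0.0
    evidence: str = ""


def load_gene_set(tsv_path: str | Path, fasta_path: str | Path,
                  set_name: str = "custom") -> list[GeneSetEntry]:
    """Gene set from a TSV (gene_name <tab> protein_id) plus a protein FASTA."""
    proteins = read_protein_fasta(fasta_path)
    entries = []
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_name, prot_id = line.split("\t")[:2]
            if gene_name == "gene_name":
                continue
            if prot_id not in proteins:
                raise ValueError(f"protein {prot_id!r} missing from FASTA")
            entries.append(GeneSetEntry(gene_name, proteins[prot_id], set_name))
    if not entries:
        raise ValueError(f"empty gene set in {tsv_path}")
    return entries


def best_reciprocal_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
                         scoring: Optional[ScoringScheme] = None,
                         min_score: float = 40.0
                         ) -> list[tuple[str, str, float]]:
    """Best-reciprocal-hit pairs between two proteomes.

    (a, b) is reported iff b is a's highest-scoring local-alignment hit and
    vice versa; score ties break by id order (and are thereby deterministic).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be nonempty")
    scoring = scoring or ScoringScheme()
    aligner = scoring.make_aligner()

    def best_hits(src: dict[str, str], dst: dict[str, str]) -> dict[str, tuple[str, float]]:
        out = {}
        for aid in sorted(src):
            best_id, best_score = None, min_score
            for bid in sorted(dst):
                try:
                    s = float(aligner.score(src[aid], dst[bid]))
                except ValueError:
                    continue
                if s > best_score or (s == best_score and best_id is None):
                    best_id, best_score = bid, s
            if best_id is not None:
                out[aid] = (best_id, best_score)
        return out

    a2b = best_hits(proteome_a, proteome_b)
    b2a = best_hits(proteome_b, proteome_a)
    pairs = []
    for aid, (bid, score) in sorted(a2b.items()):
        if b2a.get(bid, (None,))[0] == aid:
            pairs.append((aid, bid, score))
    return pairs


def classify_gene_set(entries: Sequence[GeneSetEntry],
                      genome: Sequence[GenomeRecord],
                      features_with_calls: FeatureSet,
                      cfg: Optional[CallerConfig] = None,
                      scoring: Optional[ScoringScheme] = None,
                      min_chain_score: float = 50.0) -> list[GeneStatus]:
    """Intact / pseudogene / absent status of each gene-set entry.

    Every entry is aligned against every annotated coding region (CDS or
    called pseudogene); matches above ``min_chain_score`` inherit the
    feature's call.  The verdict is order-independent: any intact match
    wins over any pseudogene match.
    """
    if not entries:
        raise ValueError("empty gene set")
    cfg = cfg or CallerConfig()
    scoring = scoring or ScoringScheme()
    gmap = {g.replicon_id: g for g in genome}

    candidates = [f for f in features_with_calls
                  if f.ftype in ("CDS", "pseudogene")]
    regions = {f.feature_id: _candidate_region(f, gmap, cfg.region_flank)
               for f in candidates}

    # invert the search: for each region, shortlist entries by shared
    # protein k-mers, then align only those
    entry_proteins = {f"{e.set_name}\x00{e.gene_name}": e.ref_protein
                      for e in entries}
    index = _RefIndex(entry_proteins, cfg.kmer)
    matches_by_entry: dict[str, list[tuple[float, str, str]]] = {}
    for f in candidates:
        region = regions[f.feature_id]
        for key in index.candidates(region, top=5):
            ref = entry_proteins[key]
            blocks = three_frame_align(region, ref, scoring, cfg.min_block_score)
            if not blocks:
                continue
            chain = chain_blocks(blocks, len(ref), scoring)
            if chain.score >= min_chain_score:
                matches_by_entry.setdefault(key, []).append(
                    (chain.score, f.ftype, f.feature_id))

    statuses: list[GeneStatus] = []
    for entry in entries:
        matches = matches_by_entry.get(
            f"{entry.set_name}\x00{entry.gene_name}", [])
        if not matches:
            statuses.append(GeneStatus(entry.gene_name, entry.set_name,
                                       "absent"))
            continue
        intact = sorted((m for m in matches if m[1] == "CDS"),
                        key=lambda m: (-m[0], m[2]))
        if intact:
            s, _, fid = intact[0]
            statuses.append(GeneStatus(entry.gene_name, entry.set_name,
                                       "intact", fid, s,
                                       "intact copy present"))
        else:
            pseudo = sorted(matches, key=lambda m: (-m[0], m[2]))
            s, _, fid = pseudo[0]
            statuses.append(GeneStatus(entry.gene_name, entry.set_name,
                                       "pseudogene", fid, s,
                                       "best copies are pseudogenized"))
    return statuses


def write_status_tsv(statuses: Sequence[GeneStatus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tgene_name\tstatus\tmatched_feature_id\tscore\n")
        for st in statuses:
            fh.write(f"{st.set_name}\t{st.gene_name}\t{st.status}\t"
                     f"{st.matched_feature_id or '.'}\t{st.score:.1f}\n")
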
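"""Genome-level erosion summary: gene inventories, pseudogene fractions,
per-replicon erosion ratios, GC content and coding fraction.

Conventions: GC is computed over an N-free denominator; the coding fraction
counts the union of intact CDS intervals once (pseudogenes excluded); the
per-replicon erosion ratio is pseudogenes : predicted genes, where the
predicted-gene denominator by default includes RNA genes but not the
pseudogenes themselves (a CDS-only variant is reported alongside).
Percentages print at one decimal; JSON keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_io import FeatureSet, GenomeRecord

__all__ = ["ErosionSummary", "gc_content", "coding_fraction",
           "erosion_summary", "pseudogene_percent_from_counts"]


@dataclass
class ErosionSummary:
    per_replicon: dict = field(default_factory=dict)
    genome_totals: dict = field(default_factory=dict)
    coding_fraction_percent: float = 0.0
    pseudogene_percent_of_genes: float = 0.0

    def to_rows(self) -> list[dict]:
        rows = []
        for rid in sorted(self.per_replicon):
            d = dict(self.per_replicon[rid])
            d["replicon_id"] = rid
            rows.append(d)
        tot = dict(self.genome_totals)
        tot["replicon_id"] = "TOTAL"
        rows.append(tot)
        return rows


def gc_content(genome: Sequence[GenomeRecord] | GenomeRecord | str) -> float:
    """Percent G+C over all replicons, N excluded from the denominator."""
    if isinstance(genome, str):
        seqs = [genome]
    elif isinstance(genome, GenomeRecord):
        seqs = [genome.sequence]
    else:
        seqs = [g.sequence for g in genome]
    gc = acgt = 0
    for s in seqs:
        gc += s.count("G") + s.count("C")
        acgt += len(s) - s.count("N")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / acgt


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def coding_fraction(genome: Sequence[GenomeRecord],
                    features: FeatureSet) -> float:
    """Percent of genome length covered by the union of intact CDS intervals."""
    total_len = sum(len(g) for g in genome)
    covered = 0
    for g in genome:
        ivs = [(f.start, f.end) for f in features.by_replicon(g.replicon_id)
               if f.ftype == "CDS"]
        covered += _union_length(ivs)
    return 100.0 * covered / total_len if total_len else 0.0


def pseudogene_percent_from_counts(n_pseudogenes: int, n_cds_intact: int,
                                   n_rna_genes: int = 0) -> float:
    """Pseudogenes as a percent of all genes (intact CDS + RNA + pseudogenes)."""
    total = n_pseudogenes + n_cds_intact + n_rna_genes
    if total == 0:
        return 0.0
    return 100.0 * n_pseudogenes / total


def erosion_summary(genome: Sequence[GenomeRecord], features: FeatureSet,
                    include_rna_in_ratio_denominator: bool = True
                    ) -> ErosionSummary:
    """Fill the per-replicon and genome-total erosion inventory.

    Requires features to carry final call status (ftype ``pseudogene`` for
    called pseudogenes).  Reordering features or replicons does not change
    any statistic.
    """
    summary = ErosionSummary()
    totals = {"length_bp": 0, "n_genes_total": 0, "n_cds_intact": 0,
              "n_pseudogenes": 0, "n_rna_genes": 0}
    gc_num = gc_den = 0
    for g in sorted(genome, key=lambda g: g.replicon_id):
        feats = features.by_replicon(g.replicon_id)
        n_cds = sum(1 for f in feats if f.ftype == "CDS")
        n_pseudo = sum(1 for f in feats if f.ftype == "pseudogene")
        n_rna = sum(1 for f in feats if f.ftype in ("tRNA", "rRNA"))
        n_total = n_cds + n_pseudo + n_rna
        denom = n_cds + (n_rna if include_rna_in_ratio_denominator else 0)
        summary.per_replicon[g.replicon_id] = {
            "length_bp": len(g),
            "gc_percent": gc_content(g),
            "n_genes_total": n_total,
            "n_cds_intact": n_cds,
            "n_pseudogenes": n_pseudo,
            "n_rna_genes": n_rna,
            "erosion_ratio": (n_pseudo / denom) if denom else float("nan"),
            "erosion_ratio_cds_only": (n_pseudo / n_cds) if n_cds else float("nan"),
        }
        totals["length_bp"] += len(g)
        totals["n_genes_total"] += n_total
        totals["n_cds_intact"] += n_cds
        totals["n_pseudogenes"] += n_pseudo
        totals["n_rna_genes"] += n_rna
        gc_num += g.sequence.count("G") + g.sequence.count("C")
        gc_den += len(g.sequence) - g.sequence.count("N")
    denom = totals["n_cds_intact"] + (
        totals["n_rna_genes"] if include_rna_in_ratio_denominator else 0)
    totals["gc_percent"] = 100.0 * gc_num / gc_den if gc_den else float("nan")
    totals["erosion_ratio"] = (
        totals["n_pseudogenes"] / denom if denom else float("nan"))
    totals["erosion_ratio_cds_only"] = (
        totals["n_pseudogenes"] / totals["n_cds_intact"]
        if totals["n_cds_intact"] else float("nan"))
    summary.genome_totals = totals
    summary.coding_fraction_percent = coding_fraction(genome, features)
    summary.pseudogene_percent_of_genes = pseudogene_percent_from_counts(
        totals["n_pseudogenes"], totals["n_cds_intact"], totals["n_rna_genes"])
    return summary
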
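"""Genome and annotation I/O with a fixed internal coordinate convention.

All intervals inside the package are 0-based, half-open ``[start, end)``.
The 1-based inclusive convention of GFF3 exists only at the file boundary:
``start_internal = start_gff - 1`` and ``end_internal = end_gff``.

Nucleotide sequences are normalized on read: lowercase is uppercased and
every IUPAC ambiguity code other than A/C/G/T collapses to N.  N never
matches anything in downstream alignment scoring, so sub-N resolution is
never needed by the analysis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COG_CATEGORIES = frozenset("BCDEFGHIJKLMNOPQRSTUV")

_NON_ACGT = re.compile(r"[^ACGT]")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates the internal data contracts."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse non-ACGT letters to N."""
    return _NON_ACGT.sub("N", seq.upper())


@dataclass
class GenomeRecord:
    """One replicon: a chromosome or plasmid."""

    replicon_id: str
    sequence: str
    topology: str = "linear"  # "circular" | "linear"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"replicon {self.replicon_id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """An annotated interval on a replicon (0-based, half-open)."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    ftype: str = "CDS"  # CDS | pseudogene | tRNA | rRNA | IS_remnant | other
    product: str = ""
    cog_category: Optional[str] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id!r}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if self.cog_category is not None and self.cog_category not in COG_CATEGORIES:
            raise ValidationError(
                f"feature {self.feature_id!r}: unknown COG category {self.cog_category!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def extract(self, genome: dict[str, GenomeRecord] | GenomeRecord) -> str:
        """Feature sequence on its own strand.

        Minus-strand features are reverse-complemented lazily here; stored
        coordinates always refer to the forward strand.
        """
        rec = genome if isinstance(genome, GenomeRecord) else genome[self.replicon_id]
        s = rec.sequence[self.start : self.end]
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


class FeatureSet:
    """Ordered collection of features, indexed by id and by replicon.

    Iteration order is (replicon_id, start, end, feature_id).
    """

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self._by_id: dict[str, Feature] = {}
        for f in features:
            self.add(f)

    def add(self, f: Feature) -> None:
        if f.feature_id in self._by_id:
            raise ValidationError(f"duplicate feature_id {f.feature_id!r}")
        self._by_id[f.feature_id] = f

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Feature]:
        return iter(
            sorted(
                self._by_id.values(),
                key=lambda f: (f.replicon_id, f.start, f.end, f.feature_id),
            )
        )

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def by_replicon(self, replicon_id: str) -> list[Feature]:
        return [f for f in self if f.replicon_id == replicon_id]

    def of_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self if f.ftype in ftypes]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read nucleotide FASTA into GenomeRecords.

    Topology defaults to linear; a ``circular=true`` tag in the header
    description switches it.  Duplicate ids and empty files are errors.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        topology = "circular" if "circular=true" in rec.description.lower() else "linear"
        records.append(GenomeRecord(rec.id, normalize_sequence(str(rec.seq)), topology))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecords = []
    for r in records:
        desc = "circular=true" if r.topology == "circular" else ""
        seqrecords.append(SeqRecord(Seq(r.sequence), id=r.replicon_id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Amino-acid FASTA as an id -> sequence map (order-preserving)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate protein id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().rstrip("*")
    if not out:
        raise FormatError(f"no protein records found in {path}")
    return out


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPE_MAP = {"CDS": "CDS", "pseudogene": "pseudogene", "tRNA": "tRNA",
                 "rRNA": "rRNA", "IS_remnant": "IS_remnant"}


def _parse_gff_attrs(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def _format_gff_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff(path: str | Path, genome: list[GenomeRecord]) -> FeatureSet:
    """Read GFF3 annotations against a loaded genome.

    Coordinates convert from 1-based inclusive to 0-based half-open.  A
    ``pseudo=true`` attribute or a ``pseudogene`` type column yields ftype
    ``pseudogene``; a ``cog=X`` attribute populates the COG category.
    """
    lengths = {g.replicon_id: len(g) for g in genome}
    fs = FeatureSet()
    unknown: list[str] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            if seqid not in lengths:
                unknown.append(seqid)
                continue
            start_gff, end_gff = int(start_s), int(end_s)
            if end_gff < start_gff:
                raise ValidationError(f"{path}:{lineno}: end < start")
            attrs = _parse_gff_attrs(col9)
            counter += 1
            fid = attrs.pop("ID", f"feature_{counter:06d}")
            if attrs.pop("pseudo", "").lower() == "true" or ftype == "pseudogene":
                internal_type = "pseudogene"
            else:
                internal_type = _GFF_TYPE_MAP.get(ftype, "other")
            cog = attrs.pop("cog", None)
            product = attrs.pop("product", "")
            start = start_gff - 1
            end = end_gff
            if end > lengths[seqid]:
                raise ValidationError(
                    f"{path}:{lineno}: feature {fid!r} extends past end of {seqid!r}"
                )
            fs.add(
                Feature(fid, seqid, start, end, strand if strand in "+-" else "+",
                        internal_type, product, cog, attrs)
            )
    if unknown:
        raise ValidationError(
            "GFF seqids not present in genome: " + ", ".join(sorted(set(unknown)))
        )
    return fs


def write_gff(features: FeatureSet, path: str | Path) -> int:
    """Write features as GFF3 (with version pragma); returns row count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = {"ID": f.feature_id}
            if f.product:
                attrs["product"] = f.product
            if f.ftype == "pseudogene":
                attrs["pseudo"] = "true"
            if f.cog_category:
                attrs["cog"] = f.cog_category
            attrs.update({k: str(v) for k, v in f.attrs.items()})
            gff_type = f.ftype if f.ftype in _GFF_TYPE_MAP else "region"
            fh.write(
                "\t".join(
                    [f.replicon_id, "erosionscan", gff_type, str(f.start + 1),
                     str(f.end), ".", f.strand, ".", _format_gff_attrs(attrs)]
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

def write_outputs(calls: FeatureSet, stats, outdir: str | Path,
                  cog_table=None, chisq=None) -> dict[str, int]:
    """Write the standard result bundle; returns a file -> row-count manifest.

    ``calls.gff3`` holds pseudogene and IS_remnant features with their
    evidence attributes; ``erosion.tsv`` the per-replicon summary;
    ``cog_table.tsv`` the contingency table with residuals; ``report.json``
    a machine-readable aggregate with keys ``pseudogene_fraction``,
    ``per_replicon`` and ``chisq``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    call_features = FeatureSet(
        f for f in calls if f.ftype in ("pseudogene", "IS_remnant")
    )
    manifest["calls.gff3"] = write_gff(call_features, outdir / "calls.gff3")

    erosion_rows = stats.to_rows() if stats is not None else []
    with open(outdir / "erosion.tsv", "w") as fh:
        header = ["replicon_id", "length_bp", "gc_percent", "n_genes_total",
                  "n_cds_intact", "n_pseudogenes", "n_rna_genes", "erosion_ratio"]
        fh.write("\t".join(header) + "\n")
        for row in erosion_rows:
            fh.write("\t".join(str(row[h]) for h in header) + "\n")
    manifest["erosion.tsv"] = len(erosion_rows)

    cog_rows = []
    if cog_table is not None:
        residuals = dict(chisq.residuals) if chisq is not None else {}
        for cat in cog_table.categories:
            ni, np_ = cog_table.counts[cat]
            tot = ni + np_
            cog_rows.append({
                "category": cat, "n_intact": ni, "n_pseudo": np_,
                "pct_pseudo": round(100.0 * np_ / tot, 1) if tot else 0.0,
                "residual": residuals.get(cat, ""),
            })
    with open(outdir / "cog_table.tsv", "w") as fh:
        header = ["category", "n_intact", "n_pseudo", "pct_pseudo", "residual"]
        fh.write("\t".join(header) + "\n")
        for row in cog_rows:
            fh.write("\t".join(str(row[h]) for h in header) + "\n")
    manifest["cog_table.tsv"] = len(cog_rows)

    report = {
        "pseudogene_fraction": (
            stats.pseudogene_percent_of_genes / 100.0 if stats is not None else None
        ),
        "per_replicon": {r["replicon_id"]: r for r in erosion_rows},
        "chisq": chisq.to_dict() if chisq is not None else None,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["report.json"] = 1
    return manifest
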
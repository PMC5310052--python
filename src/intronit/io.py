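"""On-disk formats and the internal coordinate convention.

Every coordinate inside the package is 0-based, half-open.  GFF3 input
(1-based, closed) is converted at this boundary and nowhere else, as are
the 1-based inclusive coordinates of BLAST-style 12-column alignment
tables.  Genome sequences are held uppercase; ambiguity codes are kept on
input and treated as ``N`` by every consumer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger("intronit")

PathLike = Union[str, Path]

IUPAC_NT = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomePanel:
    """One genomic arm: a labelled collection of scaffold sequences."""

    arm_id: str
    scaffolds: Dict[str, str]
    # lazily built k-mer indexes, keyed by (scaffold_id, k); see mapping.py
    _indexes: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise FormatError(f"scaffold {sid!r} in arm {self.arm_id} is empty")
            bad = set(seq) - IUPAC_NT
            if bad:
                raise FormatError(
                    f"scaffold {sid!r} contains non-IUPAC characters {sorted(bad)}")

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def sequence(self, scaffold_id: str) -> str:
        try:
            return self.scaffolds[scaffold_id]
        except KeyError:
            raise KeyError(f"arm {self.arm_id} has no scaffold {scaffold_id!r}") from None


@dataclass
class GeneModel:
    """A gene with ordered exon coordinates and its spliced transcript.

    ``exons`` are genomic intervals (0-based half-open) on ``scaffold_id``,
    sorted by genomic start regardless of strand.  ``transcript_seq`` is the
    mature spliced sequence in transcript orientation: for minus-strand
    genes it is the reverse complement of the exon concatenation taken in
    descending genomic order.
    """

    gene_id: str
    source: str
    scaffold_id: str
    strand: str
    exons: List[tuple]
    transcript_seq: str
    start_pos: Optional[int] = None  # pseudomolecule position, for window_filter

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise FormatError(f"gene {self.gene_id}: bad exon interval ({s}, {e})")
            if s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if len(self.transcript_seq) != sum(e - s for s, e in self.exons):
            raise FormatError(
                f"gene {self.gene_id}: transcript length "
                f"{len(self.transcript_seq)} != total exon length")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def spliced_sequence(scaffold_seq: str, exons: Iterable[tuple], strand: str) -> str:
    """Assemble the transcript sequence from genomic exon intervals."""
    parts = [scaffold_seq[s:e] for s, e in exons]
    seq = "".join(parts).upper()
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA / GFF3 input


def read_genome_panel(path: PathLike, arm_id: str) -> GenomePanel:
    """Load a multi-FASTA assembly as one genomic arm.

    Sequences are uppercased; duplicate scaffold ids are an error.
    """
    scaffolds: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise FormatError(f"duplicate scaffold id {rec.id!r} in {path}")
        scaffolds[rec.id] = str(rec.seq).upper()
    if not scaffolds:
        raise FormatError(f"no FASTA records in {path}")
    return GenomePanel(arm_id=arm_id, scaffolds=scaffolds)


def read_transcript_fasta(path: PathLike, source: str = "fasta") -> List[GeneModel]:
    """Load transcripts without genomic structure (single-'exon' models)."""
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        genes.append(GeneModel(rec.id, source, rec.id, "+", [(0, len(seq))], seq))
    if not genes:
        raise FormatError(f"no FASTA records in {path}")
    return genes


def read_gene_models(genome: GenomePanel, annotation: PathLike,
                     source: str = "gff3") -> List[GeneModel]:
    """Parse a GFF3 file into gene models with spliced transcripts.

    Coordinates are converted from GFF3 1-based closed to internal 0-based
    half-open.  For genes with several mRNAs the longest transcript is
    kept.  Exons whose ``Parent`` cannot be resolved are skipped with a
    warning; an exon outside its scaffold is an error.
    """
    db = gffutils.create_db(str(annotation), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: Optional[GeneModel] = None
        transcripts = list(db.children(gene, featuretype="mRNA")) or [gene]
        for tx in transcripts:
            exons = []
            for exon in db.children(tx, featuretype="exon", order_by="start"):
                exons.append((exon.start - 1, exon.end))  # to 0-based half-open
            if not exons:
                continue
            scaffold = genome.scaffolds.get(gene.seqid)
            if scaffold is None:
                raise FormatError(
                    f"gene {gene.id}: scaffold {gene.seqid!r} absent from arm "
                    f"{genome.arm_id}")
            if exons[-1][1] > len(scaffold):
                raise FormatError(
                    f"gene {gene.id}: exon end {exons[-1][1]} exceeds scaffold "
                    f"length {len(scaffold)}")
            strand = gene.strand if gene.strand in "+-" else "+"
            seq = spliced_sequence(scaffold, exons, strand)
            model = GeneModel(gene.id, source, gene.seqid, strand, exons, seq,
                              start_pos=gene.start - 1)
            if best is None or len(model.transcript_seq) > len(best.transcript_seq):
                best = model
        if best is not None:
            genes.append(best)
        else:
            logger.warning("gene %s has no exons; skipped", gene.id)
    return genes


def write_gene_models_gff3(genes: List[GeneModel], path: PathLike) -> None:
    """Write gene models back to GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = g.exons[0][0] + 1
            end = g.exons[-1][1]
            fh.write(f"{g.scaffold_id}\tintronit\tgene\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.scaffold_id}\tintronit\tmRNA\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.scaffold_id}\tintronit\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n")


# ---------------------------------------------------------------------------
# tabular formats

ALIGNMENT_COLUMNS = ["qid", "sid", "pident", "length", "mismatches", "gapopen",
                     "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_alignment_table(path: PathLike) -> pd.DataFrame:
    """Read a 12-column BLAST-tabular alignment file.

    Coordinates in the file are 1-based inclusive; ``qstart``/``qend`` etc.
    are converted to 0-based half-open on read (start-1, end), preserving
    orientation by keeping reversed subject intervals reversed.
    """
    df = pd.read_csv(path, sep="\t", names=ALIGNMENT_COLUMNS, comment="#")
    if df.empty:
        return df
    for col in ("qstart", "sstart"):
        df[col] = df[col] - 1
    # reversed subject hits have sstart > send in 1-based; after the shift a
    # reversed interval is (send, sstart+1) half-open on the minus strand
    return df


MARKER_COLUMNS = [
    "marker_id", "gene_id", "junction_index", "forward_primer", "reverse_primer",
    "tm_forward", "tm_reverse", "intron_A", "intron_B", "intron_D", "intron_V",
    "product_A", "product_B", "product_D", "product_V", "type", "is_specific",
]


def write_marker_table(markers: List["MarkerCandidate"], path: PathLike) -> None:
    """Write markers as a TSV mirroring the published marker tables.

    One row per marker, ordered by marker_id; intron and predicted product
    sizes appear per arm (A, B, D, V).  Missing products are blank.
    """
    rows = []
    for m in sorted(markers, key=lambda m: m.marker_id):
        row = {
            "marker_id": m.marker_id,
            "gene_id": m.gene_id,
            "junction_index": m.junction_index,
            "forward_primer": m.primer_pair.forward_seq,
            "reverse_primer": m.primer_pair.reverse_seq,
            "tm_forward": round(m.primer_pair.tm_f, 2),
            "tm_reverse": round(m.primer_pair.tm_r, 2),
        }
        for arm in "ABDV":
            row[f"intron_{arm}"] = m.intron_sizes.get(arm, "")
            row[f"product_{arm}"] = m.product_sizes.get(arm, "")
        row["type"] = m.type_label or ""
        row["is_specific"] = {True: "1", False: "0", None: ""}[m.is_specific]
        rows.append(row)
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_marker_table(path: PathLike) -> List["MarkerCandidate"]:
    """Round-trip reader for :func:`write_marker_table` output."""
    from .primers import MarkerCandidate, PrimerPair

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    markers = []
    for _, row in df.iterrows():
        pair = PrimerPair(
            forward_seq=row["forward_primer"], reverse_seq=row["reverse_primer"],
            tm_f=float(row["tm_forward"]), tm_r=float(row["tm_reverse"]),
            anchor_left=0, anchor_right=0, pair_score=0.0)
        introns = {a: int(float(row[f"intron_{a}"])) for a in "ABDV"
                   if row[f"intron_{a}"] != ""}
        products = {a: int(float(row[f"product_{a}"])) for a in "ABDV"
                    if row[f"product_{a}"] != ""}
        markers.append(MarkerCandidate(
            marker_id=row["marker_id"], gene_id=row["gene_id"],
            junction_index=int(row["junction_index"]), primer_pair=pair,
            intron_sizes=introns, product_sizes=products,
            type_label=row["type"] or None,
            is_specific={"1": True, "0": False, "": None}[row["is_specific"]]))
    return markers


def read_presence_matrix(path: PathLike) -> pd.DataFrame:
    """Read a marker x line presence/absence TSV (values 1/0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = set(df.values.ravel()) - {0, 1}
    if bad:
        raise FormatError(f"presence matrix contains non-binary values {sorted(bad)}")
    if df.index.duplicated().any():
        raise FormatError("duplicate marker ids in presence matrix")
    return df.astype(int)
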
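"""Gene models, genome I/O and coordinate conventions.

All genomic coordinates are 0-based, half-open, on the plus strand of the
contig. A cleavage site is stored as the 3' boundary of the transcribed
interval: on '+' it is one past the last transcribed base, on '-' it is the
coordinate of the last transcribed base itself (the low, half-open boundary).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model for 3'UTR work.

    ``stop_start``/``stop_end`` delimit the stop codon (half-open, 3 nt).
    ``furthest_site`` is the 3' boundary of the furthest annotated 3'UTR end,
    in the cleavage-site convention above. ``tx_start``/``tx_end`` span the
    whole annotated transcript on the contig.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    stop_start: int
    stop_end: int
    furthest_site: int
    tx_start: int = 0
    tx_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def sign(self) -> int:
        return 1 if self.strand == "+" else -1

    @property
    def utr_anchor(self) -> int:
        """Boundary between stop codon and 3'UTR (first UTR position)."""
        return self.stop_end if self.strand == "+" else self.stop_start

    def utr_length_of(self, site: int) -> int:
        """UTR length implied by a cleavage site (nt after the stop codon)."""
        return (site - self.utr_anchor) * self.sign

    def site_at(self, utr_length: int) -> int:
        return self.utr_anchor + self.sign * utr_length

    @property
    def max_utr_length(self) -> int:
        return self.utr_length_of(self.furthest_site)


def utr_sequence(gene: GeneModel, genome: dict[str, str], length: int | None = None) -> str:
    """Transcribed-strand 3'UTR sequence from just after the stop codon."""
    if length is None:
        length = gene.max_utr_length
    seq = genome[gene.contig]
    if gene.strand == "+":
        return seq[gene.utr_anchor : gene.utr_anchor + length]
    return revcomp(seq[gene.utr_anchor - length : gene.utr_anchor])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (gene / stop_codon / three_prime_UTR vocabulary used by this package)
# ---------------------------------------------------------------------------

def genes_to_gff3(genes: Iterable[GeneModel]) -> str:
    """Serialize gene models as GFF3 (1-based inclusive coordinates)."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for g in genes:
        attrs = f"ID={g.gene_id}"
        rows = [
            ("gene", g.tx_start, g.tx_end, attrs),
            ("stop_codon", g.stop_start, g.stop_end, f"Parent={g.gene_id}"),
        ]
        # three_prime_UTR spans anchor..furthest annotated end (transcribed order)
        if g.strand == "+":
            rows.append(("three_prime_UTR", g.utr_anchor, g.furthest_site, f"Parent={g.gene_id}"))
        else:
            # furthest_site is the coordinate of the furthest transcribed base
            rows.append(("three_prime_UTR", g.furthest_site, g.utr_anchor, f"Parent={g.gene_id}"))
        for ftype, start, end, attr in rows:
            out.write(
                "\t".join(
                    [
                        g.contig,
                        "apa_utrome",
                        ftype,
                        str(start + 1),  # GFF3 is 1-based inclusive
                        str(end),
                        ".",
                        g.strand,
                        ".",
                        attr,
                    ]
                )
                + "\n"
            )
    return out.getvalue()


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(genes_to_gff3(genes))


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from GFF3 written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            start0, end0 = int(start) - 1, int(end)
            adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = adict.get("ID") or adict.get("Parent")
            if gid is None:
                continue
            rec = genes.setdefault(gid, {"contig": contig, "strand": strand})
            if ftype == "gene":
                rec["tx_start"], rec["tx_end"] = start0, end0
            elif ftype == "stop_codon":
                rec["stop_start"], rec["stop_end"] = start0, end0
            elif ftype == "three_prime_UTR":
                rec["utr_start"], rec["utr_end"] = start0, end0
    models = []
    for gid, rec in genes.items():
        if "stop_start" not in rec:
            raise ValueError(f"gene {gid} lacks a stop_codon feature")
        if "utr_start" in rec:
            furthest = rec["utr_end"] if rec["strand"] == "+" else rec["utr_start"]
        else:
            furthest = rec["stop_end"] if rec["strand"] == "+" else rec["stop_start"]
        models.append(
            GeneModel(
                gene_id=gid,
                contig=rec["contig"],
                strand=rec["strand"],
                stop_start=rec["stop_start"],
                stop_end=rec["stop_end"],
                furthest_site=furthest,
                tx_start=rec.get("tx_start", 0),
                tx_end=rec.get("tx_end", 0),
            )
        )
    models.sort(key=lambda g: (g.contig, g.tx_start, g.gene_id))
    return models
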
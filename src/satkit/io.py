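"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing goes through Biopython; BED6 and GFF3 emission/ingestion
are thin, coordinate-convention-aware layers over the internal 0-based
half-open representation. Newick dating lives in :mod:`satkit.trees` and is
re-exported here.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO

from satkit.records import GenomeSequence, MonomerHit, SatFamily, VALID_BASES
from satkit.trees import DatedTree, read_newick_dated  # noqa: F401  (re-export)

logger = logging.getLogger("satkit")

_AMBIGUOUS = set("RYSWKMBDHVU")


def _normalize(seq: str, seq_id: str, coerce_ambiguous: bool) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        if coerce_ambiguous and bad <= _AMBIGUOUS:
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        else:
            raise ValueError(
                f"record {seq_id!r} contains ambiguity characters {sorted(bad)}; "
                "pass coerce_ambiguous=True to convert them to N"
            )
    return seq


def _check_fasta_header(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: malformed FASTA — first record has no '>' header")
            return


def read_fasta(path: str | Path, coerce_ambiguous: bool = False) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records (uppercased)."""
    path = Path(path)
    _check_fasta_header(path)
    seqs = [
        GenomeSequence(rec.id, _normalize(str(rec.seq), rec.id, coerce_ambiguous))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        logger.warning("FASTA file %s is empty", path)
    ids = [s.seq_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence identifiers in {path}")
    return seqs


def read_families(path: str | Path, coerce_ambiguous: bool = False) -> list[SatFamily]:
    """Read a consensus FASTA into SatFamily records."""
    return [SatFamily(s.seq_id, s.sequence) for s in read_fasta(path, coerce_ambiguous)]


def write_fasta(seqs, path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs, GenomeSequence or SatFamily records as FASTA."""
    with open(path, "w") as fh:
        for item in seqs:
            if isinstance(item, GenomeSequence):
                sid, seq = item.seq_id, item.sequence
            elif isinstance(item, SatFamily):
                sid, seq = item.family_id, item.consensus
            else:
                sid, seq = item
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (id, sequence) pairs (qualities are not used)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads, path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Feature emission: BED6 (0-based half-open) and GFF3 (1-based inclusive)
# ---------------------------------------------------------------------------

def _feature_fields(feature):
    if feature.end <= feature.start:
        raise ValueError(f"feature {feature.family_id}@{feature.seq_id}:{feature.start}-{feature.end}: end <= start")
    divergence = getattr(feature, "divergence", 0.0)
    rotation = getattr(feature, "rotation", None)
    return feature.seq_id, feature.start, feature.end, feature.family_id, feature.strand, divergence, rotation


def write_bed(features, path: str | Path) -> None:
    """BED6: score column carries divergence x 1000 (integer)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for feat in features:
            sid, start, end, name, strand, div, _ = _feature_fields(feat)
            fh.write(f"{sid}\t{start}\t{end}\t{name}\t{round(div * 1000)}\t{strand}\n")


def read_bed(path: str | Path) -> list[MonomerHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sid, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            hits.append(
                MonomerHit(
                    family_id=name,
                    seq_id=sid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rotation=0,
                    divergence=int(score) / 1000.0,
                )
            )
    return hits


def write_gff3(features, path: str | Path, feature_type: str = "satellite_DNA") -> None:
    """GFF3: 1-based inclusive; divergence and rotation carried as attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            sid, start, end, name, strand, div, rot = _feature_fields(feat)
            attrs = f"family_id={name};divergence={div:.6f}"
            if rot is not None:
                attrs += f";rotation={rot}"
            fh.write(
                f"{sid}\tsatkit\t{feature_type}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[MonomerHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sid, _src, _type, start, end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            hits.append(
                MonomerHit(
                    family_id=fields.get("family_id", "."),
                    seq_id=sid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    rotation=int(fields.get("rotation", 0)),
                    divergence=float(fields.get("divergence", 0.0)),
                )
            )
    return hits
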
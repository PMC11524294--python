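"""Readers and writers for every external format the pipeline touches.

All files carry 1-based inclusive coordinates; everything in memory is 0-based
half-open. The +/-1 arithmetic lives in this module only.

Formats
-------
transcripts   FASTA + GFF3 (features ``five_prime_UTR``/``CDS``/``three_prime_UTR``,
              seqid = transcript id, coordinates in transcript space)
pileup        6-column TSV: transcript, pos, ref, cov, "A,C,G,T" counts, mean qual
sites         TSV (one row per called site) or a minimal VCF dialect with INFO
              keys ED (degree), ET (type), RG (region)
expression    genes x samples TSV, header row of sample ids
labels        TSV: gene, go_terms (semicolon-joined), endosymbiont 0/1, ppr 0/1
              and optionally edited 0/1
evidence      TSV of independent per-position base observations (EST-style)
truth         TSV of simulator-planted sites
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    BASES,
    EditingSite,
    EvidenceCall,
    FormatError,
    PileupColumn,
    PlantedSite,
    TranscriptModel,
    type_label,
)

logger = logging.getLogger("nucredit")

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]
_GFF_FEATURES = {"five_prime_UTR": "utr5", "CDS": "cds", "three_prime_UTR": "utr3"}


# ---------------------------------------------------------------- transcripts

def write_transcripts(
    transcripts: Iterable[TranscriptModel], fasta_path: str | Path, gff3_path: str | Path
) -> None:
    transcripts = list(transcripts)
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for t in transcripts:
        for feature, (start, end) in (
            ("five_prime_UTR", t.utr5), ("CDS", t.cds), ("three_prime_UTR", t.utr3)
        ):
            if end > start:  # empty UTRs are simply omitted
                rows.append(
                    f"{t.id}\tnucredit\t{feature}\t{start + 1}\t{end}\t.\t+\t."
                    f"\tID={t.id}.{feature}"
                )
    Path(gff3_path).write_text("##gff-version 3\n" + "\n".join(rows) + "\n")


def read_transcripts(
    fasta_path: str | Path, gff3_path: str | Path
) -> dict[str, TranscriptModel]:
    """Load transcript models; GFF3 1-based inclusive -> 0-based half-open.

    Transcripts with no UTR features get the empty intervals ``[0,0)`` and
    ``[L,L)``. Missing CDS, overlapping/gapped regions or CDS % 3 != 0 raise
    :class:`FormatError` naming the transcript.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    gff = pd.read_csv(
        gff3_path, sep="\t", comment="#", names=_GFF_COLS, dtype={"seqid": str}
    )
    features: dict[str, dict[str, tuple[int, int]]] = {tid: {} for tid in seqs}
    for row in gff.itertuples(index=False):
        if row.type not in _GFF_FEATURES:
            continue
        if row.seqid not in seqs:
            raise FormatError(f"GFF3 feature on unknown transcript {row.seqid!r}")
        key = _GFF_FEATURES[row.type]
        if key in features[row.seqid]:
            raise FormatError(f"{row.seqid}: duplicate {row.type} feature")
        features[row.seqid][key] = (int(row.start) - 1, int(row.end))

    out: dict[str, TranscriptModel] = {}
    for tid, seq in seqs.items():
        feats = features[tid]
        if "cds" not in feats:
            raise FormatError(f"{tid}: no CDS feature in GFF3")
        cds = feats["cds"]
        utr5 = feats.get("utr5", (0, 0))
        utr3 = feats.get("utr3", (len(seq), len(seq)))
        out[tid] = TranscriptModel(id=tid, sequence=seq, utr5=utr5, cds=cds, utr3=utr3)
    return out


# -------------------------------------------------------------------- pileup

_PILEUP_HEADER = "#transcript\tpos\tref\tcov\tcounts_ACGT\tmean_qual"


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_PILEUP_HEADER + "\n")
        for col in columns:
            counts = ",".join(str(col.counts.get(b, 0)) for b in BASES)
            fh.write(
                f"{col.transcript_id}\t{col.position + 1}\t{col.ref}"
                f"\t{col.coverage}\t{counts}\t{col.mean_qual:g}\n"
            )


def read_pileup(
    path: str | Path, transcripts: dict[str, TranscriptModel] | None = None
) -> Iterator[PileupColumn]:
    """Stream pileup columns, validating each row.

    When ``transcripts`` is given, the row's ref base is checked against the
    transcript sequence (this guards the DNA-RNA comparison); columns whose
    reference base is N are skipped with a logged count.
    """
    n_skipped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{line_no}: expected 6 columns")
            tid, pos1, ref, cov, counts_s, qual = parts
            position = int(pos1) - 1
            counts = dict(zip(BASES, (int(x) for x in counts_s.split(","))))
            if sum(counts.values()) != int(cov):
                raise FormatError(
                    f"{path}:{line_no}: counts {counts_s} do not sum to cov {cov}"
                )
            if transcripts is not None:
                t = transcripts.get(tid)
                if t is None:
                    raise FormatError(f"{path}:{line_no}: unknown transcript {tid!r}")
                if not 0 <= position < len(t):
                    raise FormatError(f"{path}:{line_no}: position out of range")
                seq_base = t.sequence[position]
                if seq_base == "N":
                    n_skipped += 1
                    continue
                if seq_base != ref:
                    raise FormatError(
                        f"{path}:{line_no}: ref {ref} != transcript base {seq_base}"
                    )
            yield PileupColumn(
                transcript_id=tid, position=position, ref=ref,
                counts=counts, mean_qual=float(qual),
            )
    if n_skipped:
        logger.info("read_pileup: skipped %d columns on N reference bases", n_skipped)


# --------------------------------------------------------------------- sites

_SITE_COLS = [
    "transcript", "pos", "ref", "alt", "type", "coverage", "edited_count",
    "degree", "p", "q", "region", "codon_pos", "synonymous",
    "ref_codon", "alt_codon", "ref_aa", "alt_aa",
]


def _site_row(s: EditingSite) -> dict:
    return {
        "transcript": s.transcript_id,
        "pos": s.position + 1,
        "ref": s.ref,
        "alt": s.alt,
        "type": s.type_label,
        "coverage": s.coverage,
        "edited_count": s.alt_count,
        "degree": s.degree,
        "p": s.p_value,
        "q": s.q_value,
        "region": s.region,
        "codon_pos": s.codon_position,
        "synonymous": s.synonymous,
        "ref_codon": s.ref_codon,
        "alt_codon": s.alt_codon,
        "ref_aa": s.ref_aa,
        "alt_aa": s.alt_aa,
    }


def sites_to_frame(sites: Iterable[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame([_site_row(s) for s in sites], columns=_SITE_COLS)


def write_sites(
    sites: Iterable[EditingSite], path: str | Path, dialect: str = "tsv"
) -> None:
    sites = list(sites)
    if dialect == "tsv":
        sites_to_frame(sites).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=ED,Number=1,Type=Float,Description="Editing degree">\n')
            fh.write('##INFO=<ID=ET,Number=1,Type=String,Description="Editing type">\n')
            fh.write('##INFO=<ID=RG,Number=1,Type=String,Description="Region">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in sites:
                info = f"ED={s.degree:.6g};ET={s.type_label}"
                if s.region:
                    info += f";RG={s.region}"
                fh.write(
                    f"{s.transcript_id}\t{s.position + 1}\t.\t{s.ref}\t{s.alt}"
                    f"\t.\tPASS\t{info}\n"
                )
    else:
        raise ValueError(f"unknown sites dialect {dialect!r}")


def _opt(value, cast):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return cast(value)


def read_sites(path: str | Path) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript": str})
    out = []
    for row in df.itertuples(index=False):
        syn = _opt(row.synonymous, lambda v: str(v) in ("True", "1", "1.0"))
        out.append(
            EditingSite(
                transcript_id=row.transcript,
                position=int(row.pos) - 1,
                ref=row.ref,
                alt=row.alt,
                coverage=int(row.coverage),
                alt_count=int(row.edited_count),
                error_rate=0.0,
                p_value=_opt(row.p, float),
                q_value=_opt(row.q, float),
                type_label=row.type,
                degree=float(row.degree),
                region=_opt(row.region, str),
                codon_position=_opt(row.codon_pos, lambda v: int(float(v))),
                ref_codon=_opt(row.ref_codon, str),
                alt_codon=_opt(row.alt_codon, str),
                ref_aa=_opt(row.ref_aa, str),
                alt_aa=_opt(row.alt_aa, str),
                synonymous=syn,
            )
        )
    return out


# ----------------------------------------------------- expression and labels

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix; the index is the gene id column."""
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index_label="gene")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Label table indexed by gene: go_terms (';'-joined), endosymbiont, ppr[, edited]."""
    df = pd.read_csv(path, sep="\t", index_col="gene", dtype={"gene": str})
    if "go_terms" in df.columns:
        df["go_terms"] = df["go_terms"].fillna("")
    return df


# ------------------------------------------------------- evidence and truth

def write_evidence(calls: Iterable[EvidenceCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript\tpos\tobserved_base\n")
        for c in calls:
            fh.write(f"{c.transcript_id}\t{c.position + 1}\t{c.observed_base}\n")


def read_evidence(path: str | Path) -> list[EvidenceCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, pos1, base = line.split()
            out.append(EvidenceCall(tid, int(pos1) - 1, base))
    return out


def write_truth(sites: Iterable[PlantedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript\tpos\tref\talt\tdegree\n")
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.position + 1}\t{s.ref_base}\t{s.alt_base}"
                f"\t{s.true_degree!r}\n"  # repr: lossless float round-trip
            )


def read_truth(path: str | Path) -> list[PlantedSite]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, pos1, ref, alt, degree = line.split()
            out.append(PlantedSite(tid, int(pos1) - 1, ref, alt, float(degree)))
    return out
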
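"""Characterization of called editing sites.

Covers region assignment (5'UTR / CDS / 3'UTR), codon position and synonymy
under the standard genetic code, per-region editing densities, per-amino-acid
editing rates, transcript grouping by edited region combination, RPKM-style
expression records, and cross-validation against independent per-position
evidence (EST-style observations).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .models import EditingSite, EvidenceCall, TranscriptModel

logger = logging.getLogger("nucredit")

REGIONS = ("5UTR", "CDS", "3UTR")
_REGION_LETTER = {"5UTR": "A", "CDS": "B", "3UTR": "C"}

#: codon -> one-letter amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

#: amino acid (or '*') -> number of codons encoding it in the standard code
DEGENERACY: dict[str, int] = {}
for _codon, _aa in CODON_TO_AA.items():
    DEGENERACY[_aa] = DEGENERACY.get(_aa, 0) + 1


def assign_region(site: EditingSite, transcript: TranscriptModel) -> str:
    """Region class containing the site (half-open interval membership)."""
    return transcript.region_of(site.position)


def annotate_codon(site: EditingSite, transcript: TranscriptModel) -> None:
    """Fill codon position, ref/alt codons, amino acids and synonymy in place.

    Only meaningful for CDS sites. Codon position is 1-based within the codon;
    the alt codon substitutes the edited base; translation uses the standard
    code with '*' for stop. Codons containing N leave the codon fields unset.
    """
    cds_start = transcript.cds[0]
    offset = site.position - cds_start
    codon_position = offset % 3 + 1
    codon_start = site.position - (codon_position - 1)
    ref_codon = transcript.sequence[codon_start : codon_start + 3]
    if "N" in ref_codon or len(ref_codon) < 3:
        logger.info("annotate_codon: %s:%d codon contains N, skipped",
                    site.transcript_id, site.position)
        site.codon_position = codon_position
        return
    alt_codon = (
        ref_codon[: codon_position - 1] + site.alt + ref_codon[codon_position:]
    )
    site.codon_position = codon_position
    site.ref_codon = ref_codon
    site.alt_codon = alt_codon
    site.ref_aa = CODON_TO_AA[ref_codon]
    site.alt_aa = CODON_TO_AA[alt_codon]
    site.synonymous = site.ref_aa == site.alt_aa


def annotate_sites(
    sites: Iterable[EditingSite], transcripts: Mapping[str, TranscriptModel]
) -> list[EditingSite]:
    """Assign regions to all sites and codon annotation to CDS sites."""
    out = []
    for site in sites:
        t = transcripts[site.transcript_id]
        site.region = assign_region(site, t)
        if site.region == "CDS":
            annotate_codon(site, t)
        out.append(site)
    return out


# ------------------------------------------------------------------ density

def density_table(
    sites: Iterable[EditingSite],
    transcripts: Mapping[str, TranscriptModel],
    edited_only: bool = False,
) -> pd.DataFrame:
    """Editing density (sites per kilobase) per region class and editing type.

    The denominator for a region class is the summed length of that region
    over the supplied transcripts (restricted to edited transcripts when
    ``edited_only``), in kb.
    """
    sites = list(sites)
    if any(s.region is None for s in sites):
        raise ValueError("sites must be region-annotated first")
    pool = (
        {s.transcript_id for s in sites} if edited_only else set(transcripts)
    )
    kb = {
        region: sum(
            getattr(transcripts[tid], attr)[1] - getattr(transcripts[tid], attr)[0]
            for tid in pool
        ) / 1000.0
        for region, attr in (("5UTR", "utr5"), ("CDS", "cds"), ("3UTR", "utr3"))
    }
    counts: dict[tuple[str, str], int] = {}
    for s in sites:
        counts[(s.region, s.type_label)] = counts.get((s.region, s.type_label), 0) + 1
    rows = []
    for (region, tlab), count in sorted(counts.items()):
        if kb[region] == 0:
            raise ValueError(f"region {region} has zero total length but {count} sites")
        rows.append((region, tlab, count, kb[region], count / kb[region]))
    return pd.DataFrame(
        rows, columns=["region", "type", "count", "kb", "density"]
    )


# ----------------------------------------------------------- amino-acid rates

def amino_acid_rates(
    sites: Iterable[EditingSite],
    denominator: str = "degeneracy",
    transcripts: Mapping[str, TranscriptModel] | None = None,
) -> pd.Series:
    """Editing events per codon for each amino acid (stop included as '*').

    ``denominator="degeneracy"`` divides each amino acid's event count by the
    number of codons encoding it in the standard code (e.g. D=2, W=1, stop=3).
    ``denominator="usage"`` divides by the codon occurrences in the supplied
    transcripts' CDS instead.
    """
    counts: dict[str, int] = {aa: 0 for aa in sorted(set(CODON_TO_AA.values()))}
    for s in sites:
        if s.ref_aa is not None:
            counts[s.ref_aa] += 1
    if denominator == "degeneracy":
        denom = {aa: DEGENERACY[aa] for aa in counts}
    elif denominator == "usage":
        if transcripts is None:
            raise ValueError("usage denominator requires transcripts")
        denom = {aa: 0 for aa in counts}
        for t in transcripts.values():
            cds = t.cds_sequence
            for k in range(0, len(cds), 3):
                aa = CODON_TO_AA.get(cds[k : k + 3])
                if aa is not None:
                    denom[aa] += 1
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return pd.Series(
        {aa: counts[aa] / denom[aa] if denom[aa] else math.nan for aa in counts},
        name="events_per_codon",
    )


# ------------------------------------------------------------------- groups

def group_transcripts(
    sites: Iterable[EditingSite],
    log2_rpkm: Mapping[str, float] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Label every edited transcript by the set of regions bearing sites.

    Labels concatenate region letters in fixed order: A = 5'UTR, B = CDS,
    C = 3'UTR (so a transcript edited in 5'UTR and 3'UTR gets "AC"). Returns
    the per-transcript labels and a per-group summary (transcript count and,
    when ``log2_rpkm`` is supplied, median and mean expression).
    """
    regions_by_gene: dict[str, set[str]] = {}
    for s in sites:
        if s.region is None:
            raise ValueError("sites must be region-annotated first")
        regions_by_gene.setdefault(s.transcript_id, set()).add(s.region)
    labels = {
        gene: "".join(
            _REGION_LETTER[r] for r in REGIONS if r in regs
        )
        for gene, regs in regions_by_gene.items()
    }
    # fixed order: A<B<C by letter
    labels = {g: "".join(sorted(v)) for g, v in labels.items()}
    rows = []
    for group in ("A", "B", "C", "AB", "AC", "BC", "ABC"):
        members = [g for g, lab in labels.items() if lab == group]
        row = {"group": group, "n_transcripts": len(members)}
        if log2_rpkm is not None and members:
            vals = [log2_rpkm[g] for g in members if g in log2_rpkm]
            if vals:
                row["median_log2_rpkm"] = float(np.median(vals))
                row["mean_log2_rpkm"] = float(np.mean(vals))
        rows.append(row)
    return labels, pd.DataFrame(rows)


# --------------------------------------------------------------- expression

def expression_records(
    read_counts: pd.Series,
    length_kb: pd.Series,
    total_mapped_millions: float,
    mean_degrees: Mapping[str, float] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """RPKM-style expression records.

    rpkm = count / (length_kb * million mapped reads); log2 is taken of
    rpkm + pseudocount where positive (NaN otherwise); adjusted_expression
    multiplies rpkm by the gene's mean editing degree (1.0 when unedited),
    approximating the number of edited transcripts.
    """
    if total_mapped_millions <= 0:
        raise ValueError("total_mapped_millions must be positive")
    rpkm = read_counts / (length_kb * total_mapped_millions)
    shifted = rpkm + pseudocount
    log2 = pd.Series(
        np.where(shifted > 0, np.log2(shifted.where(shifted > 0)), np.nan),
        index=rpkm.index,
    )
    degrees = pd.Series(
        {g: (mean_degrees or {}).get(g, 1.0) for g in rpkm.index}, dtype=float
    )
    return pd.DataFrame(
        {
            "raw_count": read_counts,
            "length_kb": length_kb,
            "rpkm": rpkm,
            "log2_rpkm": log2,
            "mean_editing_degree": degrees,
            "adjusted_expression": rpkm * degrees,
        }
    )


def mean_degrees(sites: Iterable[EditingSite]) -> dict[str, float]:
    """Per-transcript mean editing degree over its sites."""
    acc: dict[str, list[float]] = {}
    for s in sites:
        acc.setdefault(s.transcript_id, []).append(s.degree)
    return {g: float(np.mean(v)) for g, v in acc.items()}


# ----------------------------------------------------------- cross-validation

def cross_validate(
    sites: Iterable[EditingSite], evidence: Iterable[EvidenceCall]
) -> dict:
    """Confirm sites against independent per-position base observations.

    A site is *covered* when at least one observation exists at its position,
    and *confirmed* when any observation there equals the edited base. The
    confirmed fraction is None when nothing is covered.
    """
    by_pos: dict[tuple[str, int], set[str]] = {}
    for ev in evidence:
        by_pos.setdefault((ev.transcript_id, ev.position), set()).add(ev.observed_base)
    covered = confirmed = 0
    per_transcript: dict[str, dict[str, int]] = {}
    confirmed_transcripts: set[str] = set()
    for s in sites:
        bases = by_pos.get((s.transcript_id, s.position))
        if bases is None:
            continue
        covered += 1
        roll = per_transcript.setdefault(
            s.transcript_id, {"covered": 0, "confirmed": 0}
        )
        roll["covered"] += 1
        if s.alt in bases:
            confirmed += 1
            roll["confirmed"] += 1
            confirmed_transcripts.add(s.transcript_id)
    fraction: Optional[float] = confirmed / covered if covered else None
    return {
        "covered": covered,
        "confirmed": confirmed,
        "confirmed_fraction": fraction,
        "covered_transcripts": len(per_transcript),
        "confirmed_transcripts": len(confirmed_transcripts),
        "per_transcript": pd.DataFrame.from_dict(per_transcript, orient="index"),
    }


# ------------------------------------------------------------------ summary

def summarize(
    sites: list[EditingSite], transcripts: Mapping[str, TranscriptModel]
) -> dict:
    """Tabular summary: type x codon-position matrix, synonymy table, density
    table, amino-acid rates and region-combination groups."""
    type_by_codon = (
        pd.DataFrame(
            [
                {"type": s.type_label, "codon_pos": s.codon_position}
                for s in sites
                if s.region == "CDS" and s.codon_position is not None
            ]
        )
        .value_counts()
        .unstack(fill_value=0)
        if any(s.region == "CDS" for s in sites)
        else pd.DataFrame()
    )
    synonymy = pd.Series(
        [s.synonymous for s in sites if s.synonymous is not None]
    ).value_counts()
    labels, groups = group_transcripts(sites)
    return {
        "n_sites": len(sites),
        "region_counts": {
            r: sum(1 for s in sites if s.region == r) for r in REGIONS
        },
        "type_by_codon_position": type_by_codon,
        "synonymy": {
            "synonymous": int(synonymy.get(True, 0)),
            "non_synonymous": int(synonymy.get(False, 0)),
        },
        "density": density_table(sites, transcripts),
        "amino_acid_rates": amino_acid_rates(sites),
        "groups": groups,
        "group_labels": labels,
    }
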
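"""Editing-site caller: coverage filter, exact test against sequencing error,
FDR correction and editing degrees.

The statistical model: at a candidate position with coverage ``n`` and
``k`` reads carrying one specific non-reference base, sequencing error alone
would produce that base at rate ``error_rate / 3`` (error is assumed uniform
over the three non-reference bases). A one-sided Fisher's exact test compares
the observed (k, n-k) split against the expected-under-error split
(round(n * error_rate / 3), rest); candidates are kept when the
Benjamini-Hochberg adjusted p-value falls strictly below ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CandidateSNV, EditingSite, PileupColumn, type_label

logger = logging.getLogger("nucredit")


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Thresholds of the filter cascade.

    seed_length: leading aligned bases that must match perfectly.
    max_edits_per_read: ceiling on candidate editing sites per aligned read.
    min_base_quality: Phred floor defining a "high quality" column.
    min_coverage: minimum high-quality reads for a candidate position.
    alpha: FDR threshold on adjusted p-values (strictly less-than).
    """

    seed_length: int = 22
    max_edits_per_read: int = 3
    min_base_quality: float = 20.0
    min_coverage: int = 50
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if min(self.seed_length, self.max_edits_per_read, self.min_coverage) <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal aligned-read record for the per-read filter: 0-based offsets of
    mismatches within the aligned portion, plus the aligned length."""

    aligned_length: int
    mismatch_offsets: tuple[int, ...] = ()


def filter_read(read: AlignedRead, policy: ReadFilterPolicy) -> tuple[bool, str]:
    """Accept/reject one aligned read; returns (accepted, reason).

    Rejected when the read is shorter than the seed, when any mismatch falls
    inside the perfect-match seed, or when it carries more candidate editing
    sites than ``max_edits_per_read``.
    """
    if read.aligned_length < policy.seed_length:
        return False, "short"
    if any(off < policy.seed_length for off in read.mismatch_offsets):
        return False, "seed_mismatch"
    if len(read.mismatch_offsets) > policy.max_edits_per_read:
        return False, "too_many_edits"
    return True, "ok"


def collect_candidates(
    pileup: Iterable[PileupColumn],
    policy: ReadFilterPolicy,
    error_rate: float | None = None,
) -> list[CandidateSNV]:
    """One candidate per (column, non-reference base with >=1 read).

    Columns failing the coverage or base-quality floor contribute nothing. The
    per-candidate error rate comes from the column's mean quality
    (``10^(-q/10)``) unless a global ``error_rate`` override is supplied.

    Note: the per-read filters (:func:`filter_read`) apply to alignment
    records; pileup input is assumed to have had them applied upstream.
    """
    dropped_cov = dropped_qual = 0
    out: list[CandidateSNV] = []
    for col in pileup:
        if col.mean_qual < policy.min_base_quality:
            dropped_qual += 1
            continue
        if col.coverage < policy.min_coverage:
            dropped_cov += 1
            continue
        eps = error_rate if error_rate is not None else col.error_rate
        for base, count in col.counts.items():
            if base == col.ref or count < 1:
                continue
            out.append(
                CandidateSNV(
                    transcript_id=col.transcript_id,
                    position=col.position,
                    ref=col.ref,
                    alt=base,
                    coverage=col.coverage,
                    alt_count=count,
                    error_rate=eps,
                )
            )
    if dropped_cov or dropped_qual:
        logger.info(
            "collect_candidates: dropped %d columns below coverage %d, "
            "%d below quality %g",
            dropped_cov, policy.min_coverage, dropped_qual, policy.min_base_quality,
        )
    return out


def fisher_error_test(alt_count: int, coverage: int, error_rate: float) -> float:
    """One-sided (greater) Fisher's exact p for the observed alt reads against
    the expectation under sequencing error.

    The 2x2 table is ``[[alt, cov-alt], [round(cov*err/3), rest]]`` with
    round-half-to-even on the expected count; error is split over the three
    possible non-reference bases.
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0,1)")
    if coverage < 1 or not 0 <= alt_count <= coverage:
        raise ValueError("need 0 <= alt_count <= coverage, coverage >= 1")
    expected = round(coverage * error_rate / 3.0)  # banker's rounding
    table = [[alt_count, coverage - alt_count], [expected, coverage - expected]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (empty in, empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sites(
    candidates: list[CandidateSNV], policy: ReadFilterPolicy
) -> list[EditingSite]:
    """Test, adjust, threshold: keep candidates with q strictly below alpha,
    attach the RNA-space type label and the editing degree."""
    if not candidates:
        return []
    pvals = [
        fisher_error_test(c.alt_count, c.coverage, c.error_rate) for c in candidates
    ]
    qvals = adjust_fdr(pvals)
    sites: list[EditingSite] = []
    for cand, p, q in zip(candidates, pvals, qvals):
        cand.p_value = p
        cand.q_value = float(q)
        if q < policy.alpha:
            sites.append(
                EditingSite(
                    transcript_id=cand.transcript_id,
                    position=cand.position,
                    ref=cand.ref,
                    alt=cand.alt,
                    coverage=cand.coverage,
                    alt_count=cand.alt_count,
                    error_rate=cand.error_rate,
                    p_value=p,
                    q_value=float(q),
                    type_label=type_label(cand.ref, cand.alt),
                    degree=cand.alt_count / cand.coverage,
                )
            )
    logger.info("call_sites: %d of %d candidates pass q < %g",
                len(sites), len(candidates), policy.alpha)
    return sites


def call_from_pileup(
    pileup: Iterable[PileupColumn],
    policy: ReadFilterPolicy | None = None,
    error_rate: float | None = None,
) -> list[EditingSite]:
    """Convenience: pileup stream -> called editing sites."""
    policy = policy or ReadFilterPolicy()
    return call_sites(collect_candidates(pileup, policy, error_rate), policy)
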
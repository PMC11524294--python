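"""Positional composition analysis around edited C residues.

For each cluster of C-to-U edited genes, the ±5 flanking bases of every edited
C are tallied into a 4 x 11 composition matrix (positions -5..+5, the edited C
at 0). A background matrix is built from the ±5 context of *every* C residue
with a full flank in the supplied transcripts, column-normalized. Each flanking
position is then tested by a chi-square goodness-of-fit of the cluster's
observed base counts against the background proportions (df = 3), and the core
motif is called from the significant purine-dominated positions: a conserved
A/G at -1 and +1 yields the core "RCR".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import BASES, EditingSite, TranscriptModel

logger = logging.getLogger("nucredit")

WINDOW = 5
POSITIONS = tuple(range(-WINDOW, WINDOW + 1))
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class CompositionMatrix:
    """Base x position count matrix over the ±window context of edited Cs."""

    counts: np.ndarray  # 4 x (2*window+1)
    n_sites: int

    def purine_fraction(self, position: int) -> float:
        col = self.counts[:, position + WINDOW]
        total = col.sum()
        return float((col[_BASE_IDX["A"]] + col[_BASE_IDX["G"]]) / total) if total else 0.0


@dataclass
class PositionTest:
    position: int
    chi2: float
    df: int
    p_value: float
    dominant_bases: str


def extract_flanks(
    sites: Iterable[EditingSite],
    transcripts: Mapping[str, TranscriptModel],
    window: int = WINDOW,
) -> list[str]:
    """(2*window+1)-mers centred on each edited C; sites too close to a
    transcript end are skipped with a logged count."""
    flanks = []
    skipped = 0
    for s in sites:
        if s.ref != "C":
            raise ValueError(
                f"{s.transcript_id}:{s.position}: flank extraction expects C-to-U "
                f"sites, got ref {s.ref}"
            )
        seq = transcripts[s.transcript_id].sequence
        if not window <= s.position <= len(seq) - 1 - window:
            skipped += 1
            continue
        flank = seq[s.position - window : s.position + window + 1]
        if seq[s.position] != "C":
            raise ValueError(
                f"{s.transcript_id}:{s.position}: transcript base is "
                f"{seq[s.position]}, not C"
            )
        flanks.append(flank)
    if skipped:
        logger.info("extract_flanks: %d sites too close to transcript ends", skipped)
    return flanks


def composition_matrix(flanks: Sequence[str], window: int = WINDOW) -> CompositionMatrix:
    """Tally base occurrences per position; flanks with non-ACGT characters
    are dropped with a logged count."""
    width = 2 * window + 1
    counts = np.zeros((4, width), dtype=np.int64)
    n = dropped = 0
    for flank in flanks:
        if len(flank) != width:
            raise ValueError(f"flank {flank!r} is not {width} bases long")
        if any(b not in _BASE_IDX for b in flank):
            dropped += 1
            continue
        for j, b in enumerate(flank):
            counts[_BASE_IDX[b], j] += 1
        n += 1
    if dropped:
        logger.info("composition_matrix: dropped %d flanks with non-ACGT bases", dropped)
    return CompositionMatrix(counts=counts, n_sites=n)


def background_matrix(
    transcripts: Mapping[str, TranscriptModel], window: int = WINDOW
) -> pd.DataFrame:
    """Column-stochastic base x position proportions over the ±window context
    of every C residue (with a full flank) in the supplied transcripts."""
    width = 2 * window + 1
    counts = np.zeros((4, width), dtype=np.int64)
    n_context = 0
    for tid in sorted(transcripts):
        seq = transcripts[tid].sequence
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(len(arr), -1, dtype=np.int8)
        for b, i in _BASE_IDX.items():
            code[arr == ord(b)] = i
        c_pos = np.flatnonzero(code == _BASE_IDX["C"])
        c_pos = c_pos[(c_pos >= window) & (c_pos <= len(arr) - 1 - window)]
        n_context += len(c_pos)
        for j, off in enumerate(range(-window, window + 1)):
            ctx = code[c_pos + off]
            for i in range(4):
                counts[i, j] += int((ctx == i).sum())
    if n_context == 0:
        raise ValueError("no C residue with a full flank in the transcripts")
    col_sums = counts.sum(axis=0)  # N neighbours excluded: normalize over ACGT
    props = counts / col_sums
    return pd.DataFrame(props, index=list(BASES), columns=list(range(-window, window + 1)))


def test_positions(
    cluster_matrix: CompositionMatrix,
    background: pd.DataFrame,
    min_sites: int = 20,
    mode: str = "gof",
) -> list[PositionTest]:
    """Chi-square per flanking position (position 0 excluded).

    ``mode="gof"`` (default) tests the cluster's observed 4-vector against the
    expected counts n * background proportions (goodness-of-fit, df 3);
    ``mode="independence"`` tests the observed counts against the background
    *counts* scaled to proportions via a 2 x 4 contingency table.

    A zero background proportion with a nonzero observation gets a continuity
    floor of 1/(4n) (expected count 0.25) so the statistic stays finite; zero
    background cells with zero observations contribute nothing.
    """
    n = cluster_matrix.n_sites
    if n < min_sites:
        raise ValueError(f"only {n} sites; need >= {min_sites} for the chi-square")
    window = (cluster_matrix.counts.shape[1] - 1) // 2
    out = []
    for pos in range(-window, window + 1):
        if pos == 0:
            continue
        obs = cluster_matrix.counts[:, pos + window].astype(float)
        bg = background[pos].to_numpy(dtype=float)
        if mode == "gof":
            bg_eff = bg.copy()
            floored = (bg_eff == 0) & (obs > 0)
            if floored.any():
                logger.info("test_positions: continuity floor at position %d", pos)
                bg_eff[floored] = 1.0 / (4.0 * n)
            expected = n * bg_eff
            with np.errstate(invalid="ignore", divide="ignore"):
                terms = (obs - expected) ** 2 / expected
            terms[(expected == 0) & (obs == 0)] = 0.0
            chi2 = float(terms.sum())
            p = float(stats.chi2.sf(chi2, df=3))
        elif mode == "independence":
            table = np.vstack([obs, n * bg])
            chi2, p, _, _ = stats.chi2_contingency(table)
            chi2, p = float(chi2), float(p)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        enriched = [
            BASES[i] for i in range(4) if obs[i] > n * bg[i]
        ]
        out.append(
            PositionTest(
                position=pos, chi2=chi2, df=3, p_value=p,
                dominant_bases="".join(enriched),
            )
        )
    return out


def call_core_motif(
    tests: Sequence[PositionTest],
    cluster_matrix: CompositionMatrix,
    purine_threshold: float = 0.6,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> dict:
    """Label each flanking position and call the core motif.

    A position is labeled R when its composition differs significantly from
    background (at ``alpha``, Bonferroni-corrected over the tested positions by
    default) *and* its purine (A+G) fraction reaches ``purine_threshold``;
    non-significant positions are labeled N; the centre is always C. The core
    motif trims flanking Ns (e.g. "RCR" when only -1/+1 are conserved).
    """
    m = len(tests) if correction == "bonferroni" else 1
    cutoff = alpha / m
    labels = {}
    purine = {}
    for t in tests:
        frac = cluster_matrix.purine_fraction(t.position)
        purine[t.position] = frac
        labels[t.position] = (
            "R" if (t.p_value < cutoff and frac >= purine_threshold) else "N"
        )
    window = max(abs(t.position) for t in tests)
    full = "".join(
        "C" if pos == 0 else labels.get(pos, "N")
        for pos in range(-window, window + 1)
    )
    # no conserved flanking position at all -> no motif, not a bare "C"
    core = full.strip("N") if any(v != "N" for v in labels.values()) else ""
    return {
        "motif": full,
        "core": core,
        "labels": labels,
        "purine_fractions": purine,
        "significant_positions": sorted(
            t.position for t in tests if t.p_value < cutoff
        ),
    }


def scan_cluster(
    sites: Iterable[EditingSite],
    transcripts: Mapping[str, TranscriptModel],
    background: pd.DataFrame | None = None,
    window: int = WINDOW,
    min_sites: int = 20,
) -> dict:
    """Convenience: C-to-U sites of one cluster -> composition, tests, motif."""
    if background is None:
        background = background_matrix(transcripts, window)
    flanks = extract_flanks(sites, transcripts, window)
    cm = composition_matrix(flanks, window)
    tests = test_positions(cm, background, min_sites=min_sites)
    motif = call_core_motif(tests, cm)
    return {"composition": cm, "tests": tests, **motif}
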